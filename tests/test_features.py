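import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from multisyn.features import (
    CombinationSpec,
    FeatureSchema,
    FeatureStandardizer,
    LabelConfig,
    assemble_samples,
    encode_combination,
    select_gene_panel,
    split_dataset,
    split_sizes,
)


@pytest.fixture()
def schema():
    return FeatureSchema(gene_panel=["g1", "g2"], target_universe=["t1", "t2", "t3", "t4"])


class TestFeatureSchema:
    def test_dimension_is_panel_plus_universe(self, schema):
        assert schema.feature_dim == 6

    @pytest.mark.parametrize("panel,universe", [([], ["t"]), (["g"], []), (["g", "g"], ["t"])])
    def test_rejects_empty_or_duplicated_lists(self, panel, universe):
        with pytest.raises(ValueError):
            FeatureSchema(panel, universe)


class TestSelectGenePanel:
    def test_duplicate_probe_rows_collapse_to_mean(self):
        mat = pd.DataFrame([[2.0], [4.0], [1.0]], index=["G", "G", "H"], columns=["c1"])
        out, report = select_gene_panel(mat, ["G", "H"])
        assert out.loc["G", "c1"] == 3.0
        assert report.collapsed_duplicates == ["G"]

    def test_full_panel_reorders_identically(self):
        mat = pd.DataFrame(np.arange(6.0).reshape(3, 2), index=["a", "b", "c"], columns=["x", "y"])
        out, _ = select_gene_panel(mat, ["c", "a", "b"])
        assert list(out.index) == ["c", "a", "b"]
        pd.testing.assert_frame_equal(out.sort_index(), mat.sort_index())

    def test_absent_gene_dropped_and_reported(self):
        mat = pd.DataFrame([[1.0]], index=["a"], columns=["x"])
        out, report = select_gene_panel(mat, ["a", "zz"])
        assert list(out.index) == ["a"] and report.missing_genes == ["zz"]

    def test_empty_intersection_raises_naming_missing(self):
        mat = pd.DataFrame([[1.0]], index=["a"], columns=["x"])
        with pytest.raises(ValueError, match="zz"):
            select_gene_panel(mat, ["zz"])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"), columns=list("xyz"))
        once, _ = select_gene_panel(mat, ["b", "d"])
        twice, _ = select_gene_panel(once, ["b", "d"])
        pd.testing.assert_frame_equal(once, twice)


class TestEncodeCombination:
    tmap = {"d1": {"t1", "t3"}, "d2": {"t3", "t4"}, "d0": set()}

    def test_singleton_matches_drug_encoding(self, schema):
        vec = encode_combination(CombinationSpec(["d1"]), self.tmap, schema)
        assert vec.tolist() == [1, 0, 1, 0]

    def test_union_of_member_targets(self, schema):
        vec = encode_combination(CombinationSpec(["d1", "d2"]), self.tmap, schema)
        assert vec.tolist() == [1, 0, 1, 1]

    def test_empty_target_set_warns_and_contributes_zeros(self, schema):
        with pytest.warns(UserWarning, match="empty target set"):
            vec = encode_combination(CombinationSpec(["d0"]), self.tmap, schema)
        assert vec.tolist() == [0, 0, 0, 0]

    def test_unknown_drug_raises(self, schema):
        with pytest.raises(KeyError):
            encode_combination(CombinationSpec(["nope"]), self.tmap, schema)

    @given(st.sets(st.sampled_from(["d1", "d2"]), min_size=1))
    def test_commutative_and_idempotent_over_drug_sets(self, drugs):
        schema = FeatureSchema(["g1", "g2"], ["t1", "t2", "t3", "t4"])
        base = encode_combination(CombinationSpec(drugs), self.tmap, schema)
        doubled = encode_combination(CombinationSpec(list(drugs) * 2), self.tmap, schema)
        assert np.array_equal(base, doubled)

    def test_canonical_id_is_order_independent(self):
        assert CombinationSpec(["b", "a"]).canonical_id == CombinationSpec(["a", "b"]).canonical_id


class TestAssembleSamples:
    profiles = {"c1": {"g1": 1.0, "g2": 2.0}}
    tmap = {"d1": {"t1"}}

    def _responses(self, ic50, unit="nM"):
        return pd.DataFrame([{"drug_id": "d1", "cell_line_id": "c1", "ic50": ic50, "unit": unit}])

    @pytest.mark.parametrize("ic50,expected", [(10.0, 1), (10.1, 0)])
    def test_class_label_threshold_at_10nM_inclusive(self, schema, ic50, expected):
        sset, _ = assemble_samples(self.profiles, self.tmap, self._responses(ic50), schema)
        assert sset.y_class[0] == expected

    def test_regression_label_is_natural_log_of_micromolar(self, schema):
        sset, _ = assemble_samples(
            self.profiles, self.tmap, self._responses(float(np.exp(2)), unit="uM"), schema
        )
        assert sset.y_regression[0] == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_ic50_rejected_and_counted(self, schema):
        resp = pd.concat([self._responses(5.0), self._responses(-1.0)], ignore_index=True)
        sset, report = assemble_samples(self.profiles, self.tmap, resp, schema)
        assert len(sset) == 1 and report.n_rejected == 1 and report.rejected_rows == [1]

    def test_feature_layout_is_expression_then_targets(self, schema):
        sset, _ = assemble_samples(self.profiles, self.tmap, self._responses(5.0), schema)
        assert sset.X[0].tolist() == [1.0, 2.0, 1.0, 0.0, 0.0, 0.0]


class TestStandardizer:
    def test_zscore_closed_form_population_sd(self):
        std = FeatureStandardizer().fit(np.array([[1.0], [2.0], [3.0]]))
        out = std.transform(np.array([[1.0], [2.0], [3.0]]))
        assert out.ravel() == pytest.approx([-1.224744871, 0.0, 1.224744871], abs=1e-8)

    def test_constant_column_flagged_and_zeroed(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0]])
        std = FeatureStandardizer().fit(X)
        assert std.constant_mask_.tolist() == [False, True]
        assert np.all(std.transform(X)[:, 1] == 0.0)

    def test_test_data_uses_training_statistics(self):
        std = FeatureStandardizer().fit(np.array([[0.0], [2.0]]))  # mean 1, sd 1
        assert std.transform(np.array([[1.0]]))[0, 0] == pytest.approx(0.0)

    def test_unfitted_transform_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            FeatureStandardizer().transform(np.zeros((2, 2)))

    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_through_inverse(self, seed):
        X = np.random.default_rng(seed).normal(size=(5, 3)) * 10
        std = FeatureStandardizer().fit(X)
        assert np.allclose(std.inverse_transform(std.transform(X)), X, atol=1e-9)


class TestSplit:
    def test_published_scale_split_arithmetic(self):
        assert split_sizes(201_405, 0.8) == (161_124, 40_281)

    def test_small_split_sizes_and_disjointness(self, tiny_world):
        import multisyn as m

        mono, _ = m.generate_responses(tiny_world)
        samples, _ = m.assemble_samples(
            tiny_world.profiles(), tiny_world.target_map, mono, tiny_world.schema
        )
        train, test = split_dataset(samples, 0.8, seed=3)
        assert len(train) == round(0.8 * len(samples)) and len(train) + len(test) == len(samples)
        ids = lambda s: {(c, d) for c, d in zip(s.cell_line_ids, s.combination_ids)}
        assert ids(train).isdisjoint(ids(test))

    def test_same_seed_reproduces_membership(self, tiny_world):
        import multisyn as m

        mono, _ = m.generate_responses(tiny_world)
        samples, _ = m.assemble_samples(
            tiny_world.profiles(), tiny_world.target_map, mono, tiny_world.schema
        )
        a1, _ = split_dataset(samples, 0.7, seed=11)
        a2, _ = split_dataset(samples, 0.7, seed=11)
        assert np.array_equal(a1.X, a2.X)

    def test_tiny_inputs_rejected(self, schema):
        sset, _ = assemble_samples(
            {"c1": {"g1": 1.0, "g2": 2.0}},
            {"d1": {"t1"}},
            pd.DataFrame([{"drug_id": "d1", "cell_line_id": "c1", "ic50": 5.0, "unit": "nM"}]),
            schema,
        )
        with pytest.raises(ValueError):
            split_dataset(sset, 0.8, seed=0)
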