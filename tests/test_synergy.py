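import numpy as np
import pytest
from hypothesis import given, strategies as st

import multisyn as m
from multisyn.synergy import (
    DoseResponseSeries,
    MedianEffectFit,
    analyze_plates,
    best_ic50,
    categorize_ci,
    combination_index,
    dose_for_effect,
    fit_median_effect,
    ratio_scheme,
    relative_potency,
)


def median_effect_fa(doses, dm, slope):
    """fa from the median-effect equation fa/fu = (D/Dm)^m."""
    r = (np.asarray(doses) / dm) ** slope
    return r / (1 + r)


def series_from(dm, slope, n=8, ratio=None):
    """Exact median-effect points at effect levels 0.05..0.95 (inside the clip band)."""
    fa = np.linspace(0.05, 0.95, n)
    doses = dm * (fa / (1 - fa)) ** (1 / slope)
    return DoseResponseSeries(doses=doses, fraction_affected=fa, ratio=ratio)


class TestMedianEffectFit:
    def test_exact_recovery_dm2_m1(self):
        fit = fit_median_effect(series_from(2.0, 1.0))
        assert fit.dm == pytest.approx(2.0, abs=1e-9)
        assert fit.m == pytest.approx(1.0, abs=1e-9)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-12)

    def test_ic50_is_dose_of_half_effect(self):
        fit = fit_median_effect(series_from(5.0, 2.0))
        assert median_effect_fa([fit.ic50], 5.0, 2.0)[0] == pytest.approx(0.5, abs=1e-9)

    @given(st.floats(0.05, 500.0), st.floats(0.3, 4.0))
    def test_noise_free_recovery_is_exact(self, dm, slope):
        fit = fit_median_effect(series_from(dm, slope))
        assert fit.dm == pytest.approx(dm, rel=1e-9)
        assert fit.m == pytest.approx(slope, rel=1e-9)

    def test_noisy_recovery_within_fifteen_percent(self):
        rng = np.random.default_rng(42)
        doses = 2.0 * 16.0 / 2.0 ** np.arange(8)
        fa = median_effect_fa(doses, 2.0, 1.5) * (1 + 0.05 * rng.normal(size=8))
        fit = fit_median_effect(DoseResponseSeries(doses=doses, fraction_affected=np.clip(fa, 0.001, 0.999)))
        assert fit.dm == pytest.approx(2.0, rel=0.15)

    def test_too_few_points_or_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            fit_median_effect(DoseResponseSeries(doses=[1.0, 2.0], fraction_affected=[0.3, 0.6]))
        with pytest.raises(ValueError):
            DoseResponseSeries(doses=[0.0, 1.0, 2.0], fraction_affected=[0.1, 0.3, 0.6])


class TestRatioScheme:
    def test_two_drug_grid(self):
        s = ratio_scheme(2)
        assert s.settings == ((1, 1), (2, 1), (1, 2)) and s.labels == ("I", "II", "III")

    def test_five_drug_sixth_setting(self):
        s = ratio_scheme(5)
        assert len(s.settings) == 6
        assert s.settings[5] == (1, 1, 1, 1, 2)

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_k_plus_one_settings_each_doubling_one_drug(self, k):
        s = ratio_scheme(k)
        assert len(s.settings) == k + 1
        assert s.settings[0] == tuple([1] * k)
        for i, setting in enumerate(s.settings[1:]):
            assert sorted(setting) == [1] * (k - 1) + [2]
            assert setting[i] == 2

    @pytest.mark.parametrize("k", [1, 6])
    def test_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            ratio_scheme(k)


class TestCombinationIndex:
    @given(st.floats(0.1, 100.0), st.floats(0.4, 3.0), st.floats(0.1, 0.9), st.integers(1, 4))
    def test_sham_combination_has_unit_ci(self, dm, slope, fa, parts):
        """A drug combined with itself at any ratio is exactly additive."""
        fit = MedianEffectFit(dm=dm, m=slope, r=1.0)
        combo = series_from(dm, slope, ratio={"d": float(parts)})
        res = combination_index({"d": fit}, combo, effect_level=fa)
        assert res.ci == pytest.approx(1.0, abs=1e-9)
        assert res.category == "additive"

    def test_direct_evaluation_of_the_ci_sum(self):
        # combo reaches fa=0.5 with each drug at 1/4 of its own half-effect dose
        fit_a = MedianEffectFit(dm=8.0, m=1.0, r=1.0)
        fit_b = MedianEffectFit(dm=8.0, m=1.0, r=1.0)
        combo = series_from(4.0, 1.0, ratio={"a": 1.0, "b": 1.0})  # total Dm 4 -> 2 each
        res = combination_index({"a": fit_a, "b": fit_b}, combo, effect_level=0.5)
        assert res.ci == pytest.approx(0.5, abs=1e-9)
        assert res.category == "synergy"

    @pytest.mark.parametrize(
        "ci,category",
        [(0.29, "strong-synergy"), (0.3, "synergy"), (0.89, "synergy"), (0.9, "additive"),
         (1.0, "additive"), (1.1, "additive"), (1.1000001, "antagonism"), (1.2, "antagonism")],
    )
    def test_category_boundaries(self, ci, category):
        assert categorize_ci(ci) == category

    def test_effect_level_must_be_open_unit_interval(self):
        fit = MedianEffectFit(dm=1.0, m=1.0, r=1.0)
        combo = series_from(1.0, 1.0, ratio={"d": 1.0})
        with pytest.raises(ValueError):
            combination_index({"d": fit}, combo, effect_level=1.0)

    def test_dose_for_effect_closed_form(self):
        fit = MedianEffectFit(dm=3.0, m=2.0, r=1.0)
        assert dose_for_effect(fit, 0.5) == pytest.approx(3.0)
        assert dose_for_effect(fit, 0.8) == pytest.approx(3.0 * 4.0**0.5)


class TestBestIc50:
    def test_reported_three_drug_minimum(self):
        value, label = best_ic50([("I", 90.43), ("II", 31.37), ("III", 30.88), ("IV", 42.94)])
        assert (value, label) == (30.88, "III")

    def test_reported_four_drug_minimum(self):
        value, label = best_ic50([("I", 177.0), ("II", 52.0), ("III", 139.0), ("IV", 2152.0), ("V", 167.0)])
        assert (value, label) == (52.0, "II")

    def test_single_entry_returns_itself(self):
        assert best_ic50([("I", 7.0)]) == (7.0, "I")

    @given(st.lists(st.floats(0.01, 1e5), min_size=1, max_size=8), st.integers(0, 1000))
    def test_minimum_invariant_under_permutation(self, values, seed):
        entries = [(f"L{i}", v) for i, v in enumerate(values)]
        rng = np.random.default_rng(seed)
        shuffled = [entries[i] for i in rng.permutation(len(entries))]
        assert best_ic50(entries)[0] == best_ic50(shuffled)[0] == min(values)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            best_ic50([])
        with pytest.raises(ValueError):
            best_ic50([("I", -2.0)])


class TestRelativePotency:
    @pytest.mark.parametrize("ref,comp,percent", [(115.5, 207.6, 55.6), (115.5, 774.2, 14.9)])
    def test_reported_percentages(self, ref, comp, percent):
        assert relative_potency(ref, comp)[0] == percent

    def test_equal_inputs(self):
        assert relative_potency(3.0, 3.0) == (100.0, 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_potency(0.0, 1.0)


class TestPlateAnalysis:
    def test_noise_free_plate_recovers_true_ic50(self, tiny_world):
        w = tiny_world
        cell = w.cell_lines[0]
        combos = m.enumerate_combinations(w.drugs[:3], 2, 2)
        plate = m.generate_plate_table(w, cell, combos, n_replicates=1, viability_noise_sd=0.0)
        result = analyze_plates(plate)
        for _, row in result.iterrows():
            drugs = row["combination_id"].split("+")
            expected = float(np.exp(w.truth.true_log_ic50(cell, drugs)))
            assert row["ic50"] == pytest.approx(expected, rel=1e-6)

    def test_synergistic_combination_has_low_ci(self, tiny_world):
        """A pair covering complementary active pathways beats additivity."""
        w = tiny_world
        truth = w.truth
        # find a cell and pair with strictly better combo truth than both singles
        found = None
        for cell in w.cell_lines:
            for combo in m.enumerate_combinations(w.drugs, 2, 2):
                a, b = sorted(combo.drugs)
                t_ab = truth.true_log_ic50(cell, [a, b])
                if t_ab < min(truth.true_log_ic50(cell, [a]), truth.true_log_ic50(cell, [b])) - 0.9:
                    found = (cell, combo)
                    break
            if found:
                break
        assert found, "world should contain a synergistic pair"
        cell, combo = found
        plate = m.generate_plate_table(w, cell, [combo], n_replicates=1, viability_noise_sd=0.0)
        result = analyze_plates(plate, effect_level=0.5)
        ci = result.loc[result["combination_id"] == combo.canonical_id, "ci"].iloc[0]
        assert ci < 0.9

    def test_noisy_sham_ci_close_to_one(self):
        # triplicate wells with 5% multiplicative noise, fa averaged before fitting
        rng = np.random.default_rng(5)
        fa_true = np.linspace(0.08, 0.92, 8)
        doses = 3.0 * (fa_true / (1 - fa_true)) ** (1 / 1.5)

        def noisy():
            reps = fa_true * (1 + 0.05 * rng.normal(size=(3, 8)))
            fa = np.clip(reps.mean(axis=0), 0.001, 0.999)
            return DoseResponseSeries(doses=doses, fraction_affected=fa, ratio={"d": 2.0})

        single = fit_median_effect(noisy())
        res = combination_index({"d": single}, noisy(), effect_level=0.5)
        assert res.ci == pytest.approx(1.0, abs=0.05)

    def test_mixed_units_refused(self, tiny_world):
        w = tiny_world
        plate = m.generate_plate_table(w, w.cell_lines[0], m.enumerate_combinations(w.drugs[:2], 2, 2),
                                       n_replicates=1)
        plate.loc[plate.index[-1], "unit"] = "nM"
        with pytest.raises(ValueError, match="mixed"):
            analyze_plates(plate)
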