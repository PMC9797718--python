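"""Feature-space construction for cell-line x drug-combination modeling.

A modeling sample concatenates two blocks:

* an expression block — the cell line's expression values over a fixed,
  ordered gene panel (cancer-pathway genes), and
* a target block — a binary fingerprint over a fixed, ordered universe of
  drug targets, with 1 at every target hit by any member of the drug set.

The layout is frozen in a :class:`FeatureSchema` so that models trained on
monotherapy samples can score arbitrary multi-drug combinations: the target
fingerprint of a combination is the element-wise OR (set union) of its
member drugs' fingerprints, while the expression block is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureSchema",
    "CombinationSpec",
    "LabelConfig",
    "Sample",
    "SampleSet",
    "AssemblyReport",
    "PanelReport",
    "select_gene_panel",
    "encode_combination",
    "assemble_samples",
    "build_combination_matrix",
    "FeatureStandardizer",
    "split_dataset",
]

# concentration unit -> nM multiplier
_UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


def _to_nm(value: float, unit: str) -> float:
    try:
        return value * _UNIT_TO_NM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; known: {sorted(_UNIT_TO_NM)}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered gene panel plus ordered target universe fixing the vector layout."""

    gene_panel: tuple[str, ...]
    target_universe: tuple[str, ...]

    def __init__(self, gene_panel: Sequence[str], target_universe: Sequence[str]):
        gene_panel = tuple(gene_panel)
        target_universe = tuple(target_universe)
        if not gene_panel or not target_universe:
            raise ValueError("gene_panel and target_universe must be non-empty")
        for name, lst in (("gene_panel", gene_panel), ("target_universe", target_universe)):
            if len(set(lst)) != len(lst):
                dupes = sorted({x for x in lst if list(lst).count(x) > 1})
                raise ValueError(f"duplicate identifiers in {name}: {dupes[:5]}")
        object.__setattr__(self, "gene_panel", gene_panel)
        object.__setattr__(self, "target_universe", target_universe)

    @property
    def n_genes(self) -> int:
        return len(self.gene_panel)

    @property
    def n_targets(self) -> int:
        return len(self.target_universe)

    @property
    def feature_dim(self) -> int:
        return self.n_genes + self.n_targets

    @property
    def feature_names(self) -> list[str]:
        return [f"expr:{g}" for g in self.gene_panel] + [f"target:{t}" for t in self.target_universe]

    def target_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.target_universe)}


@dataclass(frozen=True)
class CombinationSpec:
    """A set of drugs with an order-independent canonical identifier."""

    drugs: frozenset[str]

    def __init__(self, drugs: Iterable[str]):
        drugs = frozenset(drugs)
        if not drugs:
            raise ValueError("a combination must contain at least one drug")
        object.__setattr__(self, "drugs", drugs)

    @property
    def canonical_id(self) -> str:
        return "+".join(sorted(self.drugs))

    @property
    def size(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(sorted(self.drugs))


@dataclass(frozen=True)
class LabelConfig:
    """How raw IC50 measurements become regression and classification labels.

    ``scale`` sets the regression label: ``ln_uM`` is the natural log of the
    IC50 expressed in micromolar (the GDSC release convention), ``log10_nM``
    the base-10 log in nanomolar, ``raw`` the untransformed value in
    nanomolar.  ``threshold``/``threshold_unit`` define the positive class:
    label 1 iff IC50 <= threshold.
    """

    scale: str = "ln_uM"
    threshold: float = 10.0
    threshold_unit: str = "nM"

    def __post_init__(self):
        if self.scale not in ("ln_uM", "log10_nM", "raw"):
            raise ValueError(f"unknown label scale {self.scale!r}")
        if self.threshold <= 0:
            raise ValueError("classification threshold must be positive")

    def regression_label(self, ic50: float, unit: str) -> float:
        nm = _to_nm(ic50, unit)
        if self.scale == "ln_uM":
            return float(np.log(nm / 1e3))
        if self.scale == "log10_nM":
            return float(np.log10(nm))
        return float(nm)

    def class_label(self, ic50: float, unit: str) -> int:
        return int(_to_nm(ic50, unit) <= _to_nm(self.threshold, self.threshold_unit))


@dataclass(frozen=True)
class Sample:
    cell_line_id: str
    combination: CombinationSpec
    features: np.ndarray
    label_regression: float
    label_class: int


@dataclass
class SampleSet:
    """Column-oriented collection of modeling samples (rows align across fields)."""

    X: np.ndarray
    y_regression: np.ndarray
    y_class: np.ndarray
    cell_line_ids: np.ndarray
    combination_ids: np.ndarray
    schema: FeatureSchema

    def __len__(self) -> int:
        return self.X.shape[0]

    def __getitem__(self, i: int) -> Sample:
        return Sample(
            cell_line_id=str(self.cell_line_ids[i]),
            combination=CombinationSpec(self.combination_ids[i].split("+")),
            features=self.X[i],
            label_regression=float(self.y_regression[i]),
            label_class=int(self.y_class[i]),
        )

    def subset(self, indices: np.ndarray) -> "SampleSet":
        return SampleSet(
            X=self.X[indices],
            y_regression=self.y_regression[indices],
            y_class=self.y_class[indices],
            cell_line_ids=self.cell_line_ids[indices],
            combination_ids=self.combination_ids[indices],
            schema=self.schema,
        )


@dataclass
class PanelReport:
    missing_genes: list[str]
    collapsed_duplicates: list[str]


def select_gene_panel(
    expression_matrix: pd.DataFrame, panel: Sequence[str]
) -> tuple[pd.DataFrame, PanelReport]:
    """Restrict a gene x cell-line matrix to a gene panel, in panel order.

    Duplicate rows for the same gene (multiple probes) are collapsed by
    arithmetic mean.  Panel genes absent from the matrix are dropped and
    reported.  Raises if the intersection is empty.
    """
    if len(panel) == 0:
        raise ValueError("gene panel must be non-empty")
    dupes = sorted(expression_matrix.index[expression_matrix.index.duplicated()].unique())
    mat = expression_matrix.groupby(level=0, sort=False).mean() if dupes else expression_matrix
    present = [g for g in panel if g in mat.index]
    missing = [g for g in panel if g not in mat.index]
    if not present:
        raise ValueError(f"no panel genes found in expression matrix; first missing: {missing[:5]}")
    restricted = mat.loc[present]
    return restricted, PanelReport(missing_genes=missing, collapsed_duplicates=[str(d) for d in dupes])


def encode_combination(
    combo: CombinationSpec,
    target_map: Mapping[str, frozenset[str] | set[str]],
    schema: FeatureSchema,
) -> np.ndarray:
    """Binary fingerprint over the target universe: 1 at the union of member targets."""
    idx = schema.target_index()
    vec = np.zeros(schema.n_targets, dtype=float)
    for drug in combo.drugs:
        if drug not in target_map:
            raise KeyError(f"drug {drug!r} not present in the drug-target map")
        targets = target_map[drug]
        if not targets:
            warnings.warn(f"drug {drug!r} has an empty target set; contributes zeros", stacklevel=2)
        for t in targets:
            if t in idx:  # targets outside the universe are ignored by schema restriction
                vec[idx[t]] = 1.0
    return vec


@dataclass
class AssemblyReport:
    n_samples: int
    n_rejected: int
    rejected_rows: list[int] = field(default_factory=list)


def assemble_samples(
    profiles: Mapping[str, Mapping[str, float]],
    target_map: Mapping[str, frozenset[str] | set[str]],
    responses: pd.DataFrame,
    schema: FeatureSchema,
    label_config: LabelConfig | None = None,
) -> tuple[SampleSet, AssemblyReport]:
    """Build one sample per monotherapy response row.

    ``profiles`` maps cell-line id -> {gene symbol: expression}; ``responses``
    needs columns drug_id, cell_line_id, ic50, unit.  Rows with missing or
    non-positive IC50 are skipped and counted in the report.
    """
    label_config = label_config or LabelConfig()
    expr_cache: dict[str, np.ndarray] = {}
    fp_cache: dict[str, np.ndarray] = {}
    rows, y_reg, y_cls, cells, combos, rejected = [], [], [], [], [], []
    for i, rec in enumerate(responses.itertuples(index=False)):
        ic50 = getattr(rec, "ic50")
        if ic50 is None or not np.isfinite(ic50) or ic50 <= 0:
            rejected.append(i)
            continue
        cell = str(getattr(rec, "cell_line_id"))
        drug = str(getattr(rec, "drug_id"))
        unit = str(getattr(rec, "unit", "nM"))
        if cell not in profiles:
            raise KeyError(f"response row {i} references unknown cell line {cell!r}")
        if cell not in expr_cache:
            prof = profiles[cell]
            try:
                expr_cache[cell] = np.array([float(prof[g]) for g in schema.gene_panel])
            except KeyError as e:
                raise KeyError(f"cell line {cell!r} lacks expression for panel gene {e}") from None
        if drug not in fp_cache:
            fp_cache[drug] = encode_combination(CombinationSpec([drug]), target_map, schema)
        rows.append(np.concatenate([expr_cache[cell], fp_cache[drug]]))
        y_reg.append(label_config.regression_label(float(ic50), unit))
        y_cls.append(label_config.class_label(float(ic50), unit))
        cells.append(cell)
        combos.append(drug)
    if not rows:
        raise ValueError("no valid response rows to assemble")
    sset = SampleSet(
        X=np.vstack(rows),
        y_regression=np.array(y_reg, dtype=float),
        y_class=np.array(y_cls, dtype=int),
        cell_line_ids=np.array(cells, dtype=object),
        combination_ids=np.array(combos, dtype=object),
        schema=schema,
    )
    return sset, AssemblyReport(n_samples=len(rows), n_rejected=len(rejected), rejected_rows=rejected)


def build_combination_matrix(
    cell_expression: Mapping[str, float],
    combos: Sequence[CombinationSpec],
    target_map: Mapping[str, frozenset[str] | set[str]],
    schema: FeatureSchema,
) -> np.ndarray:
    """Feature matrix for scoring combinations in one cell line (rows align with combos)."""
    expr = np.array([float(cell_expression[g]) for g in schema.gene_panel])
    return np.vstack([np.concatenate([expr, encode_combination(c, target_map, schema)]) for c in combos])


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Zero-center and unit-scale features using training-split statistics only.

    Uses the population standard deviation.  Constant columns (sd = 0) are
    flagged and transformed to exactly 0; ``inverse_transform`` restores
    their training mean.
    """

    def fit(self, X: np.ndarray, y=None) -> "FeatureStandardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer requires a 2-D matrix with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)  # ddof=0
        self.constant_mask_ = sd == 0
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Z = (X - self.mean_) / self.scale_
        Z[:, self.constant_mask_] = 0.0
        return Z

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_

    def transform_samples(self, samples: SampleSet) -> SampleSet:
        out = samples.subset(np.arange(len(samples)))
        out.X = self.transform(samples.X)
        return out


def split_dataset(samples: SampleSet, train_fraction: float, seed: int) -> tuple[SampleSet, SampleSet]:
    """Random disjoint/exhaustive train-test split, deterministic for a fixed seed.

    The training size is round-half-up of ``train_fraction * n``; the
    remainder goes to test.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = split_sizes(n, train_fraction)[0]
    perm = np.random.default_rng(seed).permutation(n)
    return samples.subset(np.sort(perm[:n_train])), samples.subset(np.sort(perm[n_train:]))


def split_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """(train, test) sizes under round-half-up on the training count."""
    n_train = int(np.floor(n * train_fraction + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    return n_train, n - n_train
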