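"""Dose-response analysis: median-effect fits, IC50, and the combination index.

The median-effect model states fa/fu = (D/Dm)^m for dose D, fraction
affected fa (= 1 - viability fraction), fraction unaffected fu = 1 - fa,
median-effect dose Dm (the IC50) and slope m.  Linearizing,

    log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm),

so (Dm, m) come from a least-squares line.  A fixed-ratio combination is
fitted as a single pseudo-agent on its total dose; at a chosen effect
level the total dose is decomposed into per-drug doses by the molar-ratio
shares and compared with each drug's own dose for that effect, giving the
mutually-exclusive combination index

    CI = sum_i d_i / Dx_i,   Dx_i = Dm_i * (fa/(1-fa))^(1/m_i).

CI < 0.9 is synergy (< 0.3 strong synergy), 0.9-1.1 additive, > 1.1
antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponseSeries",
    "MedianEffectFit",
    "RatioScheme",
    "CIResult",
    "fit_median_effect",
    "dose_for_effect",
    "ratio_scheme",
    "combination_index",
    "categorize_ci",
    "best_ic50",
    "relative_potency",
    "plates_to_series",
    "analyze_plates",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
FA_CLIP = (0.005, 0.995)  # keeps the logit finite on 0%/100% viability wells


@dataclass(frozen=True)
class DoseResponseSeries:
    """One dose-effect curve; for combinations, total dose plus the ratio shares."""

    doses: np.ndarray
    fraction_affected: np.ndarray
    ratio: dict[str, float] | None = None  # drug -> parts of the total dose
    unit: str = "nM"

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fraction_affected, dtype=float)
        if doses.shape != fa.shape:
            raise ValueError("doses and fraction_affected must align")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fraction_affected", fa)

    @property
    def shares(self) -> dict[str, float]:
        if self.ratio is None:
            raise ValueError("series has no ratio vector")
        total = sum(self.ratio.values())
        return {d: p / total for d, p in self.ratio.items()}


@dataclass(frozen=True)
class MedianEffectFit:
    """Dm (median-effect dose = IC50), slope m, and |r| of the linearized fit."""

    dm: float
    m: float
    r: float
    unit: str = "nM"

    @property
    def ic50(self) -> float:
        return self.dm


def fit_median_effect(series: DoseResponseSeries) -> MedianEffectFit:
    """Least-squares median-effect fit of log10(fa/fu) on log10(dose)."""
    if len(series.doses) < 3:
        raise ValueError("median-effect fit needs at least 3 dose points")
    fa = np.clip(series.fraction_affected, *FA_CLIP)
    y = np.log10(fa / (1.0 - fa))
    x = np.log10(series.doses)
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError(f"non-positive median-effect slope ({m:.3g}); curve is not inhibitory")
    dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(dm=dm, m=m, r=float(res.rvalue), unit=series.unit)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected ``fa``: Dx = Dm * (fa/(1-fa))^(1/m)."""
    if not 0 < fa < 1:
        raise ValueError("effect level must be in (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


@dataclass(frozen=True)
class RatioScheme:
    """The molar-ratio settings tested per combination size.

    For k drugs there are k+1 settings: the first is all ones, then each
    subsequent setting doubles one drug's part in turn.
    """

    k: int
    settings: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...]

    def as_dict(self) -> dict[str, tuple[int, ...]]:
        return dict(zip(self.labels, self.settings))


def ratio_scheme(k: int) -> RatioScheme:
    if not 2 <= k <= 5:
        raise ValueError("ratio schemes are defined for 2-5 drugs")
    settings = [tuple([1] * k)]
    for i in range(k):
        s = [1] * k
        s[i] = 2
        settings.append(tuple(s))
    return RatioScheme(k=k, settings=tuple(settings), labels=tuple(_ROMAN[: k + 1]))


def categorize_ci(ci: float) -> str:
    if ci < 0.3:
        return "strong-synergy"
    if ci < 0.9:
        return "synergy"
    if ci <= 1.1:
        return "additive"
    return "antagonism"


@dataclass(frozen=True)
class CIResult:
    ci: float
    category: str
    effect_level: float


def combination_index(
    single_fits: Mapping[str, MedianEffectFit],
    combo_series: DoseResponseSeries,
    effect_level: float = 0.5,
    combo_fit: MedianEffectFit | None = None,
) -> CIResult:
    """Mutually-exclusive Chou-Talalay CI of a fixed-ratio combination.

    The combination is fitted as one pseudo-agent on total dose (pass
    ``combo_fit`` to reuse an existing fit); the total dose achieving
    ``effect_level`` is split by the molar-ratio shares and each part is
    divided by the member drug's own dose for that effect.
    """
    if not 0 < effect_level < 1:
        raise ValueError("effect level must be in (0, 1)")
    shares = combo_series.shares
    missing = sorted(set(shares) - set(single_fits))
    if missing:
        raise KeyError(f"no single-drug fit for {missing}")
    fit = combo_fit if combo_fit is not None else fit_median_effect(combo_series)
    dc = dose_for_effect(fit, effect_level)
    ci = 0.0
    for drug, share in shares.items():
        ci += dc * share / dose_for_effect(single_fits[drug], effect_level)
    return CIResult(ci=float(ci), category=categorize_ci(float(ci)), effect_level=effect_level)


def best_ic50(per_ratio_ic50s: Sequence[tuple[str, float]]) -> tuple[float, str]:
    """Minimum IC50 across ratio settings and its label; ties go to the first label."""
    if len(per_ratio_ic50s) == 0:
        raise ValueError("no IC50 values supplied")
    for label, v in per_ratio_ic50s:
        if v <= 0:
            raise ValueError(f"non-positive IC50 for {label}")
    best_label, best_value = min(per_ratio_ic50s, key=lambda lv: lv[1])
    return float(best_value), best_label


def relative_potency(reference_ic50: float, comparator_ic50: float) -> tuple[float, float]:
    """(percent of comparator, fold-change): how much more potent the reference is."""
    if reference_ic50 <= 0 or comparator_ic50 <= 0:
        raise ValueError("IC50 values must be positive")
    percent = round(100.0 * reference_ic50 / comparator_ic50, 1)
    fold = comparator_ic50 / reference_ic50
    return percent, fold


# -- plate tables ------------------------------------------------------------

def plates_to_series(plate: pd.DataFrame) -> dict[tuple[str, str], DoseResponseSeries]:
    """Collapse a long-format viability plate into dose-response series.

    Expected columns: combination_id, ratio_label, drug_id, dose, unit,
    viability_fraction, replicate.  Within one (combination, ratio,
    replicate) the rows of each dilution step carry one row per member drug;
    steps are aligned per drug by descending dose.  Control wells have dose
    0 and normalize viability; fa per total dose is averaged over
    replicates before fitting.  Mixed dose units are refused.
    """
    required = {"combination_id", "ratio_label", "drug_id", "dose", "unit", "viability_fraction"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    units = plate["unit"].unique()
    if len(units) > 1:
        raise ValueError(f"mixed dose units in one analysis: {sorted(units)}; convert first")
    unit = str(units[0])
    plate = plate.copy()
    if "replicate" not in plate.columns:
        plate["replicate"] = 0

    controls = plate[plate["dose"] == 0]
    control_level = float(controls["viability_fraction"].mean()) if len(controls) else 1.0
    dosed = plate[plate["dose"] > 0]

    out: dict[tuple[str, str], DoseResponseSeries] = {}
    for (combo_id, ratio_label), grp in dosed.groupby(["combination_id", "ratio_label"], sort=True):
        points: dict[float, list[float]] = {}
        ratio_parts: dict[str, float] = {}
        for _, rep_grp in grp.groupby("replicate"):
            per_drug = {
                drug: dg.sort_values("dose", ascending=False).reset_index(drop=True)
                for drug, dg in rep_grp.groupby("drug_id")
            }
            n_steps = {len(dg) for dg in per_drug.values()}
            if len(n_steps) != 1:
                raise ValueError(f"{combo_id}/{ratio_label}: unequal dilution steps across drugs")
            for step in range(n_steps.pop()):
                total = float(sum(dg["dose"].iloc[step] for dg in per_drug.values()))
                viab = float(np.mean([dg["viability_fraction"].iloc[step] for dg in per_drug.values()]))
                points.setdefault(round(total, 12), []).append(viab)
            top = {d: float(dg["dose"].iloc[0]) for d, dg in per_drug.items()}
            lo = min(top.values())
            ratio_parts = {d: v / lo for d, v in top.items()}
        totals = np.array(sorted(points))
        fa = np.array([1.0 - np.mean(points[t]) / control_level for t in sorted(points)])
        out[(str(combo_id), str(ratio_label))] = DoseResponseSeries(
            doses=totals, fraction_affected=fa, ratio=ratio_parts, unit=unit
        )
    if not out:
        raise ValueError("no dosed wells in plate table")
    return out


def analyze_plates(plate: pd.DataFrame, effect_level: float = 0.5) -> pd.DataFrame:
    """Full plate analysis: per (combination, ratio) IC50, CI and synergy category.

    Single agents (series whose ratio involves one drug) provide the
    reference fits; their CI is reported as NaN.  Returns one row per
    series with fit diagnostics (Dm, m, r).
    """
    series = plates_to_series(plate)
    fits = {key: fit_median_effect(s) for key, s in series.items()}
    single_fits: dict[str, MedianEffectFit] = {}
    for (combo_id, _), s in series.items():
        if s.ratio is not None and len(s.ratio) == 1:
            (drug,) = s.ratio
            single_fits[drug] = fits[(combo_id, _)]
    rows = []
    for key, s in sorted(series.items()):
        fit = fits[key]
        ci_val, category = float("nan"), ""
        if s.ratio is not None and len(s.ratio) > 1:
            res = combination_index(single_fits, s, effect_level=effect_level, combo_fit=fit)
            ci_val, category = res.ci, res.category
        rows.append(
            {
                "combination_id": key[0],
                "ratio_label": key[1],
                "ic50": fit.ic50,
                "ci": ci_val,
                "category": category,
                "dm": fit.dm,
                "m": fit.m,
                "r": fit.r,
                "unit": fit.unit,
            }
        )
    return pd.DataFrame(rows)
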