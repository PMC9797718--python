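"""Seeded synthetic world with known ground truth for end-to-end testing.

The world mimics the structure the pipeline consumes: cell lines with
pathway-organized expression (genes of an active pathway are elevated),
drugs with sparse target sets, and log-scale IC50 responses that improve
with the number of active pathways a drug set covers.  Synergy is
complementary pathway coverage: the true log-IC50 of a drug set is

    alpha - beta * A - gamma * max(0, C - 1) + noise,

where C is the number of distinct pathways covered by the union of the
set's targets and A is how many of those are active in the cell line.  A
sham "combination" of a drug with itself therefore has exactly the single
drug's truth, and adding a drug that covers a new active pathway strictly
lowers the truth.

Each pathway exposes one canonical druggable "hub" target; a drug that
modulates a pathway hits its hub (plus, optionally, idiosyncratic
secondary targets that carry no signal of their own).  Pathway coverage is
therefore identifiable from the binary target fingerprint, which is what
makes monotherapy-trained models informative about unseen combinations —
the response surface is a function of observable features rather than of
latent per-drug effects.  Dose-response plates are drawn from the
median-effect equation around the true IC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CombinationSpec, FeatureSchema

__all__ = ["SimConfig", "GroundTruth", "World", "generate_world", "generate_responses", "generate_plate_table"]


@dataclass(frozen=True)
class SimConfig:
    """Reference desk-scale configuration for the synthetic world."""

    n_cell_lines: int = 20
    n_genes: int = 100
    n_targets: int = 60
    n_drugs: int = 10
    n_pathways: int = 6
    pathways_per_drug: tuple[int, int] = (1, 3)
    secondary_target_prob: float = 0.0
    pathway_active_prob: float = 0.5
    expression_base: float = 5.0
    expression_effect: float = 2.0
    expression_noise_sd: float = 0.5
    alpha: float = 3.0  # baseline ln IC50 (uM) with no covered active pathway
    beta: float = 1.0  # ln-IC50 drop per covered active pathway
    gamma: float = 0.5  # extra drop per additional distinct covered active pathway
    noise_sd: float = 0.1
    hill_slope: float = 1.5  # median-effect slope for simulated plates
    n_dose_points: int = 8
    seed: int = 1

    def __post_init__(self):
        counts = (self.n_cell_lines, self.n_genes, self.n_targets, self.n_drugs, self.n_pathways)
        if min(counts) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("noise_sd, beta and gamma must be non-negative")
        lo, hi = self.pathways_per_drug
        if not 1 <= lo <= hi <= self.n_pathways:
            raise ValueError("pathways_per_drug must be an increasing range within n_pathways")
        if self.n_targets < self.n_pathways or self.n_targets < hi:
            raise ValueError("n_targets must provide at least one hub target per pathway")


@dataclass(frozen=True)
class GroundTruth:
    """Deterministic truth underlying a generated world."""

    gene_pathway: np.ndarray  # pathway index per gene
    target_pathway: np.ndarray  # pathway index per target
    pathway_active: pd.DataFrame  # cell line x pathway booleans
    target_ids: tuple[str, ...]
    target_map: dict[str, frozenset[str]]
    alpha: float
    beta: float
    gamma: float

    def covered_pathways(self, drugs: Iterable[str]) -> frozenset[int]:
        t_index = {t: i for i, t in enumerate(self.target_ids)}
        return frozenset(
            int(self.target_pathway[t_index[t]]) for d in set(drugs) for t in self.target_map[d]
        )

    def covered_active(self, cell_line_id: str, drugs: Iterable[str]) -> int:
        active = set(np.where(self.pathway_active.loc[cell_line_id].to_numpy())[0])
        return len(self.covered_pathways(drugs) & active)

    def true_log_ic50(self, cell_line_id: str, drugs: Iterable[str]) -> float:
        a = self.covered_active(cell_line_id, drugs)
        c = len(self.covered_pathways(drugs))
        return self.alpha - self.beta * a - self.gamma * max(0, c - 1)


@dataclass
class World:
    config: SimConfig
    expression: pd.DataFrame  # genes x cell lines
    target_map: dict[str, frozenset[str]]
    schema: FeatureSchema
    truth: GroundTruth
    pathway_gene_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.target_map)

    def profiles(self) -> dict[str, dict[str, float]]:
        return {c: self.expression[c].to_dict() for c in self.expression.columns}


def generate_world(config: SimConfig | None = None, **overrides) -> World:
    """Build the seeded toy world (expression, drug targets, ground truth)."""
    config = replace(config or SimConfig(), **overrides) if overrides else (config or SimConfig())
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    targets = [f"T{i:03d}" for i in range(config.n_targets)]
    drugs = [f"D{i:02d}" for i in range(config.n_drugs)]
    cells = [f"CL{i:02d}" for i in range(config.n_cell_lines)]

    # round-robin so every pathway owns genes and targets
    gene_pathway = np.arange(config.n_genes) % config.n_pathways
    target_pathway = np.arange(config.n_targets) % config.n_pathways

    active = rng.random((config.n_cell_lines, config.n_pathways)) < config.pathway_active_prob
    pathway_active = pd.DataFrame(active, index=cells, columns=range(config.n_pathways))

    expr = config.expression_base + rng.normal(
        0.0, config.expression_noise_sd, size=(config.n_genes, config.n_cell_lines)
    )
    for p in range(config.n_pathways):
        member = gene_pathway == p
        expr[np.ix_(member, active[:, p])] += config.expression_effect
    expression = pd.DataFrame(expr, index=genes, columns=cells)

    lo, hi = config.pathways_per_drug
    by_pathway = {p: np.where(target_pathway == p)[0] for p in range(config.n_pathways)}
    hub = {p: int(by_pathway[p][0]) for p in range(config.n_pathways)}
    target_map: dict[str, frozenset[str]] = {}
    for d in drugs:
        n_pw = int(rng.integers(lo, hi + 1))
        pws = rng.choice(config.n_pathways, size=n_pw, replace=False)
        chosen = {hub[int(p)] for p in pws}
        for p in pws:
            if config.secondary_target_prob > 0 and rng.random() < config.secondary_target_prob:
                pool = [t for t in by_pathway[int(p)] if t not in chosen]
                if pool:
                    chosen.add(int(rng.choice(pool)))
        target_map[d] = frozenset(targets[t] for t in sorted(chosen))

    truth = GroundTruth(
        gene_pathway=gene_pathway,
        target_pathway=target_pathway,
        pathway_active=pathway_active,
        target_ids=tuple(targets),
        target_map=target_map,
        alpha=config.alpha,
        beta=config.beta,
        gamma=config.gamma,
    )
    gene_sets = {
        f"PATHWAY_{p}": frozenset(np.array(genes)[gene_pathway == p]) for p in range(config.n_pathways)
    }
    return World(
        config=config,
        expression=expression,
        target_map=target_map,
        schema=FeatureSchema(gene_panel=genes, target_universe=targets),
        truth=truth,
        pathway_gene_sets=gene_sets,
    )


def generate_responses(
    world: World,
    combos: Sequence[CombinationSpec] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(monotherapy table, combination truth table).

    The monotherapy table has the reader format (drug_id, cell_line_id,
    ic50, unit) with IC50 = exp(truth + noise) in micromolar; only these
    rows are "observed".  The truth table holds the noise-free combination
    log-IC50s for every requested combination, for evaluation only.
    """
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    rows = []
    for cell in world.cell_lines:
        for drug in world.drugs:
            mu = world.truth.true_log_ic50(cell, [drug])
            eps = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            rows.append(
                {"drug_id": drug, "cell_line_id": cell, "ic50": float(np.exp(mu + eps)), "unit": "uM"}
            )
    mono = pd.DataFrame(rows)

    truth_rows = []
    for combo in combos or []:
        for cell in world.cell_lines:
            truth_rows.append(
                {
                    "cell_line_id": cell,
                    "combination_id": combo.canonical_id,
                    "n_drugs": combo.size,
                    "true_log_ic50": world.truth.true_log_ic50(cell, combo.drugs),
                }
            )
    truth_df = pd.DataFrame(
        truth_rows, columns=["cell_line_id", "combination_id", "n_drugs", "true_log_ic50"]
    )
    return mono, truth_df


def generate_plate_table(
    world: World,
    cell_line_id: str,
    combos: Sequence[CombinationSpec],
    scheme_settings: Mapping[str, Sequence[float]] | None = None,
    n_replicates: int = 3,
    viability_noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format viability plate for the synergy lab, one row per drug well.

    Each (combination, ratio setting) gets an ``n_dose_points``-point
    two-fold dilution series of total dose bracketing the true IC50, with
    viability from the median-effect equation (slope ``hill_slope``) under
    multiplicative noise.  Member drugs of every combination are also
    plated singly so that combination indices can be computed.
    """
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if cell_line_id not in world.cell_lines:
        raise KeyError(f"unknown cell line {cell_line_id!r}")
    for combo in combos:
        unknown = combo.drugs - set(world.drugs)
        if unknown:
            raise KeyError(f"unknown drugs {sorted(unknown)}")

    singles = sorted({d for c in combos for d in c.drugs})
    jobs: list[tuple[CombinationSpec, str, tuple[float, ...]]] = []
    for d in singles:
        jobs.append((CombinationSpec([d]), "I", (1.0,)))
    for combo in combos:
        if combo.size == 1:
            continue
        if scheme_settings is None:
            from .synergy import ratio_scheme

            scheme = ratio_scheme(combo.size)
            settings = scheme.as_dict()
        else:
            settings = {k: tuple(v) for k, v in scheme_settings.items() if len(v) == combo.size}
        for label, parts in settings.items():
            jobs.append((combo, label, tuple(float(p) for p in parts)))

    rows = []
    for combo, label, parts in jobs:
        drugs = sorted(combo.drugs)
        dm = float(np.exp(world.truth.true_log_ic50(cell_line_id, combo.drugs)))
        shares = np.array(parts) / sum(parts)
        top = dm * 2 ** (cfg.n_dose_points // 2)
        totals = top / (2.0 ** np.arange(cfg.n_dose_points))
        for rep in range(n_replicates):
            for total in totals:
                fa = 1.0 / (1.0 + (dm / total) ** cfg.hill_slope)
                viability = 1.0 - fa
                if viability_noise_sd > 0:
                    viability *= 1.0 + rng.normal(0.0, viability_noise_sd)
                viability = float(np.clip(viability, 0.0, 1.0))
                for drug, share in zip(drugs, shares):
                    rows.append(
                        {
                            "combination_id": combo.canonical_id,
                            "ratio_label": label,
                            "drug_id": drug,
                            "dose": float(total * share),
                            "unit": "uM",
                            "viability_fraction": viability,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)
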