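"""Enumeration and per-cell-line ranking of candidate drug combinations.

A trained monotherapy model scores every candidate combination of a drug
pool for one cell line; the scores (pseudo-IC50, a log-scale model output
used only for ordering, never converted back to a concentration) are sorted
ascending so rank 1 is the predicted most potent set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CombinationSpec, FeatureSchema, FeatureStandardizer, build_combination_matrix

__all__ = ["RankingTable", "enumerate_combinations", "rank_combinations", "n_combinations"]


@dataclass
class RankingTable:
    """Ascending pseudo-IC50 ranking of combinations for one cell line."""

    cell_line_id: str
    table: pd.DataFrame  # columns: rank, combination_id, member_drugs, pseudo_ic50

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def rank_of(self, combo: CombinationSpec) -> int:
        row = self.table[self.table["combination_id"] == combo.canonical_id]
        if row.empty:
            raise KeyError(f"{combo.canonical_id} not in ranking")
        return int(row["rank"].iloc[0])


def enumerate_combinations(
    pool: Sequence[str],
    min_size: int = 2,
    max_size: int | None = None,
    include_singletons: bool = False,
) -> list[CombinationSpec]:
    """All drug subsets with sizes in [min_size, max_size], each exactly once.

    Singletons are appended when requested (the ranking universe then also
    contains the individual drugs themselves).
    """
    pool = list(dict.fromkeys(pool))
    if not pool:
        raise ValueError("drug pool is empty")
    max_size = len(pool) if max_size is None else max_size
    if not 1 <= min_size <= max_size <= len(pool):
        raise ValueError(f"need 1 <= min_size <= max_size <= {len(pool)}")
    combos = [
        CombinationSpec(c)
        for size in range(min_size, max_size + 1)
        for c in _combinations(sorted(pool), size)
    ]
    if include_singletons and min_size > 1:
        combos.extend(CombinationSpec([d]) for d in sorted(pool))
    return combos


def n_combinations(n_drugs: int, min_size: int, max_size: int) -> int:
    """Closed-form count of subsets with sizes in [min_size, max_size]."""
    from math import comb

    return sum(comb(n_drugs, k) for k in range(min_size, max_size + 1))


def rank_combinations(
    model,
    cell_line_id: str,
    cell_expression: Mapping[str, float],
    combos: Sequence[CombinationSpec],
    target_map: Mapping[str, frozenset[str] | set[str]],
    schema: FeatureSchema,
    standardizer: FeatureStandardizer,
) -> RankingTable:
    """Score every combination with the model and sort ascending by pseudo-IC50.

    Ties are broken by canonical combination id, so the table is a
    deterministic permutation of the input combinations regardless of their
    order.  Unknown drugs raise before any prediction is made.
    """
    for combo in combos:
        for drug in combo.drugs:
            if drug not in target_map:
                raise KeyError(f"drug {drug!r} in {combo.canonical_id} missing from target map")
    X = build_combination_matrix(cell_expression, combos, target_map, schema)
    scores = np.asarray(model.predict(standardizer.transform(X)), dtype=float).ravel()
    df = pd.DataFrame(
        {
            "combination_id": [c.canonical_id for c in combos],
            "member_drugs": [";".join(sorted(c.drugs)) for c in combos],
            "pseudo_ic50": scores,
        }
    )
    df = df.sort_values(["pseudo_ic50", "combination_id"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RankingTable(cell_line_id=cell_line_id, table=df)
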