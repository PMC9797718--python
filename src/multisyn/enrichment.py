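"""Over-representation analysis of drug-combination target genes.

One-sided hypergeometric test of a query gene set (typically the union of
a combination's target genes restricted to the cell line's feature genes)
against each set of a gene-set collection, over a fixed background
universe.  Raw p-values are compared with the cutoff (default 0.01);
Benjamini-Hochberg adjustment is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "overrepresentation"]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        universe = frozenset(universe)
        restricted = {}
        for name, members in sets.items():
            inside = frozenset(members) & universe
            if not inside:
                continue
            restricted[name] = inside
        if not restricted:
            raise ValueError("no gene set overlaps the universe")
        object.__setattr__(self, "sets", restricted)
        object.__setattr__(self, "universe", universe)


def overrepresentation(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric tail p per gene set, sorted ascending by p.

    Query genes outside the universe are dropped with a warning.  With
    ``adjust`` the significance call uses Benjamini-Hochberg adjusted
    p-values (reported in a ``p_adj`` column).
    """
    query = frozenset(query)
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped", stacklevel=2)
    query &= collection.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    M, N = len(collection.universe), len(query)
    rows = []
    for name, members in sorted(collection.sets.items()):
        K = len(members)
        overlap = len(query & members)
        # P(X >= overlap) for X ~ Hypergeom(M, K, N)
        p = float(hypergeom.sf(overlap - 1, M, K, N))
        rows.append(
            {
                "set": name,
                "universe_size": M,
                "set_size": K,
                "query_size": N,
                "overlap": overlap,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows).sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    if adjust:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df
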