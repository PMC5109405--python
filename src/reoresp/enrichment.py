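"""Hypergeometric (one-tailed Fisher) gene-set over-representation.

Given a query gene list and a named collection of gene sets over a
universe of N genes, the overlap k between the query (size n) and a set
(size K) is scored by the hypergeometric upper tail
P(X >= k | N, K, n), equivalently a one-sided Fisher exact test on the
2x2 overlap table, with BH adjustment across sets. The universe defaults
to the genes measured in the experiment intersected with the genes covered
by the collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .core import bh_adjust

__all__ = ["GeneSetCollection", "hypergeometric_enrichment"]


@dataclass
class GeneSetCollection:
    sets: dict  # name -> set of gene ids
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        self.sets = {name: set(members) & self.universe
                     for name, members in self.sets.items()}

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        sets = read_gmt(path)
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(sets, set(universe))

    def restrict_universe(self, genes) -> "GeneSetCollection":
        return GeneSetCollection(self.sets, self.universe & set(genes))


def read_gmt(path) -> dict:
    """Parse a GMT file (name, description, members...) into named sets."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def hypergeometric_enrichment(
    query,
    collection: GeneSetCollection,
    fdr_report_threshold: float = 0.2,
) -> pd.DataFrame:
    """Over-representation p-values of the query in every set.

    Rows (set_name, k, n, K, N, p, fdr, significant) sorted by p; the
    ``significant`` flag marks FDR <= ``fdr_report_threshold``.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    q = set(query) & universe
    if not q:
        warnings.warn("query has no genes in the universe; all p = 1")
    n = len(q)
    big_n = len(universe)
    rows = []
    for name, members in collection.sets.items():
        big_k = len(members)
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        rows.append({"set_name": name, "k": k, "n": n, "K": big_k, "N": big_n,
                     "p": min(1.0, p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["fdr"] <= fdr_report_threshold
        table = table.sort_values(["p", "set_name"]).reset_index(drop=True)
    return table
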