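"""Group-level differential expression by rank products, and list merging.

For two sample groups A and B, every (a, b) sample pair yields a per-gene
log-fold difference; genes are ranked within each comparison (rank 1 = most
up-regulated in A for the "up" statistic, symmetric for "down") and the
rank product is the geometric mean of a gene's ranks over all comparisons.
Significance comes from the permutation null in which ranks are assigned
uniformly at random within each comparison: exactly, by enumerating all
rank combinations for one gene when that is feasible, else by Monte Carlo
permutation with a pooled null. Benjamini-Hochberg adjustment is applied
per direction.

Two directed DE lists from independent datasets are compared by their
concordance score s/k (shared genes s of k with the same direction) under
a Binomial(k, 0.5) null, and merged by dropping direction-inconsistent
shared genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import DOWN, UP, ExpressionMatrix, bh_adjust
from .landscape import ConcordanceResult, binomial_upper_tail

__all__ = [
    "RankProductResult",
    "DirectedGeneList",
    "rank_product_de",
    "directed_list_from_result",
    "concordance_and_merge",
]

MAX_COMPARISONS = 200
EXACT_ENUM_LIMIT = 500_000  # enumerate G**n_comparisons null products up to here


@dataclass
class RankProductResult:
    table: pd.DataFrame  # index gene; rp_up, rp_down, p_up, p_down, fdr_up, fdr_down
    n_comparisons: int
    n_permutations: int
    method: str          # "exact" | "permutation"
    seed: int | None


@dataclass
class DirectedGeneList:
    """DE genes with an up/down direction (in group A relative to group B)."""

    directions: pd.Series  # gene -> UP | DOWN
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.directions.index.has_duplicates:
            raise ValueError("a gene may appear only once in a directed list")
        bad = set(self.directions) - {UP, DOWN}
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")

    @property
    def genes(self) -> set:
        return set(self.directions.index)

    def __len__(self) -> int:
        return len(self.directions)


def _rank_matrix(values: np.ndarray, pairs: list[tuple[int, int]], sign: float):
    """Per-comparison ranks of sign*(A - B) fold differences, descending
    (rank 1 = largest). Ties get average ranks."""
    ranks = np.empty((values.shape[0], len(pairs)))
    for c, (ia, ib) in enumerate(pairs):
        fold = sign * (values[:, ia] - values[:, ib])
        ranks[:, c] = rankdata(-fold, method="average")
    return ranks


def _null_log_rp_exact(n_genes: int, n_comp: int) -> np.ndarray:
    """All G**c log rank products of one gene under the uniform-rank null."""
    logs = np.log(np.arange(1, n_genes + 1, dtype=float))
    acc = np.zeros(1)
    for _ in range(n_comp):
        acc = (acc[:, None] + logs[None, :]).ravel()
    return acc


def rank_product_de(
    matrix: ExpressionMatrix,
    group_a_samples,
    group_b_samples,
    n_permutations: int = 100,
    alpha_fdr: float = 0.05,
    seed: int | None = 0,
    max_comparisons: int = MAX_COMPARISONS,
) -> RankProductResult:
    """Rank-product DE statistics for group A vs group B.

    All |A| x |B| pairwise comparisons are used when their number does not
    exceed ``max_comparisons``; otherwise a seeded random subset is drawn.
    """
    a = list(group_a_samples)
    b = list(group_b_samples)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per group")
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed if seed is not None else 0))
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    values = matrix.values.to_numpy(dtype=float)
    pairs = [(cols[x], cols[y]) for x in a for y in b]
    if len(pairs) > max_comparisons:
        keep = rng.choice(len(pairs), size=max_comparisons, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    n_comp = len(pairs)
    n_genes = values.shape[0]

    log_rp = {}
    for key, sign in (("up", 1.0), ("down", -1.0)):
        ranks = _rank_matrix(values, pairs, sign)
        log_rp[key] = np.log(ranks).sum(axis=1)

    if n_genes ** n_comp <= EXACT_ENUM_LIMIT:
        method = "exact"
        null = np.sort(_null_log_rp_exact(n_genes, n_comp))
        total = null.size
        p = {
            key: (np.searchsorted(null, log_rp[key] + 1e-9, side="right")) / total
            for key in log_rp
        }
    else:
        method = "permutation"
        null_chunks = []
        base = np.arange(1, n_genes + 1, dtype=float)
        for _ in range(n_permutations):
            acc = np.zeros(n_genes)
            for _ in range(n_comp):
                acc += np.log(rng.permutation(base))
            null_chunks.append(acc)
        null = np.sort(np.concatenate(null_chunks))
        total = null.size
        p = {
            key: (np.searchsorted(null, log_rp[key] + 1e-9, side="right") + 1)
            / (total + 1)
            for key in log_rp
        }

    table = pd.DataFrame(
        {
            "rp_up": np.exp(log_rp["up"] / n_comp),
            "rp_down": np.exp(log_rp["down"] / n_comp),
            "p_up": np.minimum(1.0, p["up"]),
            "p_down": np.minimum(1.0, p["down"]),
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    table["fdr_up"] = bh_adjust(table["p_up"].to_numpy())
    table["fdr_down"] = bh_adjust(table["p_down"].to_numpy())
    return RankProductResult(table, n_comp, n_permutations, method, seed)


def directed_list_from_result(
    result: RankProductResult, alpha_fdr: float = 0.05, source_label: str = ""
) -> DirectedGeneList:
    """Genes significant in either direction at the given BH FDR.

    A gene significant both ways (possible only at degenerate settings)
    takes the direction with the smaller rank product.
    """
    t = result.table
    sig_up = t["fdr_up"] <= alpha_fdr
    sig_down = t["fdr_down"] <= alpha_fdr
    directions = {}
    for gene in t.index[sig_up | sig_down]:
        if sig_up[gene] and sig_down[gene]:
            directions[gene] = UP if t.at[gene, "rp_up"] <= t.at[gene, "rp_down"] else DOWN
        else:
            directions[gene] = UP if sig_up[gene] else DOWN
    return DirectedGeneList(pd.Series(directions, dtype=object), source_label)


def concordance_and_merge(
    list_a: DirectedGeneList, list_b: DirectedGeneList
) -> tuple[ConcordanceResult, DirectedGeneList]:
    """Direction concordance of two DE lists and their consistent merge.

    k = shared genes, s = shared genes with equal direction; the merged
    list is the union minus the k - s direction-inconsistent genes.
    """
    shared = list_a.genes & list_b.genes
    k = len(shared)
    consistent = {g for g in shared if list_a.directions[g] == list_b.directions[g]}
    s = len(consistent)
    if k == 0:
        conc = ConcordanceResult(0, 0, None, 1.0, 0.0, defined=False)
    else:
        tail = binomial_upper_tail(s, k, 0.5)
        conc = ConcordanceResult(k, s, s / k, tail.p, tail.log10_p)
    merged = {}
    for g in list_a.genes - shared:
        merged[g] = list_a.directions[g]
    for g in list_b.genes - shared:
        merged[g] = list_b.directions[g]
    for g in consistent:
        merged[g] = list_a.directions[g]
    label = f"merge({list_a.source_label},{list_b.source_label})"
    return conc, DirectedGeneList(pd.Series(merged, dtype=object).sort_index(), label)
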