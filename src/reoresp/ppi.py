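"""Protein-protein interaction neighbourhood statistics.

Counts *direct* (distance-1) links from each gene of a query set to a
target set in an undirected simple PPI graph, reports the total and the
per-mapped-gene average, and compares two per-gene link-count
distributions with a two-sided Wilcoxon rank-sum test (exact by
enumeration for small samples, normal approximation with tie correction
otherwise).

Genes lying in both the query and the target set stay in the query (a gene
is never its own neighbour); an ``exclude_overlap`` flag removes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "PPIGraph",
    "InteractionStats",
    "RankSumResult",
    "load_ppi_edgelist",
    "map_to_network",
    "direct_link_stats",
    "compare_link_distributions",
]

EXACT_RANKSUM_LIMIT = 400  # enumerate assignments while n*m <= this


def PPIGraph(edges) -> nx.Graph:
    """Build an undirected simple graph from an iterable of gene pairs,
    dropping self-loops and collapsing duplicate/reversed edges."""
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(str(a), str(b))
    return g


def load_ppi_edgelist(path) -> nx.Graph:
    edges = pd.read_csv(path, sep="\t", header=None, comment="#",
                        usecols=[0, 1], dtype=str)
    return PPIGraph(edges.itertuples(index=False, name=None))


@dataclass
class InteractionStats:
    mapped_query: set
    per_gene_counts: pd.Series  # index mapped query gene -> links into target
    total_links: int
    average: float | None      # None when no query gene maps into the graph

    @property
    def defined(self) -> bool:
        return self.average is not None


def map_to_network(genes, graph: nx.Graph) -> set:
    """Genes of the list present as nodes of the PPI graph."""
    return set(genes) & set(graph.nodes)


def direct_link_stats(query, target, graph: nx.Graph) -> InteractionStats:
    """Direct link counts from each mapped query gene into the target set."""
    mapped = map_to_network(query, graph)
    target = set(target)
    counts = pd.Series(
        {g: sum(1 for nb in graph.neighbors(g) if nb in target) for g in sorted(mapped)},
        dtype=int,
    )
    total = int(counts.sum()) if len(counts) else 0
    average = total / len(mapped) if mapped else None
    return InteractionStats(mapped, counts, total, average)


@dataclass
class RankSumResult:
    p_value: float
    statistic: float  # rank sum of the first sample (midranks)
    method: str       # "exact" | "normal_approx"


def _exact_two_sided(x: np.ndarray, y: np.ndarray) -> RankSumResult:
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    n = len(x)
    w_obs = float(ranks[:n].sum())
    mu = ranks.sum() * n / len(pooled)
    dev = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return RankSumResult(hits / total, w_obs, "exact")


def compare_link_distributions(counts_a, counts_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two link-count samples."""
    x = np.asarray(list(counts_a), dtype=float)
    y = np.asarray(list(counts_b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size * y.size <= EXACT_RANKSUM_LIMIT:
        return _exact_two_sided(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    ranks = pd.Series(np.concatenate([x, y])).rank(method="average").to_numpy()
    w = float(ranks[: x.size].sum())
    return RankSumResult(float(res.pvalue), w, "normal_approx")


def export_bipartite_subgraph(query, target, graph: nx.Graph) -> list[tuple[str, str]]:
    """Plain edge list of the direct query-target links, for external
    visualisation."""
    query = set(query) & set(graph.nodes)
    target = set(target)
    edges = []
    for q in sorted(query):
        for nb in graph.neighbors(q):
            if nb in target:
                edges.append((q, nb))
    return edges
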