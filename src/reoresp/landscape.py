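"""Stable relative expression ordering (REO) landscape of normal tissue.

A gene pair (a, b) has a *stable* REO if expression(a) > expression(b)
strictly in (a fraction >= ``support_threshold`` of) every normal sample
considered, pooled across datasets over the intersection of their gene
universes. Because the order relation is invariant under any strictly
monotone per-platform transform, stable pairs mined on one platform are
comparable across platforms — the premise that makes individual-sample
differential expression calling possible without between-sample
normalisation.

Cross-set agreement of two landscapes is scored as the fraction of shared
(unordered) pairs with identical orientation and tested against a
Binomial(k, 0.5) null; for the pair counts that arise at genome scale the
upper-tail probability is computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .core import ExpressionMatrix

__all__ = [
    "StableREOSet",
    "BinomialTail",
    "ConcordanceResult",
    "find_stable_pairs",
    "cross_set_concordance",
    "binomial_upper_tail",
    "hoeffding_log10_bound",
]

# G^2 boolean work arrays; above this the pair landscape no longer fits a
# desk-scale memory contract (~10^8 pairs).
MAX_GENES = 10_000


@dataclass
class StableREOSet:
    """Directed gene pairs (hi, lo) with expression(hi) > expression(lo)
    in at least ``support_threshold`` of the contributing normal samples."""

    genes: list
    greater: np.ndarray  # bool (G, G); greater[i, j] == True <=> (gene_i, gene_j) stable
    support_threshold: float
    n_supporting_samples: int

    def __post_init__(self) -> None:
        g = np.asarray(self.greater, dtype=bool)
        if np.any(g & g.T):
            raise ValueError("antisymmetry violated: both orientations present")
        if g.diagonal().any():
            raise ValueError("self-pairs are not allowed")
        self.greater = g
        self._index = {gene: i for i, gene in enumerate(self.genes)}

    @property
    def gene_universe(self) -> set:
        return set(self.genes)

    @property
    def n_pairs(self) -> int:
        return int(self.greater.sum())

    @property
    def pairs(self) -> set:
        hi, lo = np.nonzero(self.greater)
        return {(self.genes[i], self.genes[j]) for i, j in zip(hi, lo)}

    def has_pair(self, hi, lo) -> bool:
        try:
            return bool(self.greater[self._index[hi], self._index[lo]])
        except KeyError:
            return False

    def restrict(self, genes) -> "StableREOSet":
        keep = [g for g in self.genes if g in set(genes)]
        idx = np.array([self._index[g] for g in keep], dtype=int)
        return StableREOSet(
            keep,
            self.greater[np.ix_(idx, idx)].copy(),
            self.support_threshold,
            self.n_supporting_samples,
        )

    def intersect(self, other: "StableREOSet") -> "StableREOSet":
        """Pairs stable (same orientation) in both sets, over the shared universe."""
        common = [g for g in self.genes if g in other._index]
        ia = np.array([self._index[g] for g in common], dtype=int)
        ib = np.array([other._index[g] for g in common], dtype=int)
        g = self.greater[np.ix_(ia, ia)] & other.greater[np.ix_(ib, ib)]
        return StableREOSet(
            common,
            g,
            min(self.support_threshold, other.support_threshold),
            self.n_supporting_samples + other.n_supporting_samples,
        )


@dataclass
class BinomialTail:
    """P(X >= s) for X ~ Binomial(k, p_e), with a log-domain value that
    stays informative when the probability underflows double precision."""

    p: float
    log10_p: float
    method: str  # "sf" | "log_exact" | "chernoff_bound"


@dataclass
class ConcordanceResult:
    k: int
    s: int
    score: float | None
    p_value: float
    log10_p_value: float
    p_e: float = 0.5
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "s": self.s,
            "score": self.score,
            "p_value": self.p_value,
            "log10_p_value": self.log10_p_value,
            "p_e": self.p_e,
            "defined": self.defined,
        }


def find_stable_pairs(
    matrices: list[ExpressionMatrix], support_threshold: float = 1.0
) -> StableREOSet:
    """Mine gene pairs whose strict ordering holds in >= ``support_threshold``
    of all pooled samples.

    Ties (exactly equal values within a sample) support neither orientation,
    so at threshold 1.0 a single tied sample disqualifies the pair.
    """
    if not 0.5 < support_threshold <= 1.0:
        raise ValueError(
            "support_threshold must be in (0.5, 1]; values <= 0.5 would allow "
            "both orientations of a pair"
        )
    if not matrices:
        raise ValueError("at least one expression matrix is required")
    genes = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        genes &= set(m.gene_ids)
    if not genes:
        raise ValueError("empty gene intersection across matrices")
    genes = sorted(genes)
    if len(genes) > MAX_GENES:
        raise ValueError(f"gene universe exceeds the configured cap of {MAX_GENES}")

    blocks = [m.values.loc[genes].to_numpy(dtype=float) for m in matrices]
    values = np.concatenate(blocks, axis=1)
    n_samples = values.shape[1]
    if n_samples < 1:
        raise ValueError("no samples provided")

    counts = np.zeros((len(genes), len(genes)), dtype=np.int32)
    for s in range(n_samples):
        v = values[:, s]
        counts += v[:, None] > v[None, :]
    greater = counts >= support_threshold * n_samples - 1e-9
    np.fill_diagonal(greater, False)
    # fractional thresholds can momentarily admit both orientations on
    # near-balanced pairs; keep the majority one only
    both = greater & greater.T
    if both.any():
        greater &= ~(both & (counts <= counts.T))
    return StableREOSet(genes, greater, support_threshold, n_samples)


def binomial_upper_tail(s: int, k: int, p_e: float) -> BinomialTail:
    """Upper-tail probability P(X >= s), X ~ Binomial(k, p_e).

    Uses ``scipy``'s survival function when it is representable; otherwise
    sums the pmf in log space (exact), falling back to a Chernoff
    (Kullback-Leibler) upper bound when the summation range is impractical.
    """
    s, k = int(s), int(k)
    if not 0 <= s <= k:
        raise ValueError("require 0 <= s <= k")
    if not 0.0 < p_e < 1.0:
        raise ValueError("p_e must be in (0, 1)")
    if s == 0:
        return BinomialTail(1.0, 0.0, "sf")
    p = float(binom.sf(s - 1, k, p_e))
    if p > 5e-300:
        return BinomialTail(p, math.log10(p), "sf")
    # deep in the upper tail the pmf terms decay geometrically with ratio
    # <= r0, so the sum can be truncated at double precision
    r0 = (k - s) / (s + 1) * p_e / (1 - p_e)
    if r0 < 1.0:
        m = int(math.ceil((-45.0 - math.log1p(-r0)) / math.log(r0))) if r0 > 0 else 1
        n_terms = min(k - s + 1, max(m, 8))
    else:
        n_terms = k - s + 1
    if n_terms <= 20_000_000:
        i = np.arange(s, s + n_terms, dtype=float)
        logpmf = (
            gammaln(k + 1)
            - gammaln(i + 1)
            - gammaln(k - i + 1)
            + i * math.log(p_e)
            + (k - i) * math.log1p(-p_e)
        )
        log_p = float(logsumexp(logpmf))
        return BinomialTail(math.exp(log_p), log_p / math.log(10), "log_exact")
    # Chernoff: P(X >= s) <= exp(-k * KL(s/k || p_e)) for s/k > p_e
    q = s / k
    kl = q * math.log(q / p_e) + (1 - q) * math.log((1 - q) / (1 - p_e))
    log_p = -k * kl
    return BinomialTail(math.exp(log_p), log_p / math.log(10), "chernoff_bound")


def hoeffding_log10_bound(s: int, k: int, p_e: float) -> float:
    """log10 of the Hoeffding bound on P(X >= s); valid for s/k >= p_e."""
    if k <= 0 or s / k < p_e:
        raise ValueError("Hoeffding bound requires s/k >= p_e")
    return -2.0 * k * (s / k - p_e) ** 2 / math.log(10)


def cross_set_concordance(set_a: StableREOSet, set_b: StableREOSet) -> ConcordanceResult:
    """Concordance of two REO landscapes over their shared unordered pairs.

    k counts unordered pairs present (either orientation) in both sets,
    s those with identical orientation; significance is the Binomial(k, 0.5)
    upper tail at s.
    """
    common = [g for g in set_a.genes if g in set_b._index]
    if common:
        ia = np.array([set_a._index[g] for g in common], dtype=int)
        ib = np.array([set_b._index[g] for g in common], dtype=int)
        a = set_a.greater[np.ix_(ia, ia)]
        b = set_b.greater[np.ix_(ib, ib)]
        in_a = a | a.T
        in_b = b | b.T
        shared = in_a & in_b
        k = int(shared.sum()) // 2
        s = int((a & b).sum())
    else:
        k = s = 0
    if k == 0:
        return ConcordanceResult(0, 0, None, 1.0, 0.0, defined=False)
    tail = binomial_upper_tail(s, k, 0.5)
    return ConcordanceResult(k, s, s / k, tail.p, tail.log10_p)
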