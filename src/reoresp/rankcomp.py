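"""Individual-sample differential expression calling from REO reversals.

For a disease sample, every stable pair that involves gene X and whose
ordering is reversed in that sample is evidence about X: a partner that is
normally below X but now above it supports downregulation of X, and a
partner normally above X but now below it supports upregulation. Whether
the up- and down-supporting reversal frequencies differ is tested with
Fisher's exact test on

    [[r_down, n_less - r_down],
     [r_up,   n_greater - r_up]]

where n_less / n_greater are the numbers of stable partners normally below
/ above X. P-values are Benjamini-Hochberg adjusted within the sample, the
direction is assigned by the larger reversal proportion, and a filtering
pass then re-tests each called gene after excluding reversal partners that
are themselves currently called, iterating to a fixed point so that calls
driven purely by other deregulated genes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import DOWN, NONE, UP, ExpressionMatrix, bh_adjust
from .landscape import StableREOSet

__all__ = [
    "ReversalTable",
    "SampleDECall",
    "reversal_counts",
    "fisher_exact_2x2",
    "call_de_single_sample",
    "filter_de_calls",
    "run_rankcomp",
    "calls_to_frame",
]

#: genes with fewer stable partners than this are reported as untestable
MIN_PARTNERS = 10


@dataclass
class ReversalTable:
    gene: str
    n_less: int      # stable partners x with gene > x in normal
    r_down: int      # of those, reversed in the sample (supports DOWN)
    n_greater: int   # stable partners y with gene < y in normal
    r_up: int        # of those, reversed in the sample (supports UP)
    testable: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.r_down <= self.n_less and 0 <= self.r_up <= self.n_greater):
            raise ValueError("reversal counts exceed partner counts")


@dataclass
class SampleDECall:
    """Per-gene DE verdicts for one cancer sample."""

    sample_id: str
    table: pd.DataFrame  # index gene; columns direction, p, fdr, n_less, r_down, n_greater, r_up
    alpha: float
    filter_iterations: int = 0
    converged: bool = True

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] != NONE])

    def directions(self) -> pd.Series:
        return self.table["direction"]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums, with margins fixed, the probabilities of all tables no more
    probable than the observed one (the standard two-sided definition).
    """
    cells = (int(a), int(b), int(c), int(d))
    if any(x < 0 for x in cells):
        raise ValueError("negative cell count")
    a, b, c, d = cells
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if n == 0 or row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(row1 + 1) - gammaln(k + 1) - gammaln(row1 - k + 1)
        + gammaln(row2 + 1) - gammaln(col1 - k + 1) - gammaln(row2 - col1 + k + 1)
        + gammaln(col1 + 1) + gammaln(n - col1 + 1) - gammaln(n + 1)
    )
    pmf = np.exp(logpmf)
    observed = pmf[a - lo]
    # relative tolerance mirrors the convention used by exact-test software
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return min(1.0, p)


def _count_arrays(values: np.ndarray, stable: StableREOSet):
    """Vectorised reversal counts for every gene of the universe.

    Returns (n_less, r_down, n_greater, r_up) integer arrays aligned with
    ``stable.genes``. Ties in the disease sample count as non-reversed.
    """
    g = stable.greater
    less_in_sample = values[:, None] < values[None, :]   # v_i < v_j strictly
    reversed_pairs = g & less_in_sample                  # stable i>j now flipped
    n_less = g.sum(axis=1)
    r_down = reversed_pairs.sum(axis=1)                  # flips against lower partners
    n_greater = g.sum(axis=0)
    r_up = reversed_pairs.sum(axis=0)                    # flips against higher partners
    return n_less, r_down, n_greater, r_up


def reversal_counts(
    sample_values: pd.Series, gene: str, stable_set: StableREOSet
) -> ReversalTable:
    """Reversal table of one gene in one sample against the stable landscape."""
    if gene not in stable_set._index:
        raise KeyError(f"{gene!r} not in the stable-pair universe")
    v = sample_values.reindex(stable_set.genes)
    if v.isna().any():
        raise ValueError("sample does not cover the stable-pair universe")
    values = v.to_numpy(dtype=float)
    i = stable_set._index[gene]
    g = stable_set.greater
    below = g[i, :]                # partners x: gene > x normally
    above = g[:, i]                # partners y: y > gene normally
    n_less = int(below.sum())
    n_greater = int(above.sum())
    r_down = int((below & (values[i] < values)).sum())
    r_up = int((above & (values[i] > values)).sum())
    testable = (n_less + n_greater) >= 1
    return ReversalTable(gene, n_less, r_down, n_greater, r_up, testable=testable)


def _direction(r_down, n_less, r_up, n_greater) -> str:
    pd_down = r_down / n_less if n_less else 0.0
    pd_up = r_up / n_greater if n_greater else 0.0
    if pd_up > pd_down:
        return UP
    if pd_down > pd_up:
        return DOWN
    return NONE


def call_de_single_sample(
    sample_values: pd.Series,
    stable_set: StableREOSet,
    alpha: float = 0.05,
    min_partners: int = MIN_PARTNERS,
) -> SampleDECall:
    """Unfiltered RankComp call for one sample (Fisher + BH within sample)."""
    if stable_set.n_pairs == 0:
        raise ValueError("stable set has no pairs")
    v = sample_values.reindex(stable_set.genes)
    if v.isna().any():
        raise ValueError("sample does not cover the stable-pair universe")
    values = v.to_numpy(dtype=float)
    n_less, r_down, n_greater, r_up = _count_arrays(values, stable_set)

    genes = stable_set.genes
    testable = (n_less + n_greater) >= min_partners
    p = np.full(len(genes), np.nan)
    for i in np.nonzero(testable)[0]:
        p[i] = fisher_exact_2x2(
            r_down[i], n_less[i] - r_down[i], r_up[i], n_greater[i] - r_up[i]
        )
    fdr = bh_adjust(p)
    direction = np.array([NONE] * len(genes), dtype=object)
    sig = testable & (fdr <= alpha)
    for i in np.nonzero(sig)[0]:
        direction[i] = _direction(r_down[i], n_less[i], r_up[i], n_greater[i])
    table = pd.DataFrame(
        {
            "direction": direction,
            "p": p,
            "fdr": fdr,
            "n_less": n_less,
            "r_down": r_down,
            "n_greater": n_greater,
            "r_up": r_up,
        },
        index=pd.Index(genes, name="gene"),
    )
    name = sample_values.name if sample_values.name is not None else "sample"
    return SampleDECall(str(name), table, alpha)


def filter_de_calls(
    call: SampleDECall,
    stable_set: StableREOSet,
    sample_values: pd.Series,
    max_iter: int = 100,
    min_partners: int = MIN_PARTNERS,
) -> SampleDECall:
    """Remove DE calls that lose significance once reversal partners that
    are themselves DE are excluded; iterate to a fixed point.

    Non-DE genes keep their original p-values; BH is re-applied over the
    full testable set each round. The retained DE set only shrinks.
    """
    values = sample_values.reindex(stable_set.genes).to_numpy(dtype=float)
    g = stable_set.greater
    less_in_sample = values[:, None] < values[None, :]
    table = call.table.copy()
    genes = list(table.index)
    alpha = call.alpha
    base_p = table["p"].to_numpy(dtype=float).copy()
    testable = ~np.isnan(base_p)
    de = (table["direction"] != NONE).to_numpy()

    iterations = 0
    converged = True
    for iterations in range(1, max_iter + 1):
        if not de.any():
            iterations -= 1
            break
        keep = ~de  # partners allowed in the reduced tables
        p = base_p.copy()
        red = {}
        for i in np.nonzero(de)[0]:
            below = g[i, :] & keep
            above = g[:, i] & keep
            nl = int(below.sum())
            ng = int(above.sum())
            rd = int((below & less_in_sample[i, :]).sum())
            ru = int((above & (values < values[i])).sum())
            red[i] = (nl, rd, ng, ru)
            if nl + ng < min_partners:
                p[i] = np.nan
            else:
                p[i] = fisher_exact_2x2(rd, nl - rd, ru, ng - ru)
        fdr = bh_adjust(p)
        still = de & ~np.isnan(p) & (fdr <= alpha)
        if (still == de).all():
            table["p"] = p
            table["fdr"] = fdr
            for i, (nl, rd, ng, ru) in red.items():
                table.iloc[i, table.columns.get_loc("n_less")] = nl
                table.iloc[i, table.columns.get_loc("r_down")] = rd
                table.iloc[i, table.columns.get_loc("n_greater")] = ng
                table.iloc[i, table.columns.get_loc("r_up")] = ru
            break
        de = still
    else:
        converged = False
    direction = table["direction"].to_numpy(dtype=object)
    direction[~de] = NONE
    table["direction"] = direction
    return SampleDECall(call.sample_id, table, alpha, iterations, converged)


def run_rankcomp(
    cancer_matrix: ExpressionMatrix,
    stable_set: StableREOSet,
    alpha: float = 0.05,
    apply_filter: bool = True,
    min_partners: int = MIN_PARTNERS,
) -> list[SampleDECall]:
    """Call and filter DE genes for every sample of a cancer cohort."""
    calls = []
    for sample in cancer_matrix.sample_ids:
        values = cancer_matrix.values[sample]
        call = call_de_single_sample(values, stable_set, alpha, min_partners)
        if apply_filter:
            call = filter_de_calls(call, stable_set, values, min_partners=min_partners)
        calls.append(call)
    return calls


def calls_to_frame(calls: list[SampleDECall]) -> pd.DataFrame:
    """Long-format table (sample_id, gene, direction, p, fdr) of DE calls."""
    rows = []
    for call in calls:
        sub = call.table[call.table["direction"] != NONE]
        for gene, row in sub.iterrows():
            rows.append(
                {
                    "sample_id": call.sample_id,
                    "gene": gene,
                    "direction": row["direction"],
                    "p": row["p"],
                    "fdr": row["fdr"],
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "direction", "p", "fdr"])
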