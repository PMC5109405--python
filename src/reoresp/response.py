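"""Classification of response genes by deregulation-frequency contrast.

A gene's deregulation frequency is the fraction of cancer samples in which
the individual-sample caller marks it differentially expressed relative to
normal tissue (direction-agnostic by default). Genes whose frequencies
differ between non-responders and responders (two-sided Fisher exact test,
BH FDR) are the *cancer-related* response genes; group-level DE genes not
in that set are the *cancer-unrelated* response genes. A pooled binomial
test against a background call rate flags genes deregulated in a
non-randomly high share of all cancer samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NONE, bh_adjust
from .groupde import DirectedGeneList
from .landscape import binomial_upper_tail
from .rankcomp import SampleDECall, fisher_exact_2x2

__all__ = [
    "DeregulationProfile",
    "ResponseGeneClasses",
    "build_profile",
    "cancer_related_background_test",
    "frequency_difference_test",
    "partition_classes",
]


@dataclass
class DeregulationProfile:
    """Per-gene deregulation counts within each responder group."""

    counts: pd.DataFrame  # index gene; n_dereg_nonresp, n_dereg_resp (+ per-direction)
    n_nonresp: int
    n_resp: int

    def __post_init__(self) -> None:
        c = self.counts
        if ((c["n_dereg_nonresp"] < 0) | (c["n_dereg_nonresp"] > self.n_nonresp)).any():
            raise ValueError("non-responder counts out of range")
        if ((c["n_dereg_resp"] < 0) | (c["n_dereg_resp"] > self.n_resp)).any():
            raise ValueError("responder counts out of range")


@dataclass
class ResponseGeneClasses:
    cancer_related: set
    shared_with_group_de: set
    cancer_unrelated: set

    def __post_init__(self) -> None:
        if self.cancer_related & self.cancer_unrelated:
            raise ValueError("cancer-related and cancer-unrelated classes overlap")
        if not self.shared_with_group_de <= self.cancer_related:
            raise ValueError("shared genes must be cancer-related")

    def sizes(self) -> dict:
        return {
            "cancer_related": len(self.cancer_related),
            "shared_with_group_de": len(self.shared_with_group_de),
            "cancer_unrelated": len(self.cancer_unrelated),
        }


def build_profile(
    calls: list[SampleDECall], groups: pd.Series, directed: bool = False
) -> DeregulationProfile:
    """Count, per gene and responder group, the samples calling it DE.

    ``groups`` maps each called sample to ``responder``/``nonresponder``.
    With ``directed=True`` additional per-direction columns are included;
    the headline counts remain direction-agnostic.
    """
    if not calls:
        raise ValueError("no DE calls supplied")
    for call in calls:
        if call.sample_id not in groups.index or pd.isna(groups.get(call.sample_id)):
            raise ValueError(f"sample {call.sample_id!r} has no group label")
    genes = calls[0].table.index
    cols = ["n_dereg_nonresp", "n_dereg_resp"]
    if directed:
        cols += ["n_up_nonresp", "n_down_nonresp", "n_up_resp", "n_down_resp"]
    counts = pd.DataFrame(0, index=genes, columns=cols)
    n_by_group = {"nonresponder": 0, "responder": 0}
    for call in calls:
        group = groups[call.sample_id]
        if group not in n_by_group:
            raise ValueError(f"sample {call.sample_id!r} has group {group!r}")
        n_by_group[group] += 1
        d = call.table["direction"]
        de = d != NONE
        key = "nonresp" if group == "nonresponder" else "resp"
        counts[f"n_dereg_{key}"] += de.astype(int)
        if directed:
            counts[f"n_up_{key}"] += (d == "UP").astype(int)
            counts[f"n_down_{key}"] += (d == "DOWN").astype(int)
    return DeregulationProfile(counts, n_by_group["nonresponder"], n_by_group["responder"])


def cancer_related_background_test(
    profile: DeregulationProfile, p0: float, alpha: float = 0.05
) -> set:
    """Genes deregulated in a non-randomly high share of all cancer samples.

    Pools both groups and tests the total deregulation count against a
    Binomial(n_total, p0) upper tail at significance ``alpha``.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    n_total = profile.n_nonresp + profile.n_resp
    total = profile.counts["n_dereg_nonresp"] + profile.counts["n_dereg_resp"]
    selected = set()
    for gene, count in total.items():
        if count == 0:
            continue
        if binomial_upper_tail(int(count), n_total, p0).p < alpha:
            selected.add(gene)
    return selected


def frequency_difference_test(
    profile: DeregulationProfile, alpha_fdr: float = 0.05
) -> pd.DataFrame:
    """Two-sided Fisher contrast of deregulation frequencies between groups.

    Returns the per-gene table (counts, p, fdr, selected); the selected
    genes at BH FDR <= ``alpha_fdr`` are the cancer-related response genes.
    """
    if profile.n_nonresp == 0 or profile.n_resp == 0:
        raise ValueError("both responder groups must be non-empty")
    c = profile.counts
    p = np.array(
        [
            fisher_exact_2x2(
                int(row["n_dereg_nonresp"]),
                profile.n_nonresp - int(row["n_dereg_nonresp"]),
                int(row["n_dereg_resp"]),
                profile.n_resp - int(row["n_dereg_resp"]),
            )
            for _, row in c.iterrows()
        ]
    )
    out = c[["n_dereg_nonresp", "n_dereg_resp"]].copy()
    out["n_nonresp"] = profile.n_nonresp
    out["n_resp"] = profile.n_resp
    out["p"] = p
    out["fdr"] = bh_adjust(p)
    out["selected"] = out["fdr"] <= alpha_fdr
    return out


def partition_classes(
    cancer_related: set, merged_group_de: DirectedGeneList
) -> ResponseGeneClasses:
    """Split the merged group-DE list into cancer-related and -unrelated."""
    merged = merged_group_de.genes
    shared = set(cancer_related) & merged
    return ResponseGeneClasses(
        cancer_related=set(cancer_related),
        shared_with_group_de=shared,
        cancer_unrelated=merged - shared,
    )
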