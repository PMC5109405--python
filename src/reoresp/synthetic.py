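"""Synthetic multi-platform cohorts with planted response-gene structure.

The generator emulates the study design the pipeline targets: several
normal-tissue cohorts measured on different "platforms" that share a gene
core and near-perfect within-sample orderings; a rectal-cancer cohort split
into responders and non-responders in which a chosen subset of genes is
deregulated with group-specific frequencies (cancer-related response
genes); and a second subset shifted uniformly in every sample of one group
only, mimicking pharmacokinetic markers that differ between groups without
being deregulated relative to normal tissue.

Gene baselines rise with gene index (``gene_0001`` lowest) in steps of
``baseline_spread`` log2 units, so the normal ordering is explicit and
brute-force checkable. Platforms apply strictly increasing affine
transforms to the log2 values — relative orderings are invariant by
construction, matching the cross-platform premise of REO analysis.

Ground truth (gene classes, per-sample planted events) is returned next to
the matrices so recovery of every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, ExpressionMatrix

__all__ = ["CohortConfig", "GroundTruth", "simulate_cohort", "simulate_ppi",
           "simulate_gene_sets"]


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the target study's structure: three normal cohorts of
    21, 7 and 6 samples on distinct platforms, and a cancer cohort of 38
    non-responders and 34 responders split over two datasets.
    """

    n_genes: int = 500
    n_platforms: int = 3
    genes_per_platform: int = 500
    n_normal_per_platform: int | Sequence[int] = (21, 7, 6)
    n_responders: int = 34
    n_nonresponders: int = 38
    baseline_spread: float = 0.05   # log2 gap between adjacent gene baselines
    noise_sd: float = 0.2           # log2 measurement noise
    frac_cancer_related: float = 0.05
    dereg_freq_nonresp: float = 0.8
    dereg_freq_resp: float = 0.1
    dereg_effect: float = 3.0       # |log2 shift| of a planted deregulation event
    frac_cancer_unrelated_marker: float = 0.05
    marker_effect: float = 0.4      # uniform group shift of marker genes
    seed: int = 0
    cancer_dataset_split: tuple[float, float] = (22 / 38, 24 / 34)
    # fractions of (nonresponders, responders) assigned to the first cancer dataset

    def normals_per_platform(self) -> list[int]:
        n = self.n_normal_per_platform
        if isinstance(n, (int, np.integer)):
            counts = [int(n)] * self.n_platforms
        else:
            counts = [int(x) for x in n]
            if len(counts) != self.n_platforms:
                raise ConfigurationError(
                    "n_normal_per_platform sequence length must equal n_platforms"
                )
        return counts

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_platforms <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0 < self.genes_per_platform <= self.n_genes:
            raise ConfigurationError("genes_per_platform must be in (0, n_genes]")
        if any(c <= 0 for c in self.normals_per_platform()):
            raise ConfigurationError("normal sample counts must be positive")
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ConfigurationError("responder counts must be non-negative")
        for name in ("frac_cancer_related", "dereg_freq_nonresp", "dereg_freq_resp",
                     "frac_cancer_unrelated_marker"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.baseline_spread <= 0 or self.dereg_effect <= 0:
            raise ConfigurationError("baseline_spread and dereg_effect must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    ``cancer_related`` and ``markers`` are disjoint gene classes;
    ``events`` lists every per-sample planted deregulation of a
    cancer-related gene.
    """

    cancer_related: pd.DataFrame   # gene, direction, freq_nonresp, freq_resp
    markers: pd.DataFrame          # gene, direction, group
    events: pd.DataFrame           # sample, gene, direction

    def __post_init__(self) -> None:
        overlap = set(self.cancer_related["gene"]) & set(self.markers["gene"])
        if overlap:
            raise ValueError(f"truth classes overlap: {sorted(overlap)[:5]}")

    @property
    def cancer_related_genes(self) -> set:
        return set(self.cancer_related["gene"])

    @property
    def marker_genes(self) -> set:
        return set(self.markers["gene"])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"gene_{i + 1:0{width}d}" for i in range(n)]


def simulate_cohort(config: CohortConfig):
    """Draw a full synthetic study.

    Returns ``(normals, cancers, truth)`` where ``normals`` is one
    :class:`ExpressionMatrix` per platform, ``cancers`` a single matrix
    with responder / non-responder labels and a per-sample dataset split,
    and ``truth`` the planted ground truth. Deterministic given
    ``config.seed``.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_assign = np.random.default_rng(streams[0])
    rng_normal = np.random.default_rng(streams[1])
    rng_cancer = np.random.default_rng(streams[2])

    genes = _gene_ids(config.n_genes)
    baseline = np.arange(config.n_genes) * config.baseline_spread + 4.0

    # --- truth classes -------------------------------------------------
    n_cr = int(round(config.frac_cancer_related * config.n_genes))
    n_mk = int(round(config.frac_cancer_unrelated_marker * config.n_genes))
    chosen = rng_assign.choice(config.n_genes, size=n_cr + n_mk, replace=False)
    cr_idx = np.sort(chosen[:n_cr])
    mk_idx = np.sort(chosen[n_cr:])
    cr_dir = rng_assign.choice([1, -1], size=n_cr)
    mk_dir = rng_assign.choice([1, -1], size=n_mk)
    mk_group = rng_assign.choice(["nonresponder", "responder"], size=n_mk)

    # --- normal cohorts ------------------------------------------------
    normals = []
    sample_counter = 0
    for p, n_samples in enumerate(config.normals_per_platform()):
        sub = np.sort(
            rng_assign.choice(config.n_genes, size=config.genes_per_platform,
                              replace=False)
        )
        scale = rng_assign.uniform(0.6, 1.6)
        offset = rng_assign.uniform(-2.0, 2.0)
        noise = rng_normal.normal(0.0, config.noise_sd,
                                  size=(config.genes_per_platform, n_samples))
        values = baseline[sub, None] + noise
        values = scale * values + offset  # strictly increasing platform transform
        sample_ids = [f"normal_{sample_counter + i + 1:03d}" for i in range(n_samples)]
        sample_counter += n_samples
        df = pd.DataFrame(values, index=[genes[i] for i in sub], columns=sample_ids)
        groups = pd.Series("normal", index=sample_ids)
        normals.append(ExpressionMatrix(df, groups, dataset_label=f"platform_{p + 1}"))

    # --- cancer cohort -------------------------------------------------
    n_cancer = config.n_nonresponders + config.n_responders
    labels = (["nonresponder"] * config.n_nonresponders
              + ["responder"] * config.n_responders)
    sample_ids = [f"cancer_{i + 1:03d}" for i in range(n_cancer)]
    values = baseline[:, None] + rng_cancer.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_cancer)
    )

    events = []
    freq = {"nonresponder": config.dereg_freq_nonresp,
            "responder": config.dereg_freq_resp}
    for gi, d in zip(cr_idx, cr_dir):
        for s, group in enumerate(labels):
            if rng_cancer.random() < freq[group]:
                values[gi, s] += d * config.dereg_effect
                events.append(
                    {"sample": sample_ids[s], "gene": genes[gi],
                     "direction": "UP" if d > 0 else "DOWN"}
                )
    for gi, d, grp in zip(mk_idx, mk_dir, mk_group):
        for s, group in enumerate(labels):
            if group == grp:
                values[gi, s] += d * config.marker_effect

    groups = pd.Series(labels, index=sample_ids)
    split_nr, split_r = config.cancer_dataset_split
    ds = []
    nr_seen = r_seen = 0
    for group in labels:
        if group == "nonresponder":
            ds.append("cancer_ds1" if nr_seen < round(split_nr * config.n_nonresponders)
                      else "cancer_ds2")
            nr_seen += 1
        else:
            ds.append("cancer_ds1" if r_seen < round(split_r * config.n_responders)
                      else "cancer_ds2")
            r_seen += 1
    cancers = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        groups,
        dataset_label="cancer",
        datasets=pd.Series(ds, index=sample_ids),
    )

    truth = GroundTruth(
        cancer_related=pd.DataFrame(
            {
                "gene": [genes[i] for i in cr_idx],
                "direction": ["UP" if d > 0 else "DOWN" for d in cr_dir],
                "freq_nonresp": config.dereg_freq_nonresp,
                "freq_resp": config.dereg_freq_resp,
            }
        ),
        markers=pd.DataFrame(
            {
                "gene": [genes[i] for i in mk_idx],
                "direction": ["UP" if d > 0 else "DOWN" for d in mk_dir],
                "group": mk_group,
            }
        ),
        events=pd.DataFrame(events, columns=["sample", "gene", "direction"]),
    )
    return normals, cancers, truth


def simulate_ppi(
    gene_universe: Sequence[str],
    query_set: Sequence[str],
    target_set: Sequence[str],
    base_edge_prob: float,
    boost_edge_prob: float,
    seed: int,
) -> list[tuple[str, str]]:
    """Erdos-Renyi background with boosted query-target edge probability.

    Every unordered pair of distinct genes is an edge with probability
    ``base_edge_prob``, raised to ``boost_edge_prob`` when one endpoint is
    in the query set and the other in the target set. No self-loops, no
    duplicates; deterministic given ``seed``.
    """
    for name, p in (("base_edge_prob", base_edge_prob),
                    ("boost_edge_prob", boost_edge_prob)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    if boost_edge_prob < base_edge_prob:
        raise ConfigurationError("boost_edge_prob must be >= base_edge_prob")
    universe = list(gene_universe)
    uni = set(universe)
    query = set(query_set)
    target = set(target_set)
    if not query <= uni or not target <= uni:
        raise ConfigurationError("query and target sets must lie in the universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edges = []
    for i, a in enumerate(universe):
        for b in universe[i + 1:]:
            boosted = (a in query and b in target) or (b in query and a in target)
            p = boost_edge_prob if boosted else base_edge_prob
            if rng.random() < p:
                edges.append((a, b))
    return edges


def simulate_gene_sets(
    gene_universe: Sequence[str],
    n_sets: int = 20,
    size_range: tuple[int, int] = (10, 50),
    planted: dict[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene-set collection (GMT-style) over a universe.

    ``planted`` entries are emitted verbatim as additional sets, so tests
    can plant genuinely enriched pathways next to random ones.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(gene_universe)
    lo, hi = size_range
    if not 0 < lo <= hi <= len(universe):
        raise ConfigurationError("invalid size_range for the given universe")
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"random_set_{i + 1:02d}"] = sorted(universe[j] for j in members)
    for name, members in (planted or {}).items():
        sets[name] = sorted(members)
    return sets
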