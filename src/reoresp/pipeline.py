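"""End-to-end orchestration on a synthetic cohort.

Runs simulate -> normal REO landscape -> per-sample RankComp -> group
rank-product DE -> response-gene classes -> pathway enrichment -> PPI
statistics, writing every stage's tables under an output directory and a
manifest JSON that summarises the run (sizes, parameters, seeds). All
randomness derives from one seed, so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .core import ExpressionMatrix
from .enrichment import GeneSetCollection, hypergeometric_enrichment, write_gmt
from .groupde import concordance_and_merge, directed_list_from_result, rank_product_de
from .landscape import cross_set_concordance, find_stable_pairs
from .ppi import PPIGraph, compare_link_distributions, direct_link_stats
from .rankcomp import calls_to_frame, run_rankcomp
from .response import (
    build_profile,
    cancer_related_background_test,
    frequency_difference_test,
    partition_classes,
)
from .synthetic import CohortConfig, simulate_cohort, simulate_gene_sets, simulate_ppi

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "landscape", "rankcomp", "groupde", "classes",
              "enrich", "ppi")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stable_support: float = 1.0
    rankcomp_alpha: float = 0.05
    group_de_fdr: float = 0.05
    freq_contrast_fdr: float = 0.05
    enrichment_fdr: float = 0.2
    background_p0: float | None = None  # defaults to rankcomp_alpha
    n_permutations: int = 100
    ppi_base_edge_prob: float = 0.01
    ppi_boost_edge_prob: float = 0.25
    stages: tuple = ALL_STAGES

    def __post_init__(self) -> None:
        for name in ("stable_support", "rankcomp_alpha", "group_de_fdr",
                     "freq_contrast_fdr", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        cohort = d["cohort"]
        for key, value in cohort.items():
            if isinstance(value, tuple):
                cohort[key] = list(value)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.to_dict(), "stages": {}}
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGES[stage](config, state, manifest, out)
        except Exception as exc:  # keep partial outputs, name the stage
            _write_manifest(manifest, out)
            raise StageError(stage, exc) from exc

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _stage_simulate(config, state, manifest, out):
    normals, cancers, truth = simulate_cohort(config.cohort)
    state["normals"], state["cancers"], state["truth"] = normals, cancers, truth
    d = out / "simulated"
    d.mkdir(exist_ok=True)
    for m in normals:
        io.write_expression(m, d / f"normals_{m.dataset_label}.tsv",
                            d / f"normals_{m.dataset_label}.meta.tsv")
    io.write_expression(cancers, d / "cancers.tsv", d / "cancers.meta.tsv")
    truth.cancer_related.to_csv(d / "truth_cancer_related.tsv", sep="\t", index=False)
    truth.markers.to_csv(d / "truth_markers.tsv", sep="\t", index=False)
    truth.events.to_csv(d / "truth_events.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {
        "n_normal_samples": int(sum(m.n_samples for m in normals)),
        "n_cancer_samples": int(cancers.n_samples),
        "n_cancer_related_truth": len(truth.cancer_related_genes),
        "n_marker_truth": len(truth.marker_genes),
        "n_planted_events": int(len(truth.events)),
    }


def _stage_landscape(config, state, manifest, out):
    normals = state["normals"]
    stable = find_stable_pairs(normals, config.stable_support)
    state["stable"] = stable
    io.write_pairs(stable, out / "stable_pairs.tsv.gz")
    report = {"n_pairs": stable.n_pairs, "n_genes": len(stable.genes),
              "n_supporting_samples": stable.n_supporting_samples}
    if len(normals) > 1:
        set_a = find_stable_pairs(normals[:1], config.stable_support)
        set_b = find_stable_pairs(normals[1:], config.stable_support)
        conc = cross_set_concordance(set_a, set_b)
        report["cross_set_concordance"] = conc.to_dict()
        with open(out / "landscape_concordance.json", "w") as fh:
            json.dump(conc.to_dict(), fh, indent=2)
    manifest["stages"]["landscape"] = report


def _stage_rankcomp(config, state, manifest, out):
    cancers = state["cancers"].restrict(state["stable"].genes)
    calls = run_rankcomp(cancers, state["stable"], config.rankcomp_alpha)
    state["calls"] = calls
    frame = calls_to_frame(calls)
    frame.to_csv(out / "rankcomp_calls.tsv", sep="\t", index=False)
    n_de = [len(c.de_genes) for c in calls]
    manifest["stages"]["rankcomp"] = {
        "n_samples": len(calls),
        "mean_de_genes_per_sample": float(np.mean(n_de)) if n_de else 0.0,
        "alpha": config.rankcomp_alpha,
    }


def _stage_groupde(config, state, manifest, out):
    cancers = state["cancers"]
    per_dataset = cancers.split_by_dataset()
    lists = []
    report = {"per_dataset": {}}
    for label, sub in sorted(per_dataset.items()):
        a = [s for s in sub.sample_ids if sub.groups[s] == "nonresponder"]
        b = [s for s in sub.sample_ids if sub.groups[s] == "responder"]
        result = rank_product_de(sub, a, b, config.n_permutations,
                                 config.group_de_fdr, seed=config.cohort.seed)
        result.table.to_csv(out / f"rankprod_{label}.tsv", sep="\t")
        lst = directed_list_from_result(result, config.group_de_fdr, label)
        lists.append(lst)
        report["per_dataset"][label] = {"n_de": len(lst), "method": result.method,
                                        "n_comparisons": result.n_comparisons}
    if len(lists) >= 2:
        conc, merged = concordance_and_merge(lists[0], lists[1])
        report["concordance"] = conc.to_dict()
        with open(out / "groupde_concordance.json", "w") as fh:
            json.dump(conc.to_dict(), fh, indent=2)
    else:
        merged = lists[0]
    state["merged_de"] = merged
    merged.directions.rename("direction").to_csv(
        out / "merged_group_de.tsv", sep="\t", index_label="gene")
    report["n_merged"] = len(merged)
    manifest["stages"]["groupde"] = report


def _stage_classes(config, state, manifest, out):
    cancers = state["cancers"]
    profile = build_profile(state["calls"], cancers.groups, directed=True)
    freq = frequency_difference_test(profile, config.freq_contrast_fdr)
    freq.to_csv(out / "frequency_contrast.tsv", sep="\t", index_label="gene")
    cancer_related = set(freq.index[freq["selected"]])
    p0 = config.background_p0 or config.rankcomp_alpha
    background = cancer_related_background_test(profile, p0)
    classes = partition_classes(cancer_related, state["merged_de"])
    state["classes"] = classes
    pd.Series(sorted(background)).to_csv(
        out / "background_cancer_related.tsv", sep="\t", index=False, header=["gene"])
    for name, genes in (("cancer_related", classes.cancer_related),
                        ("cancer_unrelated", classes.cancer_unrelated),
                        ("shared_with_group_de", classes.shared_with_group_de)):
        pd.Series(sorted(genes)).to_csv(out / f"class_{name}.tsv", sep="\t",
                                        index=False, header=["gene"])
    summary = classes.sizes() | {"n_background_cancer_related": len(background)}
    with open(out / "class_sizes.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["stages"]["classes"] = summary


def _stage_enrich(config, state, manifest, out):
    universe = list(state["stable"].genes)
    truth = state["truth"]
    planted = {"planted_cancer_related_pathway":
               sorted(truth.cancer_related_genes & set(universe))}
    sets = simulate_gene_sets(universe, n_sets=20, size_range=(10, 50),
                              planted=planted, seed=config.cohort.seed + 101)
    write_gmt(sets, out / "pathways.gmt")
    collection = GeneSetCollection(sets, set(universe))
    report = {}
    for name, genes in (("cancer_related", state["classes"].cancer_related),
                        ("cancer_unrelated", state["classes"].cancer_unrelated)):
        if not genes:
            report[name] = {"n_significant": 0, "note": "empty query"}
            continue
        table = hypergeometric_enrichment(genes, collection, config.enrichment_fdr)
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        report[name] = {"n_significant": int(table["significant"].sum()),
                        "top_set": table.iloc[0]["set_name"] if len(table) else None}
    manifest["stages"]["enrich"] = report


def _stage_ppi(config, state, manifest, out):
    universe = list(state["stable"].genes)
    truth = state["truth"]
    rng = np.random.default_rng(np.random.SeedSequence(config.cohort.seed + 202))
    non_truth = sorted(set(universe) - truth.cancer_related_genes
                       - truth.marker_genes)
    effective = sorted(rng.choice(non_truth, size=min(40, len(non_truth)),
                                  replace=False))
    edges = simulate_ppi(universe, sorted(truth.cancer_related_genes), effective,
                         config.ppi_base_edge_prob, config.ppi_boost_edge_prob,
                         seed=config.cohort.seed + 303)
    io.write_edgelist(edges, out / "ppi_edges.tsv")
    graph = PPIGraph(edges)
    report = {"n_edges": graph.number_of_edges(), "n_nodes": graph.number_of_nodes()}
    classes = state["classes"]
    stats = {}
    for name, genes in (("cancer_related", classes.cancer_related),
                        ("cancer_unrelated", classes.cancer_unrelated)):
        st = direct_link_stats(genes, effective, graph)
        stats[name] = st
        report[name] = {"n_mapped": len(st.mapped_query),
                        "total_links": st.total_links, "average": st.average}
    a, b = stats["cancer_related"], stats["cancer_unrelated"]
    if len(a.per_gene_counts) and len(b.per_gene_counts):
        cmp = compare_link_distributions(a.per_gene_counts, b.per_gene_counts)
        report["rank_sum"] = {"p_value": cmp.p_value, "method": cmp.method}
    with open(out / "ppi_stats.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    manifest["stages"]["ppi"] = report


_STAGES = {
    "simulate": _stage_simulate,
    "landscape": _stage_landscape,
    "rankcomp": _stage_rankcomp,
    "groupde": _stage_groupde,
    "classes": _stage_classes,
    "enrich": _stage_enrich,
    "ppi": _stage_ppi,
}
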