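"""Generate the default synthetic study cohort and its ground truth.

Three normal-tissue cohorts (21 + 7 + 6 samples) on distinct platforms and
a 72-sample rectal-cancer cohort (38 non-responders / 34 responders, split
over two datasets) with 5% of genes planted as cancer-related (deregulated
in 80% of non-responders vs 10% of responders, |log2 shift| = 3) and 5% as
group-uniform pharmacokinetic-style markers (shift 0.4).

Writes expression/metadata/truth tables under results/analysis/simulated/.
"""

from pathlib import Path

from reoresp import io
from reoresp.synthetic import CohortConfig, simulate_cohort

OUT = Path("results/analysis/simulated")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=seed)
    normals, cancers, truth = simulate_cohort(config)
    for m in normals:
        io.write_expression(m, OUT / f"normals_{m.dataset_label}.tsv",
                            OUT / f"normals_{m.dataset_label}.meta.tsv")
    io.write_expression(cancers, OUT / "cancers.tsv", OUT / "cancers.meta.tsv")
    truth.cancer_related.to_csv(OUT / "truth_cancer_related.tsv", sep="\t",
                                index=False)
    truth.markers.to_csv(OUT / "truth_markers.tsv", sep="\t", index=False)
    truth.events.to_csv(OUT / "truth_events.tsv", sep="\t", index=False)
    print(f"simulated {sum(m.n_samples for m in normals)} normal and "
          f"{cancers.n_samples} cancer samples over {config.n_genes} genes")
    print(f"planted {len(truth.cancer_related_genes)} cancer-related genes "
          f"({len(truth.events)} per-sample events) and "
          f"{len(truth.marker_genes)} marker genes -> {OUT}")


if __name__ == "__main__":
    main()
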