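"""Classify response genes as cancer-related or cancer-unrelated.

Cancer-related response genes are those whose deregulation frequency
(RankComp calls vs normal) differs between responder groups (Fisher, BH
FDR <= 0.05); group-DE genes outside that set are cancer-unrelated.
Recovery of the planted truth is reported alongside.
"""

import json
from pathlib import Path

import pandas as pd

from reoresp import io
from reoresp.core import NONE
from reoresp.groupde import DirectedGeneList
from reoresp.rankcomp import SampleDECall
from reoresp.response import (
    build_profile,
    cancer_related_background_test,
    frequency_difference_test,
    partition_classes,
)

SIM = Path("results/analysis/simulated")
OUT = Path("results/analysis")


def load_calls(cancers, stable_genes) -> list[SampleDECall]:
    frame = pd.read_csv(OUT / "rankcomp_calls.tsv", sep="\t")
    calls = []
    for sample in cancers.sample_ids:
        sub = frame[frame["sample_id"] == sample].set_index("gene")
        table = pd.DataFrame(
            {"direction": NONE, "p": 1.0, "fdr": 1.0},
            index=pd.Index(stable_genes, name="gene"),
        )
        table.loc[sub.index, ["direction", "p", "fdr"]] = sub[
            ["direction", "p", "fdr"]
        ]
        calls.append(SampleDECall(sample, table, alpha=0.05))
    return calls


def main() -> None:
    cancers = io.read_expression(SIM / "cancers.tsv", SIM / "cancers.meta.tsv")
    stable_genes = io.read_pairs(OUT / "stable_pairs.tsv.gz").genes
    calls = load_calls(cancers, stable_genes)
    profile = build_profile(calls, cancers.groups)

    freq = frequency_difference_test(profile, alpha_fdr=0.05)
    freq.to_csv(OUT / "frequency_contrast.tsv", sep="\t", index_label="gene")
    cancer_related = set(freq.index[freq["selected"]])
    background = cancer_related_background_test(profile, p0=0.05)

    merged = pd.read_csv(OUT / "merged_group_de.tsv", sep="\t").set_index("gene")
    classes = partition_classes(
        cancer_related, DirectedGeneList(merged["direction"], "merged")
    )
    sizes = classes.sizes() | {"n_background_cancer_related": len(background)}
    with open(OUT / "class_sizes.json", "w") as fh:
        json.dump(sizes, fh, indent=2)
    for name, genes in (("cancer_related", classes.cancer_related),
                        ("cancer_unrelated", classes.cancer_unrelated)):
        pd.Series(sorted(genes)).to_csv(OUT / f"class_{name}.tsv", sep="\t",
                                        index=False, header=["gene"])

    truth = set(pd.read_csv(SIM / "truth_cancer_related.tsv", sep="\t")["gene"])
    tp = len(cancer_related & truth)
    print(f"{len(cancer_related)} cancer-related response genes "
          f"({len(classes.shared_with_group_de)} shared with the merged group-DE "
          f"list, {len(classes.cancer_unrelated)} cancer-unrelated)")
    print(f"truth recovery: recall {tp / len(truth):.2f}, "
          f"precision {tp / max(len(cancer_related), 1):.2f}; "
          f"background binomial test flags {len(background)} genes")


if __name__ == "__main__":
    main()
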