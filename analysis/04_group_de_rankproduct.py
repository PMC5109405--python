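"""Group-level DE between non-responders and responders, per dataset.

Rank products over pairwise fold-change ranks give per-dataset directed DE
lists; their direction concordance over shared genes is binomial-tested
and the lists are merged, dropping direction-inconsistent genes.
"""

import json
from pathlib import Path

from reoresp import io
from reoresp.groupde import (
    concordance_and_merge,
    directed_list_from_result,
    rank_product_de,
)

SIM = Path("results/analysis/simulated")
OUT = Path("results/analysis")


def main(fdr: float = 0.05, n_permutations: int = 100, seed: int = 1) -> None:
    cancers = io.read_expression(SIM / "cancers.tsv", SIM / "cancers.meta.tsv")
    lists = []
    for label, sub in sorted(cancers.split_by_dataset().items()):
        a = [s for s in sub.sample_ids if sub.groups[s] == "nonresponder"]
        b = [s for s in sub.sample_ids if sub.groups[s] == "responder"]
        result = rank_product_de(sub, a, b, n_permutations, fdr, seed=seed)
        result.table.to_csv(OUT / f"rankprod_{label}.tsv", sep="\t")
        lst = directed_list_from_result(result, fdr, label)
        lists.append(lst)
        print(f"{label}: {len(lst)} DE genes "
              f"({result.n_comparisons} comparisons, {result.method} null)")
    conc, merged = concordance_and_merge(lists[0], lists[1])
    merged.directions.rename("direction").to_csv(
        OUT / "merged_group_de.tsv", sep="\t", index_label="gene")
    with open(OUT / "groupde_concordance.json", "w") as fh:
        json.dump(conc.to_dict(), fh, indent=2)
    print(f"shared k={conc.k}, same-direction s={conc.s} "
          f"(score {conc.score:.2f}, p={conc.p_value:.2e}); "
          f"merged list holds {len(merged)} genes")


if __name__ == "__main__":
    main()
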