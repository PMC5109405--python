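"""Pathway over-representation of the two response-gene classes.

Builds a pathway collection over the measured universe (random sets plus
one set planted from the true cancer-related genes) and scores both gene
classes with the hypergeometric upper tail at a reporting FDR of 0.2.
"""

from pathlib import Path

import pandas as pd

from reoresp import io
from reoresp.enrichment import GeneSetCollection, hypergeometric_enrichment, write_gmt
from reoresp.synthetic import simulate_gene_sets

SIM = Path("results/analysis/simulated")
OUT = Path("results/analysis")


def main(seed: int = 1) -> None:
    universe = io.read_pairs(OUT / "stable_pairs.tsv.gz").genes
    truth = set(pd.read_csv(SIM / "truth_cancer_related.tsv", sep="\t")["gene"])
    sets = simulate_gene_sets(
        universe, n_sets=20, size_range=(10, 50),
        planted={"planted_cancer_related_pathway": sorted(truth & set(universe))},
        seed=seed + 101,
    )
    write_gmt(sets, OUT / "pathways.gmt")
    collection = GeneSetCollection(sets, set(universe))
    for name in ("cancer_related", "cancer_unrelated"):
        query = pd.read_csv(OUT / f"class_{name}.tsv", sep="\t")["gene"]
        table = hypergeometric_enrichment(query, collection, 0.2)
        table.to_csv(OUT / f"enrichment_{name}.tsv", sep="\t", index=False)
        top = table.iloc[0]
        print(f"{name}: {int(table['significant'].sum())} sets at FDR<=0.2; "
              f"top = {top['set_name']} (k={top['k']}, p={top['p']:.2e})")


if __name__ == "__main__":
    main()
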