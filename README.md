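# reoresp

Discriminating **cancer-related** from **cancer-unrelated**
chemoradiation-response genes in rectal cancer transcriptomes using
relative expression orderings (REOs).

Genes differentially expressed between responders and non-responders to
preoperative chemoradiation mix two mechanisms: genes whose deregulation
*relative to normal tissue* occurs at different frequencies in the two
outcome groups (cancer-related), and genes that merely differ between
groups — e.g. drug-metabolism differences — without asymmetric
deregulation (cancer-unrelated). Telling them apart needs differential
expression calls in *individual* cancer samples, across microarray
platforms, without between-sample normalisation. The within-sample order
relation expr(a) > expr(b) is invariant to any monotone per-platform
transform, which makes that possible:

1. mine gene pairs whose ordering is identical in **all** normal samples
   (the stable REO landscape), validating cross-platform agreement with
   a cumulative binomial test on the concordance score *s/k*;
2. call per-sample DE genes from reversals of stable pairs — for gene
   *X*, Fisher's exact test on
   [[r_down, n_less − r_down], [r_up, n_greater − r_up]] contrasts the
   reversal frequencies supporting down- vs up-regulation, with BH
   adjustment per sample and iterative filtering of calls that depend on
   other called genes (RankComp);
3. contrast each gene's deregulation frequency between non-responders
   and responders (Fisher exact, BH FDR ≤ 0.05) → cancer-related
   response genes;
4. find group-level DE genes per dataset by rank products with
   permutation p-values, merge the lists after dropping
   direction-inconsistent genes → response genes at large; the merged
   list minus the cancer-related set is the cancer-unrelated class;
5. characterise both classes by hypergeometric pathway enrichment and
   by direct-link counts to curated effector / pharmacokinetic gene sets
   in a protein–protein interaction network (Wilcoxon rank-sum).

A synthetic-cohort generator with full ground truth (multi-platform
normals, planted group-asymmetric deregulation, planted marker genes,
PPI graphs with boosted link structure) makes every stage testable
without any external download. See `docs/methods.md` for the model
details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic cohort (500 genes; 21+7+6 normals on three platforms;
38 non-responders and 34 responders over two datasets) and write their
tables under `results/analysis/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_mine_reo_landscape.py
python analysis/03_call_individual_de.py
python analysis/04_group_de_rankproduct.py
python analysis/05_classify_response_genes.py
python analysis/06_pathway_enrichment.py
python analysis/07_ppi_proximity.py
```

Output of a run with the default seed:

```
simulated 34 normal and 72 cancer samples over 500 genes
planted 25 cancer-related genes (854 per-sample events) and 25 marker genes
119111 stable pairs over 500 genes (34 supporting samples)
two-set concordance: 119111/119111 pairs agree (score 1.000, log10 p = -35856.0)
called DE genes in 72 cancer samples (mean 11.2 genes/sample at FDR 0.05)
cancer_ds1: 105 DE genes (200 comparisons, permutation null)
cancer_ds2: 149 DE genes (160 comparisons, permutation null)
shared k=62, same-direction s=56 (score 0.90, p=1.49e-11); merged list holds 186 genes
20 cancer-related response genes (19 shared with the merged group-DE list, 167 cancer-unrelated)
truth recovery: recall 0.76, precision 0.95; background binomial test flags 23 genes
cancer_related: 1 sets at FDR<=0.2; top = planted_cancer_related_pathway (k=19, p=3.16e-28)
cancer_unrelated: 0 sets at FDR<=0.2; top = random_set_16 (k=13, p=5.43e-02)
cancer_related: 197 direct links from 20 mapped genes (average 9.85)
cancer_unrelated: 118 direct links from 167 mapped genes (average 0.71)
rank-sum comparison of link counts: p = 2.62e-15 (normal_approx)
```

Reading the numbers: all 119,111 pairs stable on platform 1 agree in
orientation with the landscape of the other platforms (the cross-platform
premise); the per-sample caller finds on average 11.2 DE genes — close
to the 11.9 planted events per sample; the frequency contrast selects 20
genes of which 19 of 20 are truly planted (precision 0.95), and the
enrichment and PPI stages both single out the planted structure
(the planted pathway at p ≈ 1e-28; ~14× more effector links per
cancer-related gene, rank-sum p ≈ 1e-15).

The same run is available as one command through the CLI
(`reoresp all --outdir results/pipeline --seed 1`), with per-stage
subcommands `simulate`, `landscape`, `rankcomp`, `groupde`, `classes`,
`enrich`, `ppi` and a YAML config (see `reoresp all --help`).

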