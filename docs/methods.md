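# Methods

## Problem and overall model

Genes differentially expressed between chemoradiation responders and
non-responders of locally advanced rectal cancer mix two mechanisms:
genes whose *deregulation relative to normal tissue* differs between the
outcome groups (cancer-related response genes, plausibly acting through
tumour biology), and genes that differ between the groups without being
deregulated relative to normal at group-asymmetric frequency
(cancer-unrelated response genes, plausibly reflecting pharmacokinetics).
Separating the two requires calling differential expression **per
individual cancer sample** against a normal reference, which standard
group statistics cannot do across microarray platforms without risky
between-sample normalisation.

The package's route around this is the relative expression ordering
(REO): within one sample, whether gene *a*'s measured expression exceeds
gene *b*'s is invariant under any strictly increasing per-platform
transform of the measurement scale. The pipeline is:

1. **Stable REO landscape** (`reoresp.landscape`). A gene pair (hi, lo)
   enters the landscape iff expression(hi) > expression(lo) strictly in
   at least `support_threshold` (default 1.0 — every one) of the pooled
   normal samples, over the gene universe shared by all normal datasets.
   Ties support neither orientation, so at full support a single tied
   sample disqualifies a pair. Two independently mined landscapes are
   compared by the fraction *s/k* of shared unordered pairs with equal
   orientation, tested against Binomial(*k*, 0.5): the upper tail
   P(X ≥ s) is computed with `scipy` where representable and otherwise
   exactly in log space by truncated log-pmf summation (the terms decay
   geometrically deep in the tail; truncation error < 1e-15 relative),
   with a Chernoff–Kullback-Leibler bound as a fallback and a Hoeffding
   bound available as an independent certificate.

2. **Individual-sample DE calling** (`reoresp.rankcomp`). For gene X in
   one cancer sample, among its stable partners normally below it
   (n_less) count reversals r_down (X now below the partner, supporting
   downregulation), and among partners normally above it (n_greater)
   count reversals r_up (supporting upregulation). The two reversal
   frequencies are compared with a two-sided Fisher exact test on
   [[r_down, n_less − r_down], [r_up, n_greater − r_up]]; p-values are
   Benjamini–Hochberg adjusted within the sample and calls at FDR ≤ α
   (default 0.05) receive the direction with the larger reversal
   proportion. A filtering pass then re-tests every called gene after
   removing reversal partners that are themselves currently called,
   re-applying BH each round and iterating to a fixed point (cap 100
   rounds), so that calls riding entirely on other deregulated genes are
   removed; the retained set only ever shrinks.

3. **Deregulation-frequency contrast** (`reoresp.response`). Per gene,
   the number of samples calling it DE (direction-agnostic by default)
   is tallied within each outcome group and contrasted with a two-sided
   Fisher test, BH-adjusted across genes; selections at FDR ≤ 0.05 are
   the cancer-related response genes. A pooled binomial test against a
   background call rate p₀ (default = the per-sample α, the expected
   false-call rate under the null) separately flags genes deregulated in
   a non-randomly high share of all cancer samples.

4. **Group-level DE and merging** (`reoresp.groupde`). Per dataset,
   every non-responder × responder sample pair yields per-gene
   log-fold-difference ranks (rank 1 = most up-regulated; ties get
   average ranks); the rank product is the geometric mean over
   comparisons, computed separately for the up and down orientations.
   Significance comes from the null that ranks are uniform and
   independent across comparisons: enumerated exactly when
   G^n_comparisons is small (≤ 5·10⁵), else estimated from pooled Monte
   Carlo rank permutations (default 100 rounds) with an add-one
   correction. All pairwise comparisons are used up to a cap of 200,
   beyond which a seeded random subset is drawn. Dataset lists are
   merged after dropping direction-inconsistent shared genes, and their
   concordance *s/k* is tested with the same binomial model as the
   landscape.

5. **Classification, enrichment, PPI proximity** (`reoresp.response`,
   `reoresp.enrichment`, `reoresp.ppi`). The merged group-DE list is
   partitioned by intersection with the cancer-related set. Gene-class
   over-representation in a GMT collection uses the hypergeometric upper
   tail (equivalently one-sided Fisher), universe = measured genes ∩
   collection coverage, BH across sets, reporting FDR 0.2. PPI proximity
   counts only direct (distance-1) links from each mapped query gene
   into a target set on an undirected simple graph; two per-gene count
   distributions are compared with a two-sided Wilcoxon rank-sum test,
   exact by assignment enumeration while n·m ≤ 400 and by normal
   approximation with tie correction beyond.

## Synthetic cohorts and what they do (not) emulate

`reoresp.synthetic` draws the full study design from one seed
(substreams per stage, so stages can be regenerated independently):

- Gene baselines rise with index in steps of `baseline_spread`
  (default 0.05 log2 units over 500 genes), making the true normal
  ordering explicit and brute-force checkable. Normal cohorts (default
  21 + 7 + 6 samples on three "platforms") add Gaussian noise
  (`noise_sd` = 0.2 log2) and a strictly increasing affine per-platform
  transform, which leaves REOs untouched by construction.
- Cancer samples (default 38 non-responders + 34 responders, split over
  two datasets in the proportions 22/24 and 16/10) start from the same
  normal model. Planted *cancer-related* genes (5% of the universe)
  shift by ±`dereg_effect` (3.0 log2) per sample with group-specific
  probability (0.8 in non-responders vs 0.1 in responders); every event
  is recorded in the ground truth. Planted *marker* genes (5%) shift by
  ±`marker_effect` (0.4 log2) uniformly in every sample of exactly one
  group: large enough for group-level DE, but too small to reverse
  stable pairs (whose expression gaps are ≳ 0.6 log2 at these noise
  settings), so they model pharmacokinetic differences that are not
  deregulations relative to normal.
- `simulate_ppi` draws an Erdős–Rényi background with a boosted edge
  probability between designated query and target sets;
  `simulate_gene_sets` builds random GMT collections with optional
  planted sets.

Deliberately absent: probe-level effects, batch effects, heavy-tailed
noise, correlated gene modules, and real platform annotations. Passing
tests therefore demonstrate correctness of the algorithms under the
generative model, not performance on real microarray data.

### Edge effects of the linear baseline

With a strict baseline ladder, pairs closer than ~0.6 log2 units are not
stable across 34 noisy normals, so genes near either end of the index
range have few or no stable partners on one side. A planted shift toward
the short side then yields a degenerate or powerless 2×2 table (e.g.
[[35, 425], [0, 6]]), and such genes evade per-sample detection even at
effect 3.0; their large traversal simultaneously gives the genes they
pass 2–5 consistent reversals, which the coupled-pair filter cannot
remove because the mover itself is never significant. At the default
scale this caps frequency-contrast recall near 0.8 and lifts its
empirical false-discovery proportion to ≈ 0.1; both effects shrink as
the gene universe grows relative to the shift's rank span.

## Numerical and design choices

- **Fisher exact p** is computed directly from the hypergeometric
  log-pmf over the margin-constrained support (two-sided: sum of
  probabilities ≤ observed, with the customary 1 + 1e-7 tie tolerance);
  `scipy.stats.fisher_exact` and full margin enumeration serve as
  independent cross-checks in the tests.
- **Testability**: genes with fewer than 10 stable partners in total are
  reported as untestable (NONE, missing p); note a gene with zero
  partners on one particular side is formally testable but its table is
  degenerate and p = 1.
- **Support threshold** is restricted to (0.5, 1]: at or below 0.5 both
  orientations of a pair could qualify, violating antisymmetry.
- **Rank-product p-values** are exact only against the
  independent-uniform-rank null. When comparisons share samples (all
  pairwise fold changes), observed rank products have heavier tails, and
  BH at 5% can admit roughly twice the nominal fraction under a global
  null; the bulk of the p distribution remains uniform-like. This is the
  cost of replacing the original percentage-of-false-prediction
  machinery with permutation p + BH and is inherited by downstream
  merged-list sizes.
- **Determinism**: every stochastic stage takes a seed or derives one
  from the cohort seed via `numpy` `SeedSequence` spawning; reruns are
  bit-identical.
- **Scale**: the pair landscape is O(G²·N) time and O(G²) memory, capped
  at G = 10,000 genes; analyses in this repository use the 500-gene
  default cohort, where the full pipeline runs in seconds.

## Known limitations

- Degenerate power at the extremes of the synthetic baseline (above).
- The rank-sum normal approximation is used whenever n·m > 400; exact
  mid-p or network-based alternatives are not implemented.
- The pooled landscape equals the intersection of per-dataset landscapes
  only at support threshold 1.0 (a property the tests assert); at lower
  thresholds pooling is the primary definition.
- Enrichment assumes the query was measured on the same universe as the
  collection; no size-bias or overlap-aware corrections.
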