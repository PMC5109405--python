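"""Individual-sample DE calling: reversal counts, Fisher test, filtering."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from reoresp.core import DOWN, NONE, UP
from reoresp.landscape import find_stable_pairs
from reoresp.rankcomp import (
    call_de_single_sample,
    calls_to_frame,
    filter_de_calls,
    fisher_exact_2x2,
    reversal_counts,
    run_rankcomp,
)

from conftest import make_matrix


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p by enumerating all tables with the
    observed margins."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if n == 0 or 0 in (row1, row2) or col1 in (0, n):
        return 1.0
    total = comb(n, col1)
    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / total
    observed = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, col1 - row2), min(col1, row1) + 1)
        if prob(x) <= observed * (1 + 1e-9)
    )


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((0, 10, 0, 12), 1.0),
            ((5, 0, 0, 5), 2 / comb(10, 5)),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            ours = fisher_exact_2x2(a, b, c, d)
            assert ours == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestReversalCounts:
    def test_sample_matching_normal_order_has_no_reversals(self):
        normals = make_matrix(np.linspace(5, 1, 6)[:, None] + np.zeros((6, 3)))
        stable = find_stable_pairs([normals])
        sample = pd.Series(np.linspace(5, 1, 6), index=normals.gene_ids)
        t = reversal_counts(sample, "g3", stable)
        assert (t.r_up, t.r_down) == (0, 0)
        assert (t.n_less, t.n_greater) == (3, 2)

    def test_gene_moved_above_every_partner(self):
        normals = make_matrix(np.linspace(5, 1, 6)[:, None] + np.zeros((6, 3)))
        stable = find_stable_pairs([normals])
        sample = pd.Series(np.linspace(5, 1, 6), index=normals.gene_ids)
        sample["g6"] = 10.0
        t = reversal_counts(sample, "g6", stable)
        assert t.r_up == t.n_greater == 5
        assert t.r_down == 0

    def test_matches_exhaustive_pair_loop(self):
        rng = np.random.default_rng(1)
        normals = make_matrix(rng.normal(size=(6, 8)))
        stable = find_stable_pairs([normals])
        sample = pd.Series(rng.normal(size=6), index=normals.gene_ids)
        pairs = stable.pairs
        for gene in normals.gene_ids:
            t = reversal_counts(sample, gene, stable)
            less = [lo for (hi, lo) in pairs if hi == gene]
            greater = [hi for (hi, lo) in pairs if lo == gene]
            assert t.n_less == len(less)
            assert t.n_greater == len(greater)
            assert t.r_down == sum(sample[gene] < sample[x] for x in less)
            assert t.r_up == sum(sample[gene] > sample[y] for y in greater)

    def test_unknown_gene_rejected(self):
        normals = make_matrix(np.linspace(3, 1, 3)[:, None])
        stable = find_stable_pairs([normals])
        with pytest.raises(KeyError):
            reversal_counts(
                pd.Series([1.0, 2.0, 3.0], index=normals.gene_ids), "nope", stable
            )


def naive_call_reference(sample, stable, min_partners=10):
    """Independent per-gene loop computing the Fisher p-vector."""
    out = {}
    for gene in stable.genes:
        t = reversal_counts(sample, gene, stable)
        if t.n_less + t.n_greater < min_partners:
            out[gene] = np.nan
        else:
            out[gene] = scipy.stats.fisher_exact(
                [[t.r_down, t.n_less - t.r_down], [t.r_up, t.n_greater - t.r_up]]
            )[1]
    return pd.Series(out)


class TestCallSingleSample:
    def test_planted_jump_called_up(self):
        # a near-bottom gene jumps above everything; the very bottom gene has
        # no stable partners below it, leaving its 2x2 table degenerate
        n_genes = 200
        baseline = np.arange(n_genes) * 0.2
        rng = np.random.default_rng(2)
        normals = make_matrix(baseline[:, None] + rng.normal(0, 0.05, (n_genes, 10)))
        stable = find_stable_pairs([normals])
        sample = pd.Series(baseline + rng.normal(0, 0.05, n_genes),
                           index=normals.gene_ids, name="case")
        sample.iloc[5] = baseline[-1] + 5.0
        call = call_de_single_sample(sample, stable, alpha=0.05)
        assert call.table.loc[normals.gene_ids[5], "direction"] == UP

    def test_pvalues_match_naive_reference(self):
        rng = np.random.default_rng(3)
        normals = make_matrix(rng.normal(size=(50, 12)))
        stable = find_stable_pairs([normals])
        sample = pd.Series(rng.normal(size=50), index=normals.gene_ids)
        call = call_de_single_sample(sample, stable)
        ref = naive_call_reference(sample, stable)
        pd.testing.assert_series_equal(
            call.table["p"], ref.rename("p"), rtol=1e-7, check_names=False
        )

    def test_direction_swaps_under_negation(self):
        rng = np.random.default_rng(4)
        values = np.arange(30)[:, None] * 0.3 + rng.normal(0, 0.05, (30, 8))
        normals = make_matrix(values)
        sample = pd.Series(values[:, 0], index=normals.gene_ids)
        sample.iloc[5] += 6.0
        sample.iloc[20] -= 6.0
        stable = find_stable_pairs([normals])
        call = call_de_single_sample(sample, stable)

        neg = make_matrix(-values)
        neg_stable = find_stable_pairs([neg])
        neg_call = call_de_single_sample(-sample, neg_stable)
        swap = {UP: DOWN, DOWN: UP, NONE: NONE}
        assert list(neg_call.table["direction"]) == [
            swap[d] for d in call.table["direction"]
        ]
        np.testing.assert_allclose(neg_call.table["p"], call.table["p"])


class TestFilter:
    def _setup(self, seed=5, n_genes=60, planted=()):
        rng = np.random.default_rng(seed)
        values = np.arange(n_genes)[:, None] * 0.25 + rng.normal(
            0, 0.1, (n_genes, 10)
        )
        normals = make_matrix(values)
        stable = find_stable_pairs([normals])
        sample = pd.Series(
            np.arange(n_genes) * 0.25 + rng.normal(0, 0.1, n_genes),
            index=normals.gene_ids,
        )
        for idx, shift in planted:
            sample.iloc[idx] += shift
        return stable, sample

    def test_no_de_genes_unchanged(self):
        stable, sample = self._setup()
        call = call_de_single_sample(sample, stable)
        assert not call.de_genes
        filtered = filter_de_calls(call, stable, sample)
        assert filtered.filter_iterations == 0
        pd.testing.assert_frame_equal(filtered.table, call.table)

    def test_independent_de_gene_retained_with_same_p(self):
        stable, sample = self._setup(planted=[(30, 5.0)])
        call = call_de_single_sample(sample, stable)
        gene = sample.index[30]
        assert gene in call.de_genes
        filtered = filter_de_calls(call, stable, sample)
        assert gene in filtered.de_genes

    def test_filtered_set_is_subset_and_drops_are_justified(self):
        stable, sample = self._setup(seed=6, planted=[(10, 8.0), (45, -8.0)])
        call = call_de_single_sample(sample, stable)
        filtered = filter_de_calls(call, stable, sample)
        assert set(filtered.de_genes) <= set(call.de_genes)
        # every surviving gene is still significant in its reduced table
        de = set(filtered.de_genes)
        values = sample.reindex(stable.genes).to_numpy()
        for gene in de:
            i = stable.genes.index(gene)
            keep = np.array([g not in de or g == gene for g in stable.genes])
            below = stable.greater[i, :] & keep
            above = stable.greater[:, i] & keep
            rd = int((below & (values[i] < values)).sum())
            ru = int((above & (values < values[i])).sum())
            p = fisher_exact_2x2(rd, int(below.sum()) - rd, ru, int(above.sum()) - ru)
            assert p == pytest.approx(filtered.table.loc[gene, "p"], rel=1e-9)


class TestRunRankcomp:
    def test_copies_of_normal_sample_yield_no_calls(self, small_cohort, small_stable):
        _, normals, _, _ = small_cohort
        base = normals[0]
        # one normal-model sample replicated as a pseudo-cancer cohort
        rep = base.values.iloc[:, [0, 0, 0]].copy()
        rep.columns = ["c1", "c2", "c3"]
        cancer = make_matrix(rep.to_numpy(), group="responder")
        cancer.values.index = base.gene_ids
        calls = run_rankcomp(cancer.restrict(small_stable.genes), small_stable)
        assert all(len(c.de_genes) == 0 for c in calls)

    def test_sample_permutation_equivariance(self, small_cohort, small_stable):
        _, _, cancers, _ = small_cohort
        sub = cancers.restrict(small_stable.genes)
        calls = run_rankcomp(sub, small_stable)
        permuted = sub.select_samples(list(reversed(sub.sample_ids)))
        calls_perm = run_rankcomp(permuted, small_stable)
        by_id = {c.sample_id: c for c in calls}
        for c in calls_perm:
            pd.testing.assert_frame_equal(c.table, by_id[c.sample_id].table)

    def test_planted_events_recovered(self, small_cohort, small_stable):
        _, _, cancers, truth = small_cohort
        calls = run_rankcomp(cancers.restrict(small_stable.genes), small_stable)
        frame = calls_to_frame(calls)
        called = set(zip(frame["sample_id"], frame["gene"]))
        planted = set(zip(truth.events["sample"], truth.events["gene"]))
        recall = len(called & planted) / len(planted)
        precision = len(called & planted) / max(len(called), 1)
        assert recall > 0.6
        assert precision > 0.6
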