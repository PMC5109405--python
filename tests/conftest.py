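import numpy as np
import pandas as pd
import pytest

from reoresp.core import ExpressionMatrix
from reoresp.landscape import StableREOSet, find_stable_pairs
from reoresp.synthetic import CohortConfig, simulate_cohort


def make_matrix(values, group="normal", label="ds", prefix="s"):
    """ExpressionMatrix from a 2-D array (genes x samples)."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i + 1}" for i in range(values.shape[0])]
    samples = [f"{prefix}{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(group, index=samples)
    return ExpressionMatrix(df, groups, label)


def brute_force_stable_pairs(matrices, support_threshold=1.0):
    """Independent double-loop oracle for stable-pair mining."""
    genes = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        genes &= set(m.gene_ids)
    genes = sorted(genes)
    columns = []
    for m in matrices:
        for s in m.sample_ids:
            columns.append(m.values.loc[genes, s])
    n = len(columns)
    pairs = set()
    for a in genes:
        for b in genes:
            if a == b:
                continue
            support = sum(1 for col in columns if col[a] > col[b])
            if support / n >= support_threshold - 1e-12:
                pairs.add((a, b))
    return pairs


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 80-gene cohort with planted structure, shared across tests."""
    config = CohortConfig(
        n_genes=80,
        genes_per_platform=80,
        n_normal_per_platform=(8, 5, 4),
        n_responders=8,
        n_nonresponders=10,
        baseline_spread=0.15,
        noise_sd=0.15,
        frac_cancer_related=0.1,
        dereg_effect=3.0,
        frac_cancer_unrelated_marker=0.1,
        seed=7,
    )
    normals, cancers, truth = simulate_cohort(config)
    return config, normals, cancers, truth


@pytest.fixture(scope="session")
def small_stable(small_cohort):
    _, normals, _, _ = small_cohort
    return find_stable_pairs(normals)
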