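"""Shared containers and small statistical helpers.

The central in-memory object is :class:`ExpressionMatrix`, a gene x sample
log2 expression table with per-sample group labels (``normal``,
``responder``, ``nonresponder``) and a dataset/platform label. All
downstream stages consume this container; preprocessing that produces it
(probe summarisation, background correction) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

VALID_GROUPS = frozenset({"normal", "responder", "nonresponder"})

UP = "UP"
DOWN = "DOWN"
NONE = "NONE"


class ConfigurationError(ValueError):
    """Raised for invalid parameter combinations."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values for a gene universe across named samples.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    groups
        Series mapping sample id to its group label.
    dataset_label
        Name of the dataset/platform the samples came from. Cohorts
        spanning several datasets may additionally carry a per-sample
        ``datasets`` series.
    """

    values: pd.DataFrame
    groups: pd.Series
    dataset_label: str = "dataset"
    datasets: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.values.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups) - VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.datasets is None:
            self.datasets = pd.Series(
                self.dataset_label, index=self.values.columns, name="dataset"
            )
        else:
            self.datasets = self.datasets.reindex(self.values.columns)
            if self.datasets.isna().any():
                raise ValueError("every sample needs a dataset label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, genes) -> "ExpressionMatrix":
        """Subset to ``genes`` (order preserved from the argument)."""
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes].copy(),
            self.groups.copy(),
            self.dataset_label,
            self.datasets.copy(),
        )

    def select_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples].copy(),
            self.groups.loc[samples].copy(),
            self.dataset_label,
            self.datasets.loc[samples].copy(),
        )

    def split_by_dataset(self) -> dict[str, "ExpressionMatrix"]:
        out = {}
        for label in self.datasets.unique():
            samples = self.datasets.index[self.datasets == label]
            sub = self.select_samples(samples)
            sub.dataset_label = str(label)
            out[str(label)] = sub
        return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
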