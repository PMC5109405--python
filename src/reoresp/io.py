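"""Plain-text readers and writers for the pipeline's file formats.

Expression matrices travel as TSV (rows = gene ids, columns = sample ids,
log2 values) next to a sample-metadata TSV (sample_id, group, dataset);
stable pairs as (optionally gzipped) two-column TSV; PPI networks as
two-column edge lists; gene categories as GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .landscape import StableREOSet

__all__ = [
    "write_expression",
    "read_expression",
    "write_pairs",
    "read_pairs",
    "write_edgelist",
]


def write_expression(matrix: ExpressionMatrix, values_path, metadata_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene_id")
    meta = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": matrix.groups.values,
            "dataset": matrix.datasets.values,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression(values_path, metadata_path, dataset_label=None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample_id")
    label = dataset_label or (meta["dataset"].iloc[0] if len(meta) else "dataset")
    return ExpressionMatrix(
        values,
        meta["group"].reindex(values.columns),
        str(label),
        meta["dataset"].reindex(values.columns),
    )


def write_pairs(stable: StableREOSet, path) -> None:
    """Stable pairs as TSV (hi_gene, lo_gene); gzip inferred from suffix."""
    hi, lo = np.nonzero(stable.greater)
    df = pd.DataFrame(
        {
            "hi_gene": [stable.genes[i] for i in hi],
            "lo_gene": [stable.genes[j] for j in lo],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path, support_threshold: float = 1.0,
               n_supporting_samples: int = 0) -> StableREOSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = sorted(set(df["hi_gene"]) | set(df["lo_gene"]))
    index = {g: i for i, g in enumerate(genes)}
    greater = np.zeros((len(genes), len(genes)), dtype=bool)
    for hi, lo in zip(df["hi_gene"], df["lo_gene"]):
        greater[index[hi], index[lo]] = True
    return StableREOSet(genes, greater, support_threshold, n_supporting_samples)


def write_edgelist(edges, path) -> None:
    with open(Path(path), "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
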