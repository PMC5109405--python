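"""Curated chemoradiation-response gene categories.

The bundled GMT is a synthetic stand-in for the curated supplementary gene
lists of the original study (which are not redistributable here): plausible
human gene symbols at the published category sizes — 28 pharmacokinetic
(drug metabolism/transport), 47 purine/pyrimidine metabolism, 17
downstream 5-FU effector and 21 radio-response genes. The purine/
pyrimidine, 5-FU effector and radio-response categories together form the
85 *effective* genes; all four categories total 113 genes.
"""

from __future__ import annotations

from importlib import resources

from .enrichment import read_gmt

__all__ = ["load_categories", "effective_genes", "pharmacokinetic_genes",
           "EFFECTIVE_CATEGORY_NAMES"]

EFFECTIVE_CATEGORY_NAMES = (
    "purine_pyrimidine_metabolism",
    "fu_downstream_effectors",
    "radio_response",
)

_GMT = "synthetic_pcrt_gene_categories.gmt"


def load_categories() -> dict:
    """Named curated categories as sets of gene symbols."""
    path = resources.files("reoresp.data").joinpath(_GMT)
    with resources.as_file(path) as p:
        return read_gmt(p)


def effective_genes(categories: dict | None = None) -> set:
    """Union of the three effector-side categories (85 genes)."""
    categories = categories or load_categories()
    out: set = set()
    for name in EFFECTIVE_CATEGORY_NAMES:
        out |= categories[name]
    return out


def pharmacokinetic_genes(categories: dict | None = None) -> set:
    categories = categories or load_categories()
    return set(categories["pharmacokinetic"])
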