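"""Loader for the bundled published count tables.

The package ships the printed contingency data of the source study
(cluster-by-group subject counts, per-stratum genotype counts and the
MetS cluster-1 vs cluster-2 genotype tables) as a JSON fixture, so the
association machinery can be exercised and checked without simulating.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np


def load_published_counts() -> dict:
    with resources.files("fadsmets.data").joinpath("published_counts.json").open() as fh:
        return json.load(fh)


def cluster_by_group_table() -> np.ndarray:
    """2x2 subject counts: rows (MetS, CON) x columns (cluster 1, cluster 2)."""
    return np.array(load_published_counts()["cluster_by_group"]["table"])


def mets_cluster_genotype_tables() -> dict[str, np.ndarray]:
    """Per-SNP 2x3 genotype tables, rows (MetS1, MetS2), columns (AA, Aa, aa)."""
    raw = load_published_counts()["mets_cluster_genotype_tables"]
    return {k: np.array(v) for k, v in raw.items() if k.startswith("rs")}


def genotype_counts_by_stratum() -> dict[str, dict[str, np.ndarray]]:
    """Per-SNP, per-stratum (AA, Aa, aa) genotype counts."""
    raw = load_published_counts()["genotype_counts_by_stratum"]
    return {snp: {g: np.array(c) for g, c in by.items()} for snp, by in raw.items()}
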