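"""Per-SNP allele/genotype tables, chi-square tests, HWE and BH adjustment.

Conventions follow the study protocol: genotype (2x3) case-control tables
are tested with the uncorrected Pearson chi-square, allele (2x2) tables
with Yates' continuity correction (|O-E| - 0.5, floored at zero), and the
Hardy-Weinberg test uses expected counts n*(p^2, 2pq, q^2) with one degree
of freedom (one estimated allele frequency).  Benjamini-Hochberg adjustment
is applied per comparison family across a scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .genio import MISSING, GenotypeMatrix


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    correction: str = "none"  # "none" or "yates"
    p_adjusted: float | None = None


def pearson_chi2(table, correction: str = "none") -> ContingencyResult:
    """Pearson chi-square on an r x c table; Yates correction for 2x2 only."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("need a non-negative 2-D table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        zero_rows = list(np.where(row == 0)[0])
        zero_cols = list(np.where(col == 0)[0])
        raise ValueError(f"zero margin (rows {zero_rows}, cols {zero_cols})")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "yates" and obs.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    exp = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - exp)
    if correction == "yates":
        dev = np.clip(dev - 0.5, 0.0, None)
    stat = float((dev**2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(
        observed=obs, expected=exp, chi2=stat, df=df,
        p_value=float(chi2_dist.sf(stat, df)), correction=correction,
    )


def genotype_table(geno: GenotypeMatrix, snp_id: str, grouping) -> np.ndarray:
    """2x3 genotype counts (AA, Aa, aa by declared major allele) per group.

    ``grouping`` is a per-subject label with exactly two levels; subjects
    with missing calls at the SNP are dropped (count logged via warning).
    """
    col = geno.column(snp_id)
    groups = np.asarray(grouping)
    if len(groups) != geno.n_subjects:
        raise ValueError("grouping length does not match genotype matrix")
    levels = _two_levels(groups)
    n_missing = int((col == MISSING).sum())
    if n_missing:
        warnings.warn(f"{snp_id}: dropping {n_missing} missing genotypes")
    table = np.zeros((2, 3), dtype=int)
    for r, lev in enumerate(levels):
        mask = (groups == lev) & (col != MISSING)
        if not mask.any():
            raise ValueError(f"empty stratum {lev!r} at {snp_id}")
        for d in (0, 1, 2):
            table[r, d] = int((col[mask] == d).sum())
    return table


def _two_levels(groups: np.ndarray) -> list:
    levels = list(dict.fromkeys(groups))  # first-appearance order
    if len(levels) != 2:
        raise ValueError(f"grouping must have two levels, got {levels}")
    return levels


def allele_table(genotype_tab) -> np.ndarray:
    """Collapse a 2x3 genotype table to 2x2 allele counts (A = 2AA + Aa)."""
    g = np.asarray(genotype_tab, dtype=int)
    if g.shape != (2, 3):
        raise ValueError("expected a 2x3 genotype table")
    return np.column_stack([2 * g[:, 0] + g[:, 1], g[:, 1] + 2 * g[:, 2]])


def hwe_test(genotype_counts) -> ContingencyResult:
    """Hardy-Weinberg chi-square with df = 1 on (AA, Aa, aa) counts."""
    obs = np.asarray(genotype_counts, dtype=float)
    if obs.shape != (3,) or obs.min() < 0:
        raise ValueError("need non-negative counts (AA, Aa, aa)")
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic locus: HWE test undefined, returning p = 1")
        exp = obs.copy()
        return ContingencyResult(obs, exp, 0.0, 1, 1.0)
    exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    stat = float(((obs - exp) ** 2 / exp).sum())
    return ContingencyResult(obs, exp, stat, 1, float(chi2_dist.sf(stat, 1)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SnpScanResult:
    snp_id: str
    genotype: ContingencyResult          # 2x3, uncorrected
    allele: ContingencyResult            # 2x2, Yates
    hwe_by_stratum: dict                 # level -> ContingencyResult


def association_scan(geno: GenotypeMatrix, grouping, snp_ids=None) -> list[SnpScanResult]:
    """Genotype + allele case-control tests and per-stratum HWE for each SNP,
    with BH adjustment across the genotype family and across the allele
    family separately."""
    if snp_ids is None:
        snp_ids = geno.snp_ids
    if len(snp_ids) == 0:
        raise ValueError("no SNPs requested")
    groups = np.asarray(grouping)
    levels = _two_levels(groups)
    results = []
    for sid in snp_ids:
        gt = genotype_table(geno, sid, groups)
        cols = gt.sum(axis=0) > 0  # drop genotype classes absent from both strata
        g_res = pearson_chi2(gt[:, cols], correction="none")
        g_res.observed = gt
        a_res = pearson_chi2(allele_table(gt), correction="yates")
        hwe = {lev: hwe_test(gt[r]) for r, lev in enumerate(levels)}
        results.append(SnpScanResult(sid, g_res, a_res, hwe))
    for family in ("genotype", "allele"):
        adj = bh_adjust([getattr(r, family).p_value for r in results])
        for r, q in zip(results, adj):
            getattr(r, family).p_adjusted = float(q)
    return results
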