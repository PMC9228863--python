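"""Fatty-acid panel summaries, desaturase indices, HOMA-IR and group tests.

The panel is the 18 plasma-phospholipid fatty acids reported as percent of
total esterified FA, keyed by the usual shorthand ``carbons:double-bonds
n-position`` (e.g. ``"20:3n-6"`` for dihomo-gamma-linolenic acid).
Desaturase activities are estimated as product/precursor ratios computed
per subject, never as ratios of group summaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FA_PANEL = [
    "14:0", "16:0", "16:1n-9", "16:1n-7", "18:0", "18:1n-9", "18:1n-7",
    "18:2n-6", "18:3n-6", "18:3n-3", "20:2n-6", "20:3n-6", "20:4n-6",
    "20:5n-3", "22:4n-6", "22:5n-6", "22:5n-3", "22:6n-3",
]

# Family membership: the n-position suffix determines the family; saturated
# and monounsaturated acids are split on double-bond count.
SFA = ["14:0", "16:0", "18:0"]
MFA = ["16:1n-9", "16:1n-7", "18:1n-9", "18:1n-7"]
N6 = ["18:2n-6", "18:3n-6", "20:2n-6", "20:3n-6", "20:4n-6", "22:4n-6", "22:5n-6"]
N3 = ["18:3n-3", "20:5n-3", "22:5n-3", "22:6n-3"]

_SHORTHAND = re.compile(r"^(\d+):(\d+)(n-(\d+))?$")


def parse_shorthand(name: str) -> tuple[int, int, int | None]:
    """Parse ``carbons:double-bonds[n-position]`` shorthand."""
    m = _SHORTHAND.match(name)
    if not m:
        raise ValueError(f"not a fatty-acid shorthand: {name!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(4)) if m.group(4) else None


def fa_sums(profile) -> dict[str, float]:
    """Family sums (percent): saturated, monounsaturated, n-6, n-3."""
    def total(keys):
        try:
            return float(sum(profile[k] for k in keys))
        except KeyError as e:
            raise KeyError(f"profile missing fatty acid {e.args[0]!r}") from None

    return {
        "sum_sfa": total(SFA),
        "sum_mfa": total(MFA),
        "sum_n6": total(N6),
        "sum_n3": total(N3),
    }


def desaturase_indices(profile) -> dict[str, float]:
    """Product/precursor desaturase indices.

    D9D-16 = 16:1n-7/16:0, D9D-18 = 18:1n-9/18:0, D6D = 18:3n-6/18:2n-6,
    D5D = 20:4n-6/20:3n-6.  A zero denominator yields NaN (flagged
    undefined), not an exception.
    """
    def ratio(num, den):
        d = profile[den]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(np.asarray(d) > 0, np.asarray(profile[num]) / np.asarray(d), np.nan)
        return float(out) if out.ndim == 0 else out

    return {
        "d9d16": ratio("16:1n-7", "16:0"),
        "d9d18": ratio("18:1n-9", "18:0"),
        "d6d_n6": ratio("18:3n-6", "18:2n-6"),
        "d5d_n6": ratio("20:4n-6", "20:3n-6"),
    }


def add_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append family sums and desaturase indices to a cohort table."""
    out = table.copy()
    out["sum_sfa"] = out[SFA].sum(axis=1)
    out["sum_mfa"] = out[MFA].sum(axis=1)
    out["sum_n6"] = out[N6].sum(axis=1)
    out["sum_n3"] = out[N3].sum(axis=1)
    idx = desaturase_indices({k: out[k].to_numpy(float) for k in FA_PANEL})
    for k, v in idx.items():
        out[k] = v
    return out


def homa_ir(insulin_mU_per_L, glucose_mmol_per_L):
    """Insulin-resistance index: fasting insulin x fasting glucose / 22.5."""
    ins = np.asarray(insulin_mU_per_L, dtype=float)
    glu = np.asarray(glucose_mmol_per_L, dtype=float)
    if (ins < 0).any() or (glu < 0).any():
        raise ValueError("insulin and glucose must be non-negative")
    out = ins * glu / 22.5
    return float(out) if out.ndim == 0 else out


@dataclass
class GroupComparison:
    trait: str
    test: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_groups(table: pd.DataFrame, trait: str, group_col: str,
                   group_a: str, group_b: str, alpha_normality: float = 0.05
                   ) -> GroupComparison:
    """Two-group comparison: t-test if both samples pass Shapiro-Wilk
    normality at ``alpha_normality``, else Wilcoxon rank-sum."""
    xa = table.loc[table[group_col] == group_a, trait].dropna().to_numpy(float)
    xb = table.loc[table[group_col] == group_b, trait].dropna().to_numpy(float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 observations per group")
    use_t = False
    if np.ptp(xa) > 0 and np.ptp(xb) > 0:
        use_t = (stats.shapiro(xa).pvalue > alpha_normality
                 and stats.shapiro(xb).pvalue > alpha_normality)
    else:
        warnings.warn(f"{trait}: constant within a group; rank-sum fallback")
    if use_t:
        res = stats.ttest_ind(xa, xb)
        return GroupComparison(trait, "t", float(res.statistic), float(res.pvalue),
                               len(xa), len(xb))
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    return GroupComparison(trait, "wilcoxon", float(res.statistic), float(res.pvalue),
                           len(xa), len(xb))


def compare_many(table: pd.DataFrame, traits: list[str], group_col: str,
                 group_a: str, group_b: str) -> pd.DataFrame:
    """Batch comparisons with Benjamini-Hochberg adjustment across traits."""
    rows = [compare_groups(table, t, group_col, group_a, group_b) for t in traits]
    df = pd.DataFrame({
        "trait": [r.trait for r in rows],
        "test": [r.test for r in rows],
        "statistic": [r.statistic for r in rows],
        "p_raw": [r.p_value for r in rows],
    })
    df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def ancova_group_effect(table: pd.DataFrame, trait: str, group_col: str,
                        covariate: str) -> dict:
    """Linear model ``trait ~ group + covariate``; test of the group effect."""
    import statsmodels.formula.api as smf

    df = table[[trait, group_col, covariate]].dropna().copy()
    if len(df) <= 3:
        raise ValueError("need more than 3 complete observations")
    if df[covariate].nunique() < 2:
        raise ValueError("covariate is constant")
    df = df.rename(columns={trait: "_y", group_col: "_g", covariate: "_x"})
    codes, levels = pd.factorize(df["_g"])
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    if df.groupby("_g")["_x"].nunique().min() < 2 and df["_x"].nunique() == 2:
        raise ValueError("group and covariate are collinear")
    fit = smf.ols("_y ~ C(_g) + _x", data=df).fit()
    term = [t for t in fit.params.index if t.startswith("C(_g)")][0]
    return {
        "effect": float(fit.params[term]),
        "p_value": float(fit.pvalues[term]),
        "covariate_coef": float(fit.params["_x"]),
        "levels": list(levels),
        "n": len(df),
    }


def summarize_trait(x: np.ndarray, alpha_normality: float = 0.05) -> str:
    """mean +/- SD when Shapiro-Wilk accepts normality, else median/IQR."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) >= 3 and np.ptp(x) > 0 and stats.shapiro(x).pvalue > alpha_normality:
        return f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g}/{q3 - q1:.3g}"
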