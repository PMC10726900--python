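"""Phenotype derivations and descriptive change tests.

Leg lean mass (DXA fat-free leg mass minus bone mineral content), bilateral
averaging of dynamometry values, within-arm paired t-tests on changes, and
between-arm Wilcoxon rank-sum tests on changes (exact for small tie-free
samples, normal approximation with continuity correction otherwise).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .types import VISITS


def leg_lean_mass(fat_free_mass_leg: float, bone_content_leg: float) -> float:
    """Fat-free leg mass minus bone mineral content, in kg."""
    if fat_free_mass_leg < 0 or bone_content_leg < 0:
        raise ValueError("masses must be nonnegative")
    out = fat_free_mass_leg - bone_content_leg
    if out < 0:
        raise ValueError("bone content exceeds fat-free mass")
    return out


def average_bilateral(left: float | None, right: float | None) -> tuple[float, bool]:
    """Mean of the present sides; a single-side value passes through with a
    flag.  Returns (value, single_side_flag); (nan, False) when both are
    missing."""
    def missing(v):
        return v is None or (isinstance(v, float) and math.isnan(v))
    lm, rm = missing(left), missing(right)
    if lm and rm:
        return float("nan"), False
    if lm:
        return float(right), True
    if rm:
        return float(left), True
    return (float(left) + float(right)) / 2.0, False


def paired_change_test(pre: np.ndarray, post: np.ndarray) -> dict:
    """Paired t-test on post - pre; all-zero differences yield p = 1 with a
    degenerate flag (zero variance leaves t undefined)."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    if len(pre) < 2 or len(pre) != len(post):
        raise ValueError("need >= 2 pairs")
    d = post - pre
    if np.allclose(d, 0) or np.std(d, ddof=1) == 0:
        return {"stat": 0.0, "p": 1.0, "degenerate": True, "n": len(d)}
    t, p = stats.ttest_rel(post, pre)
    return {"stat": float(t), "p": float(p), "degenerate": False, "n": len(d)}


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray,
                      alternative: str = "two-sided",
                      exact_max_n: int = 25) -> dict:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have <= ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with continuity correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties)
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return {"stat": float(res.statistic), "p": float(res.pvalue), "exact": exact}


def change_tests(pheno: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Within-arm paired t and between-arm Wilcoxon tests of baseline-to-
    follow-up changes of one phenotype column.

    ``pheno`` is tidy with subject_id, group, visit and the value column.
    One row per (test, follow-up visit); within-arm tests compare baseline
    against the follow-up in subjects attending both, between-arm tests
    compare the CR and AL change distributions.
    """
    wide = pheno.pivot_table(index=["subject_id", "group"], columns="visit",
                             values=value_col, aggfunc="first")
    rows = []
    for visit in [v for v in VISITS if v != "Ba" and v in wide.columns]:
        both = wide[["Ba", visit]].dropna()
        groups = both.index.get_level_values("group")
        for arm in ("CR", "AL"):
            sub = both[groups == arm]
            if len(sub) < 2:
                continue
            r = paired_change_test(sub["Ba"].to_numpy(), sub[visit].to_numpy())
            rows.append({"test": "paired_t", "arm": arm, "visit": visit,
                         "stat": r["stat"], "p": r["p"], "n": r["n"],
                         "exact": not r["degenerate"]})
        d_cr = (both[visit] - both["Ba"])[groups == "CR"].to_numpy()
        d_al = (both[visit] - both["Ba"])[groups == "AL"].to_numpy()
        if len(d_cr) >= 2 and len(d_al) >= 2:
            r = wilcoxon_rank_sum(d_cr, d_al)
            rows.append({"test": "wilcoxon_between_arm", "arm": "CR_vs_AL",
                         "visit": visit, "stat": r["stat"], "p": r["p"],
                         "n": len(d_cr) + len(d_al), "exact": r["exact"]})
    return pd.DataFrame(rows)
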