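"""Pathway-score mediation of the CR effect on mass-adjusted strength.

Pathway scores are per-sample means of z-scored (across all samples)
log2-CPM expression over a pathway's leading-edge genes.  Subject-level
changes (baseline to 24 months, falling back to 12 months) of strength,
mass and pathway scores are Z-transformed and fed to ordinary
least-squares models:

    base:     DeltaStrength ~ Group + DeltaMass + Sex
    adjusted: base + DeltaPathway_1 ... DeltaPathway_k      (k = 1..4)

Percent mediation is the relative reduction in |beta_Group| between the two;
combinations attenuating it by at least the threshold (default 20%) are
reported as partial mediation.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import VISITS


def pathway_scores(expr: pd.DataFrame, leading_edges: dict[str, list[str]]) -> pd.DataFrame:
    """samples x pathways score matrix: z-score each gene across all
    samples, then average within each pathway's gene list per sample."""
    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
    cols = {}
    for name, genes in leading_edges.items():
        present = [g for g in genes if g in z.index]
        if not present:
            raise ValueError(f"pathway {name!r} has no genes in the expression matrix")
        cols[name] = z.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


def delta_scores(values: pd.DataFrame, value_cols: list[str],
                 standardize: bool = True) -> pd.DataFrame:
    """Per-subject changes with the 24-month-else-12-month rule.

    ``values`` is tidy with subject_id, visit and the value columns; delta =
    value(24mo) - value(Ba), falling back to 12mo when the 24-month visit is
    missing.  Subjects without a baseline or without any follow-up are
    dropped.  Deltas are then Z-transformed column-wise (unless
    ``standardize=False``); passthrough columns (group, sex) are kept from
    the subject's first row.
    """
    keep_cols = [c for c in ("group", "sex") if c in values.columns]
    rows = []
    for sid, grp in values.groupby("subject_id"):
        byv = grp.set_index("visit")
        if "Ba" not in byv.index:
            continue
        follow = "24mo" if "24mo" in byv.index else ("12mo" if "12mo" in byv.index else None)
        if follow is None:
            continue
        row = {"subject_id": sid, "followup_visit": follow}
        for c in keep_cols:
            row[c] = grp[c].iloc[0]
        for c in value_cols:
            row[f"delta_{c}"] = byv.loc[follow, c] - byv.loc["Ba", c]
        rows.append(row)
    out = pd.DataFrame(rows)
    if standardize and not out.empty:
        for c in value_cols:
            col = out[f"delta_{c}"]
            sd = col.std(ddof=1)
            out[f"delta_{c}"] = (col - col.mean()) / sd if sd > 0 else col * 0.0
    return out


def _design(deltas: pd.DataFrame, strength_var: str,
            pathway_cols: list[str] | None = None):
    y = deltas[f"delta_{strength_var}"].to_numpy(dtype=float)
    X = pd.DataFrame({
        "Group": (deltas["group"] == "CR").astype(float),
        "DeltaMass": deltas["delta_leg_lean_mass"].to_numpy(dtype=float),
        "Sex": (deltas["sex"] == "M").astype(float),
    })
    for c in pathway_cols or []:
        X[c] = deltas[f"delta_{c}"].to_numpy(dtype=float)
    X = sm.add_constant(X)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    return y[mask], X[mask]


def fit_base_model(deltas: pd.DataFrame, strength_var: str) -> dict:
    """OLS of standardized strength change on Group (CR vs AL), mass change
    and sex; returns the CR coefficient with SE and p."""
    if deltas["group"].nunique() < 2:
        raise ValueError("both arms must be present")
    y, X = _design(deltas, strength_var)
    if len(y) <= 4:
        raise ValueError("too few subjects for the base model")
    fit = sm.OLS(y, X).fit()
    return {"beta1": float(fit.params["Group"]), "se": float(fit.bse["Group"]),
            "p": float(fit.pvalues["Group"]), "n": int(len(y))}


def percent_mediation(beta_base: float, beta_adj: float) -> float:
    """100 * (|beta_base| - |beta_adj|) / |beta_base|; negative values mean
    suppression (the adjusted coefficient grew)."""
    if beta_base == 0:
        raise ValueError("percent mediation undefined for beta_base = 0")
    return 100.0 * (abs(beta_base) - abs(beta_adj)) / abs(beta_base)


def mediation_search(deltas: pd.DataFrame, pathway_ids: list[str],
                     strength_var: str, k_max: int = 4, threshold: float = 20.0,
                     categories: dict[str, str] | None = None) -> dict:
    """Exhaustive pathway-combination search for beta attenuation.

    Fits the adjusted model for every combination of 1..k_max pathway
    deltas.  Returns a dict with ``records`` (combinations at or above the
    percent-mediation threshold), ``per_k_max`` (the maximum percent per k)
    and, when a pathway -> functional-category map is supplied,
    ``best_distinct`` (best combination per k among category-distinct
    combinations).  Combinations containing near-collinear pathway deltas
    (|corr| > 0.999) are skipped.
    """
    base = fit_base_model(deltas, strength_var)
    b0 = base["beta1"]
    if b0 == 0:
        raise ValueError("base CR coefficient is exactly zero")

    pw_cols = {p: deltas[f"delta_{p}"].to_numpy(dtype=float) for p in pathway_ids}
    corr = np.corrcoef(np.column_stack(list(pw_cols.values())), rowvar=False) \
        if len(pathway_ids) > 1 else np.ones((1, 1))
    pw_index = {p: i for i, p in enumerate(pathway_ids)}

    y, Xbase = _design(deltas, strength_var)
    Xb = Xbase.to_numpy()
    records = []
    per_k_max: dict[int, float] = {}
    best_distinct: dict[int, dict] = {}
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(pathway_ids, k):
            if k > 1:
                idx = [pw_index[p] for p in combo]
                sub = np.abs(corr[np.ix_(idx, idx)])
                if (sub[np.triu_indices(k, 1)] > 0.999).any():
                    continue
            X = np.column_stack([Xb] + [pw_cols[p] for p in combo])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            b_adj = float(coef[1])  # column order: const, Group, ...
            pct = percent_mediation(b0, b_adj)
            if k not in per_k_max or pct > per_k_max[k]:
                per_k_max[k] = pct
            if categories is not None:
                cats = [categories.get(p) for p in combo]
                if len(set(cats)) == k and (k not in best_distinct
                                            or pct > best_distinct[k]["percent"]):
                    best_distinct[k] = {"combination": combo, "percent": pct}
            if pct >= threshold:
                records.append({"combination": "+".join(combo), "k": k,
                                "strength_var": strength_var,
                                "beta_base": b0, "beta_adj": b_adj,
                                "percent": pct})
    return {"records": pd.DataFrame(records,
                                    columns=["combination", "k", "strength_var",
                                             "beta_base", "beta_adj", "percent"]),
            "base": base, "per_k_max": per_k_max, "best_distinct": best_distinct}
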