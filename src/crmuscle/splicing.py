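"""Transcript-level analyses: DTE, DTU, dual-quantifier intersection.

Transcripts are filtered by an arm-by-visit detection rule, then analysed
two ways: differential transcript expression (DTE) on log2(TPM+1) and
differential transcript usage (DTU) on within-gene proportions of
log2(TPM+1) (a 0-1 scale).  Both reuse the per-feature mixed-model sweep.
Running the same analysis on two independent quantifications of the same
samples and intersecting the significant sets (p < 0.01 in both) guards
against quantifier-specific artifacts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import run_dge
from .types import DesignSpec


def filter_transcripts(tpm: pd.DataFrame, meta: pd.DataFrame,
                       gene_map: pd.DataFrame) -> pd.DataFrame:
    """Detection filter plus the single-transcript rule.

    Keeps a transcript iff every arm-by-visit subgroup has >= 2 samples
    with TPM > 0; genes left with a single surviving transcript are then
    dropped entirely (usage is meaningless for them).
    """
    meta = meta.set_index("sample_id").loc[tpm.columns]
    cells = meta.groupby(["group", "visit"], observed=True).groups
    if len(cells) != 6:
        raise ValueError(f"expected 6 arm-by-visit subgroups, found {len(cells)}")
    keep = np.ones(len(tpm), dtype=bool)
    for _, samples in cells.items():
        if len(samples) < 2:
            raise ValueError("subgroup with < 2 samples; detection rule unevaluable")
        keep &= (tpm.loc[:, list(samples)].to_numpy() > 0).sum(axis=1) >= 2
    out = tpm.loc[keep]
    gene_of = gene_map.set_index("transcript_id")["gene_id"].reindex(out.index)
    n_tx = gene_of.groupby(gene_of).transform("size")
    return out.loc[(n_tx >= 2).to_numpy()]


def dte_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(TPM + 1)."""
    return np.log2(tpm + 1.0)


def dtu_transform(tpm: pd.DataFrame, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Within-gene usage fractions of log2(TPM+1), per sample.

    usage(t, s) = log2(TPM+1)(t, s) / sum over the gene's transcripts; NaN
    where the gene's denominator is 0 (usage undefined, treated as missing
    downstream, not imputed).  Defined values sum to 1 per gene and sample.
    """
    lt = dte_transform(tpm)
    gene_of = gene_map.set_index("transcript_id")["gene_id"].reindex(lt.index)
    denom = lt.groupby(gene_of.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = lt / denom.to_numpy()
    return usage.where(denom > 0)


def _run_lmm_table(mat: pd.DataFrame, meta: pd.DataFrame,
                   design: DesignSpec | None) -> pd.DataFrame:
    design = design or DesignSpec()
    if mat.empty:
        return run_dge(mat, meta, design)
    complete = mat.dropna()
    parts = [run_dge(complete, meta, design)] if not complete.empty else []
    rest = mat.loc[mat.index.difference(complete.index, sort=False)]
    for _, row in rest.iterrows():
        ok = row.notna()
        sub = row[ok]
        sub_meta = meta[meta["sample_id"].isin(sub.index)]
        try:
            parts.append(run_dge(sub.to_frame().T, sub_meta, design))
        except Exception:
            parts.append(pd.DataFrame([{"gene_id": row.name, "contrast": "na",
                                        "beta": np.nan, "se": np.nan, "df": np.nan,
                                        "p": np.nan, "converged": False,
                                        "boundary": False, "var_subject": np.nan,
                                        "var_resid": np.nan}]))
    out = pd.concat(parts, ignore_index=True) if parts else run_dge(mat, meta, design)
    return out.rename(columns={"gene_id": "transcript_id"})


def run_dte(tpm: pd.DataFrame, meta: pd.DataFrame,
            design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-transcript LMM on log2(TPM+1)."""
    return _run_lmm_table(dte_transform(tpm), meta, design)


def run_dtu(tpm: pd.DataFrame, meta: pd.DataFrame, gene_map: pd.DataFrame,
            design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-transcript LMM on usage fractions; samples with undefined usage
    for a transcript are excluded from that transcript's fit."""
    return _run_lmm_table(dtu_transform(tpm, gene_map), meta, design)


def intersect_quantifiers(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          alpha: float = 0.01) -> pd.DataFrame:
    """Transcripts significant (p < alpha) in both quantifier tables.

    Tables must be keyed by transcript_id; returns the intersection with
    both p-values.
    """
    for t in (table_a, table_b):
        if "transcript_id" not in t.columns:
            raise KeyError("tables must carry a transcript_id column")
    a = table_a.set_index("transcript_id")
    b = table_b.set_index("transcript_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0 and (len(a) or len(b)):
        if len(a.index.union(b.index)) == len(a) + len(b) and len(a) and len(b):
            raise KeyError("quantifier tables share no transcript keys")
    sig = shared[(a.loc[shared, "p"] < alpha) & (b.loc[shared, "p"] < alpha)]
    return pd.DataFrame({"transcript_id": sig,
                         "p_a": a.loc[sig, "p"].to_numpy(),
                         "p_b": b.loc[sig, "p"].to_numpy()})


def shared_variant_sets(dte_a, dte_b, dtu_a, dtu_b, alpha: float = 0.01) -> dict:
    """Dual-quantifier intersections per analysis, their union, and the
    DTE-and-DTU overlap."""
    dte = set(intersect_quantifiers(dte_a, dte_b, alpha)["transcript_id"])
    dtu = set(intersect_quantifiers(dtu_a, dtu_b, alpha)["transcript_id"])
    return {"dte": dte, "dtu": dtu, "union": dte | dtu, "both": dte & dtu}


def classify_biotypes(variants, gene_map: pd.DataFrame,
                      dge: pd.DataFrame | None = None,
                      alpha: float = 0.05) -> dict:
    """Biotype tally of a variant set, optionally cross-tabulated with
    DGE significance of the parent gene."""
    ann = gene_map.set_index("transcript_id")
    variants = list(variants)
    missing = [v for v in variants if v not in ann.index]
    if missing:
        raise KeyError(f"unannotated variant(s): {missing[:5]}")
    bio = ann.loc[variants, "biotype"]
    tally = bio.value_counts().to_dict()
    out = {"tally": tally}
    if dge is not None:
        sig_genes = set(dge.loc[dge["p"] < alpha, "gene_id"])
        parent = ann.loc[variants, "gene_id"]
        cross = pd.crosstab(bio, parent.isin(sig_genes).rename("parent_gene_sig"))
        out["cross_tab"] = cross
    return out
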