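"""Gene-level filtering and normalization.

Protein-coding restriction, the arm-by-visit zero-count filter, TMM
(trimmed mean of M-values) scaling factors, and log2 counts-per-million.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

# Printed filtering bookkeeping of the study being emulated: 60,605 assayed
# genes, 40,672 non-coding, 16,450 retained for analysis out of 19,937 known
# protein-coding genes in the hg38/Ensembl-v104 annotation.
STUDY_FILTER_COUNTS = {
    "total_genes": 60_605,
    "noncoding_genes": 40_672,
    "retained_genes": 16_450,
    "known_coding_genes": 19_937,
}


def filter_protein_coding(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows annotated as protein_coding, preserving order.

    ``annotation`` needs columns gene_id and biotype and must cover every
    row of ``counts``.
    """
    bio = annotation.drop_duplicates("gene_id").set_index("gene_id")["biotype"]
    missing = counts.index.difference(bio.index)
    if len(missing):
        raise KeyError(f"unannotated gene(s): {', '.join(map(str, missing[:5]))}")
    keep = bio.reindex(counts.index) == "protein_coding"
    return counts.loc[keep.to_numpy()]


def filter_low_expression(counts: pd.DataFrame, meta: pd.DataFrame,
                          scope: str = "subgroup",
                          threshold: float = 0.5) -> pd.DataFrame:
    """Drop genes with zero counts in >= ``threshold`` of samples.

    With ``scope="subgroup"`` (the Methods rule) the fraction is evaluated
    in each of the six arm-by-visit cells and a gene is dropped if ANY cell
    reaches it; ``scope="total"`` evaluates a single fraction over all
    samples.
    """
    meta = meta.set_index("sample_id").loc[counts.columns]
    if scope == "total":
        frac0 = (counts.to_numpy() == 0).mean(axis=1)
        drop = frac0 >= threshold
    elif scope == "subgroup":
        cells = meta.groupby(["group", "visit"], observed=True).groups
        if len(cells) != 6:
            raise ValueError(f"expected 6 arm-by-visit subgroups, found {len(cells)}")
        drop = np.zeros(len(counts), dtype=bool)
        for _, samples in cells.items():
            if len(samples) == 0:
                raise ValueError("empty subgroup; filter undefined")
            sub = counts.loc[:, list(samples)].to_numpy()
            drop |= (sub == 0).mean(axis=1) >= threshold
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return counts.loc[~drop]


def retention_percentages(total_genes: int, noncoding_genes: int,
                          retained_genes: int, known_coding_genes: int) -> dict[str, float]:
    """Retained/excluded fractions of known protein-coding genes, in percent,
    from filter bookkeeping counts."""
    if retained_genes > known_coding_genes:
        raise ValueError("retained exceeds known coding genes")
    coding_assayed = total_genes - noncoding_genes
    retained = 100.0 * retained_genes / known_coding_genes
    return {
        "coding_assayed": float(coding_assayed),
        "retained_pct_of_known_coding": retained,
        "excluded_pct_of_known_coding": 100.0 - retained,
    }


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference
    (double trimming on M and A, inverse-asymptotic-variance weights)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / lib_obs, ref / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.abs(m).max() < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or not np.isfinite(m[keep]).any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile; factors express composition bias
    only (pure depth differences give factor 1 and are handled by CPM).
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    uq = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_idx]
    factors = np.array([
        _tmm_pair(x[:, j], ref, lib[j], lib[ref_idx], logratio_trim, sum_trim)
        for j in range(x.shape[1])])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
             prior: float = 1.0) -> pd.DataFrame:
    """log2( count / (libsize * factor) * 1e6 + prior ).

    Default prior 1 keeps zeros at 0 and is symmetric with the transcript
    branch's log2(TPM+1); prior 0 recovers exact CPM on the log scale.
    """
    if prior < 0:
        raise ValueError("prior must be >= 0")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative count")
    lib = x.sum(axis=0)
    f = factors.loc[counts.columns].to_numpy() if factors is not None else 1.0
    eff = lib * f
    return pd.DataFrame(np.log2(x / eff[None, :] * 1e6 + prior),
                        index=counts.index, columns=counts.columns)
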