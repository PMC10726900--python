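"""Preranked gene-set enrichment with a Monte-Carlo consensus ensemble.

The enrichment score (ES) is the extremum of the classic weighted
running-sum statistic over a ranked gene list: set members ("hits")
increment the sum by |r|^weight normalized by the in-set total, non-members
decrement by 1/(N - n).  Significance comes from gene-label permutations;
NES divides ES by the mean |ES| of same-sign permutations; adjusted p is
Benjamini-Hochberg, pooled across collections by default.

Because permutation p-values (hence the reported pathway set) are
stochastic, the consensus layer re-runs the whole preranked analysis
``n_iter`` times with fresh permutation streams and reports a pathway only
if it is adjusted-significant in more than ``freq_threshold`` of iterations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def enrichment_score(ranked: pd.Series, gene_set, weight: float = 1.0
                     ) -> tuple[float, list[str]]:
    """ES and leading-edge genes of one set against a ranked list.

    ``ranked`` must be sorted descending by rank metric.  The leading edge
    is the members at or before the extremum (positive ES) or at or after
    it (negative ES).
    """
    universe = ranked.index.to_numpy()
    member = np.isin(universe, list(gene_set))
    n = int(member.sum())
    N = len(universe)
    if n == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n == N:
        raise ValueError("gene set equals the universe; ES undefined (N - n = 0)")
    pos = np.flatnonzero(member)
    absr = np.abs(ranked.to_numpy())
    w = absr[pos] ** weight
    W = w.sum()
    if W == 0:  # all hit weights zero: fall back to unweighted form
        w = np.ones(n)
        W = float(n)
    cw = np.cumsum(w)
    miss = (pos - np.arange(n)) / (N - n)
    post = cw / W - miss           # value just after each hit
    pre = (cw - w) / W - miss      # value just before each hit
    j_max = int(np.argmax(post))
    j_min = int(np.argmin(pre))
    # the positive extremum wins magnitude ties (tolerance absorbs
    # floating-point noise on analytically exact ties)
    if post[j_max] >= -pre[j_min] - 1e-12:
        es = float(post[j_max])
        leading = universe[pos[:j_max + 1]]
    else:
        es = float(pre[j_min])
        leading = universe[pos[j_min:]]
    return es, list(leading)


def _es_permutations(absr_w: np.ndarray, n: int, nperm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """ES values for ``nperm`` random size-n hit-position draws (gene-label
    permutation null), vectorized over permutations."""
    N = absr_w.shape[0]
    u = rng.random((nperm, N))
    pos = np.sort(np.argpartition(u, n, axis=1)[:, :n], axis=1)
    w = absr_w[pos]
    W = w.sum(axis=1, keepdims=True)
    W[W == 0] = 1.0
    cw = np.cumsum(w, axis=1)
    miss = (pos - np.arange(n)[None, :]) / (N - n)
    post = cw / W - miss
    pre = (cw - w) / W - miss
    maxp = post.max(axis=1)
    minp = pre.min(axis=1)
    return np.where(maxp >= -minp - 1e-12, maxp, minp)


def gsea_preranked(ranked: pd.Series, collections: dict[str, dict[str, list[str]]],
                   nperm: int = 1000, weight: float = 1.0, seed: int = 0,
                   min_size: int = 10, max_size: int = 500,
                   pool_collections: bool = True) -> pd.DataFrame:
    """Permutation GSEA over one or more named gene-set collections.

    ``collections`` maps source label -> {pathway -> genes}.  Pathways
    falling outside [min_size, max_size] after intersecting the universe
    are skipped.  p = (1 + #{permutation ES at least as extreme, same
    side}) / (nperm + 1), so the attainable minimum is 1/(nperm+1).
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    rng = np.random.default_rng(seed)
    universe = set(ranked.index)
    absr_w = np.abs(ranked.to_numpy()) ** weight
    perm_cache: dict[int, np.ndarray] = {}
    rows = []
    for source in sorted(collections):
        for name in sorted(collections[source]):
            genes = [g for g in collections[source][name] if g in universe]
            n = len(genes)
            if n < min_size or n > max_size or n == len(universe):
                continue
            es, leading = enrichment_score(ranked, genes, weight)
            if n not in perm_cache:
                perm_cache[n] = _es_permutations(absr_w, n, nperm, rng)
            perm = perm_cache[n]
            # two-sided permutation p on |ES|: uniform under the null and
            # attains 1/(nperm+1) for a maximally enriched set
            p = (1 + int((np.abs(perm) >= abs(es)).sum())) / (nperm + 1)
            if es >= 0:
                denom = np.abs(perm[perm > 0]).mean() if (perm > 0).any() else np.abs(perm).mean()
            else:
                denom = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else np.abs(perm).mean()
            nes = es / denom if denom > 0 else np.nan
            rows.append({"pathway": name, "source": source, "size": n, "ES": es,
                         "NES": nes, "p": p, "leading_edge": leading})
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adj"] = []
        return out
    if pool_collections:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = np.nan
        for source in out["source"].unique():
            m = out["source"] == source
            out.loc[m, "p_adj"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    return out


def gsea_consensus(ranked: pd.Series, collections: dict[str, dict[str, list[str]]],
                   n_iter: int = 1000, alpha: float = 0.05,
                   freq_threshold: float = 0.8, nperm: int = 1000,
                   weight: float = 1.0, seed: int = 0,
                   min_size: int = 10, max_size: int = 500,
                   pool_collections: bool = True) -> pd.DataFrame:
    """Monte-Carlo consensus over repeated preranked runs.

    Each iteration redraws the permutation null with a child seed spawned
    from ``seed``; a pathway's frequency is the fraction of iterations with
    adjusted p < alpha, and it is reported iff frequency > freq_threshold
    (strict).  Median NES over iterations is reported.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    child_seeds = [int(s.generate_state(1)[0]) % (2**31)
                   for s in np.random.SeedSequence(seed).spawn(n_iter)]
    sig_counts: dict[tuple[str, str], int] = {}
    nes_acc: dict[tuple[str, str], list[float]] = {}
    leading: dict[tuple[str, str], list[str]] = {}
    for it_seed in child_seeds:
        res = gsea_preranked(ranked, collections, nperm=nperm, weight=weight,
                             seed=it_seed, min_size=min_size, max_size=max_size,
                             pool_collections=pool_collections)
        for _, r in res.iterrows():
            key = (r["pathway"], r["source"])
            sig_counts[key] = sig_counts.get(key, 0) + int(r["p_adj"] < alpha)
            nes_acc.setdefault(key, []).append(r["NES"])
            leading.setdefault(key, r["leading_edge"])
    rows = []
    for key in sorted(sig_counts):
        freq = sig_counts[key] / n_iter
        rows.append({"pathway": key[0], "source": key[1],
                     "median_NES": float(np.median(nes_acc[key])),
                     "frequency": freq, "reported": freq > freq_threshold,
                     "leading_edge": leading[key]})
    return pd.DataFrame(rows)
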