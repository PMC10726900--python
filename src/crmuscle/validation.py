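"""Independent oracles and simulation-based validation experiments.

The oracle functions here are deliberately separate, brute-force
implementations (exhaustive prefix enumeration for the enrichment score,
loop-based trimmed-mean for TMM) used only to cross-check the production
code paths.  The experiment functions run the generator-to-analysis loop at
its study conditions and report the quantity of interest (type-I rate,
recovery bias, consensus frequencies, mediation flag rates, shared-variant
recovery); they are called both by the test suite and by the acceptance
script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import gsea, mediation, phenotype, preprocess, simulate, splicing
from .lmm import RandomInterceptREML, build_design, run_dge
from .types import CohortConfig, DesignSpec, EffectSpec, PhenotypeTruth


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) % (2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------- filtering

def filter_arithmetic() -> dict[str, float]:
    """Retained/excluded percentages of known protein-coding genes from the
    study's printed filter bookkeeping."""
    return preprocess.retention_percentages(**preprocess.STUDY_FILTER_COUNTS)


# ------------------------------------------------------------- GSEA oracle

def es_exhaustive(ranked: pd.Series, gene_set, weight: float = 1.0) -> float:
    """Enrichment score by explicit enumeration of every prefix position."""
    member = np.isin(ranked.index.to_numpy(), list(gene_set))
    absr = np.abs(ranked.to_numpy()) ** weight
    W = absr[member].sum()
    n, N = int(member.sum()), len(member)
    if W == 0:
        absr = np.ones(N)
        W = float(n)
    running = 0.0
    lo = hi = 0.0
    for i in range(N):
        if member[i]:
            running += absr[i] / W
        else:
            running -= 1.0 / (N - n)
        hi = max(hi, running)
        lo = min(lo, running)
    # positive extremum wins an exact-magnitude tie (same rule and
    # tolerance as the streaming implementation)
    return hi if hi >= -lo - 1e-12 else lo


def es_oracle_max_diff(seed: int = 0, n_instances: int = 100) -> float:
    """Max |streaming ES - exhaustive ES| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        N = int(rng.integers(8, 51))
        r = np.sort(rng.normal(0, 1.5, N))[::-1]
        genes = [f"g{i}" for i in range(N)]
        ranked = pd.Series(r, index=genes)
        n = int(rng.integers(2, max(3, N // 2)))
        gene_set = list(rng.choice(genes, size=n, replace=False))
        weight = float(rng.choice([0.0, 1.0, 1.5]))
        es, _ = gsea.enrichment_score(ranked, gene_set, weight)
        worst = max(worst, abs(es - es_exhaustive(ranked, gene_set, weight)))
    return worst


# -------------------------------------------------------------- TMM oracle

def tmm_reference(counts: pd.DataFrame, logratio_trim: float = 0.3,
                  sum_trim: float = 0.05) -> pd.Series:
    """Brute-force weighted trimmed mean of M-values, written independently
    of the production implementation (explicit python loops)."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    uq = np.array([float(np.quantile(x[:, j], 0.75)) / lib[j]
                   for j in range(x.shape[1])])
    ref_j = int(np.argmin([abs(q - np.mean(uq)) for q in uq]))
    factors = []
    for j in range(x.shape[1]):
        m_list, a_list, w_list = [], [], []
        for g in range(x.shape[0]):
            o, r = x[g, j], x[g, ref_j]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref_j]
                m_list.append(np.log2(po / pr))
                a_list.append(0.5 * np.log2(po * pr))
                w_list.append((lib[j] - o) / (lib[j] * o)
                              + (lib[ref_j] - r) / (lib[ref_j] * r))
        m = np.array(m_list)
        if m.size == 0 or np.abs(m).max() < 1e-6:
            factors.append(1.0)
            continue
        n = m.size
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(np.array(a_list))
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m[i] / w_list[i]
                den += 1.0 / w_list[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    f = np.array(factors)
    f /= np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns)


def tmm_fixture(seed: int = 0, n_genes: int = 200, n_samples: int = 4) -> pd.DataFrame:
    """Count fixture with one differentially expressed block, so factors
    deviate from 1."""
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 50.0, n_genes)
    counts = rng.poisson(base[:, None] * rng.uniform(0.5, 2.0, n_samples)[None, :])
    counts[: n_genes // 10, 0] *= 8  # DE block inflates sample 0's composition
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


def tmm_oracle_max_diff(seed: int = 0) -> float:
    counts = tmm_fixture(seed)
    return float(np.abs(preprocess.tmm_factors(counts)
                        - tmm_reference(counts)).max())


# ------------------------------------------------------- LMM calibration

def null_rejection_rate(seed: int = 0, n_genes: int = 2000,
                        alpha: float = 0.05) -> dict:
    """Type-I error of the Group x Time test through the full synthetic
    path: null NB counts -> zero filter -> TMM/log2-CPM -> per-gene LMM."""
    s_cohort, s_counts = _child_seeds(seed, 2)
    meta, _ = simulate.simulate_cohort(CohortConfig(seed=s_cohort))
    effects = EffectSpec(n_genes=n_genes)
    counts = simulate.simulate_counts(meta, effects, seed=s_counts)
    counts = preprocess.filter_low_expression(counts, meta)
    expr = preprocess.log2_cpm(counts, preprocess.tmm_factors(counts))
    dge = run_dge(expr, meta)
    ok = dge["p"].notna()
    rate = float((dge.loc[ok, "p"] < alpha).mean())
    return {"rate": rate, "n_fits": int(ok.sum())}


def beta_recovery(seed: int = 0, n_rep: int = 500, beta1: float = 0.5,
                  subject_sd: float = 0.3, residual_sd: float = 0.3) -> dict:
    """Bias of the interaction estimate for Gaussian trajectories simulated
    directly from the mixed model on a 90-subject cohort."""
    s_cohort, s_y = _child_seeds(seed, 2)
    meta, _ = simulate.simulate_cohort(CohortConfig(seed=s_cohort))
    X, names, interactions = build_design(meta, DesignSpec())
    solver = RandomInterceptREML(X, meta["subject_id"].to_numpy())
    j = names.index(interactions[0])
    subj_codes, subj_idx = np.unique(meta["subject_id"], return_inverse=True)
    beta_true = np.zeros(X.shape[1])
    beta_true[j] = beta1
    rng = np.random.default_rng(s_y)
    est = np.empty(n_rep)
    for r in range(n_rep):
        u = rng.normal(0, subject_sd, len(subj_codes))
        y = X @ beta_true + u[subj_idx] + rng.normal(0, residual_sd, X.shape[0])
        est[r] = solver.fit(y)["beta"][j]
    return {"mean_estimate": float(est.mean()),
            "bias": float(est.mean() - beta1), "n_rep": n_rep}


# -------------------------------------------------------------- consensus

def consensus_inputs(seed: int = 0, n_genes: int = 1000, set_size: int = 50,
                     n_null_sets: int = 20) -> tuple[pd.Series, dict]:
    """Ranked list with one planted pathway (the top ``set_size`` genes)
    plus random null sets."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    r = np.sort(rng.normal(0, 1.5, n_genes))[::-1]
    ranked = pd.Series(r, index=genes)
    sets = {"planted": genes[:set_size]}
    for i in range(n_null_sets):
        sets[f"null{i:02d}"] = list(rng.choice(genes, set_size, replace=False))
    return ranked, {"synthetic": sets}


def consensus_behavior(seed: int = 0, n_iter: int = 100, nperm: int = 1000) -> dict:
    """Consensus frequencies for a strongly planted pathway and pure-null
    pathways over ``n_iter`` Monte-Carlo iterations."""
    s_in, s_run = _child_seeds(seed, 2)
    ranked, collections = consensus_inputs(s_in)
    cons = gsea.gsea_consensus(ranked, collections, n_iter=n_iter, nperm=nperm,
                               seed=s_run).set_index("pathway")
    nulls = cons.drop(index="planted")
    return {"planted_frequency": float(cons.loc["planted", "frequency"]),
            "planted_reported": bool(cons.loc["planted", "reported"]),
            "max_null_frequency": float(nulls["frequency"].max()),
            "any_null_reported": bool(nulls["reported"].any()),
            "n_iter": n_iter}


# -------------------------------------------------------------- mediation

def _mediation_once(seed: int, planted_fraction: float, n_pathways: int = 6,
                    n_cr: int = 28, n_al: int = 16) -> dict:
    rng_seeds = _child_seeds(seed, 2)
    subjects = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n_cr + n_al)],
        "group": ["CR"] * n_cr + ["AL"] * n_al,
        "sex": list(np.where(np.random.default_rng(rng_seeds[0]).random(n_cr + n_al)
                             < 0.65, "F", "M")),
    })
    pathways = [f"PW{i:02d}" for i in range(n_pathways)]
    fracs = {"PW00": planted_fraction} if planted_fraction > 0 else {}
    # In the all-null condition the pathways carry no CR signal at all, so
    # they are uncorrelated with strength; CR-responsive but non-mediating
    # pathways act as collinear proxies of the arm and are not a clean null
    # for the attenuation rule.
    truth = PhenotypeTruth(mediated_fractions=fracs,
                           pathway_shift=1.0 if fracs else 0.0)
    visits = {s: ["Ba", "12mo", "24mo"] for s in subjects["subject_id"]}
    pdelta = simulate.simulate_pathway_deltas(subjects, pathways, truth,
                                              seed=rng_seeds[0])
    pheno = simulate.simulate_phenotypes(subjects, visits, pdelta, truth,
                                         seed=rng_seeds[1])
    # one bilateral strength variable, averaged, plus mass
    pheno["peak_torque_60"] = [
        phenotype.average_bilateral(l, r)[0]
        for l, r in zip(pheno["peak_torque_60_left"], pheno["peak_torque_60_right"])]
    deltas = mediation.delta_scores(pheno, ["leg_lean_mass", "peak_torque_60"])
    for p in pathways:
        deltas[f"delta_{p}"] = pdelta.loc[deltas["subject_id"], p].to_numpy()
        sd = deltas[f"delta_{p}"].std(ddof=1)
        deltas[f"delta_{p}"] = (deltas[f"delta_{p}"]
                                - deltas[f"delta_{p}"].mean()) / sd
    res = mediation.mediation_search(deltas, pathways, "peak_torque_60",
                                     k_max=1, threshold=20.0)
    flagged = set(res["records"]["combination"])
    return {"planted_flagged": "PW00" in flagged, "any_flagged": bool(flagged)}


def mediation_calibration(seed: int = 0, n_seeds: int = 50,
                          planted_fraction: float = 0.5) -> dict:
    """Planted-mediator detection rate and all-null false-flag rate of the
    k=1 combination search over repeated cohorts of 28 CR / 16 AL."""
    seeds = _child_seeds(seed, n_seeds)
    planted = [_mediation_once(s, planted_fraction) for s in seeds]
    nulls = [_mediation_once(s + 1, 0.0) for s in seeds]
    return {
        "planted_detection_rate": float(np.mean([r["planted_flagged"] for r in planted])),
        "null_flag_rate": float(np.mean([r["any_flagged"] for r in nulls])),
        "n_seeds": n_seeds,
    }


def mediation_noiseless_check(seed: int = 0, fraction: float = 0.5) -> dict:
    """Noiseless single-mediator limit: percent mediation should equal the
    planted fraction (in percent) up to finite-sample covariate imbalance."""
    subjects = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(200)],
        "group": ["CR"] * 120 + ["AL"] * 80,
        "sex": ["F", "M"] * 100,
    })
    truth = PhenotypeTruth(mediated_fractions={"PW00": fraction}, noise_sd=0.0,
                           mass_effect=0.0)
    visits = {s: ["Ba", "24mo"] for s in subjects["subject_id"]}
    pdelta = simulate.simulate_pathway_deltas(subjects, ["PW00"], truth, seed=seed)
    pheno = simulate.simulate_phenotypes(subjects, visits, pdelta, truth,
                                         seed=seed + 1, bilateral_sd=0.0)
    pheno["peak_torque_60"] = (pheno["peak_torque_60_left"]
                               + pheno["peak_torque_60_right"]) / 2
    deltas = mediation.delta_scores(pheno, ["leg_lean_mass", "peak_torque_60"])
    z = pdelta.loc[deltas["subject_id"], "PW00"].to_numpy()
    deltas["delta_PW00"] = (z - z.mean()) / z.std(ddof=1)
    res = mediation.mediation_search(deltas, ["PW00"], "peak_torque_60",
                                     k_max=1, threshold=0.0)
    return {"percent": float(res["per_k_max"][1]), "target": 100.0 * fraction}


# --------------------------------------------------------------- splicing

def dual_quantifier_recovery(seed: int = 0, n_seeds: int = 20,
                             n_genes: int = 60, n_planted: int = 30) -> dict:
    """Recovery of planted shared splice variants through the dual-
    quantifier DTE/DTU intersection at p < 0.01 and default quantifier
    noise."""
    seeds = _child_seeds(seed, n_seeds)
    recovered = []
    for s in seeds:
        s_cohort, s_map, s_tx = _child_seeds(s, 3)
        meta, _ = simulate.simulate_cohort(CohortConfig(seed=s_cohort))
        genes = [f"g{i:04d}" for i in range(n_genes)]
        rng = np.random.default_rng(s_map)
        gene_map = pd.DataFrame([
            {"transcript_id": f"{g}.t{j}", "gene_id": g,
             "biotype": "protein_coding"}
            for g in genes for j in range(int(rng.integers(2, 4)))])
        planted_genes = genes[:n_planted]
        usage = {g: 1.2 for g in planted_genes}
        exprsh = {g: 0.8 for g in planted_genes}
        tpm_a, tpm_b = simulate.simulate_transcripts(
            meta, gene_map, seed=s_tx, usage_shift=usage, expression_shift=exprsh)
        fa = splicing.filter_transcripts(tpm_a, meta, gene_map)
        fb = splicing.filter_transcripts(tpm_b, meta, gene_map)
        sets = splicing.shared_variant_sets(
            splicing.run_dte(fa, meta), splicing.run_dte(fb, meta),
            splicing.run_dtu(fa, meta, gene_map), splicing.run_dtu(fb, meta, gene_map))
        planted_tx = {f"{g}.t0" for g in planted_genes}
        recovered.append(len(planted_tx & sets["union"]))
    return {"mean_recovered": float(np.mean(recovered)),
            "min_recovered": int(np.min(recovered)),
            "n_planted": n_planted, "n_seeds": n_seeds}


def dtu_sum_check(seed: int = 0) -> float:
    """Max |sum(usage) - 1| over defined gene-sample cells of a simulated
    fixture."""
    s_cohort, s_tx = _child_seeds(seed, 2)
    meta, _ = simulate.simulate_cohort(CohortConfig(n_cr=10, n_al=8, seed=s_cohort))
    gene_map = simulate.default_gene_map([f"g{i:03d}" for i in range(40)], seed=s_tx)
    tpm_a, _ = simulate.simulate_transcripts(meta, gene_map, seed=s_tx)
    usage = splicing.dtu_transform(tpm_a, gene_map)
    gene_of = gene_map.set_index("transcript_id")["gene_id"].reindex(usage.index)
    sums = usage.groupby(gene_of.to_numpy()).sum(min_count=1)
    dev = (sums - 1.0).abs().to_numpy()
    return float(np.nanmax(dev))


# --------------------------------------------------------------- phenotype

def wilcoxon_exact_example() -> float:
    """One-sided exact rank-sum p for {1,2,3} vs {4,5,6}: the most extreme
    of the C(6,3)=20 equally likely assignments, p = 1/20."""
    return phenotype.wilcoxon_rank_sum(np.array([1.0, 2.0, 3.0]),
                                       np.array([4.0, 5.0, 6.0]),
                                       alternative="less")["p"]
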