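"""Synthetic two-arm longitudinal muscle-transcriptomics cohorts.

Everything downstream (filtering, mixed-model DGE, consensus GSEA, mediation,
splicing) is exercised against cohorts generated here with planted ground
truth: negative-binomial gene counts whose log-mean carries a CR-vs-AL
trajectory-difference slope and a subject random intercept, two correlated
transcript-level TPM quantifications, GMT gene sets, and strength/mass
phenotypes whose CR effect is partly transmitted through pathway expression
changes.

Randomness: one root seed per operation; ``simulate_dataset`` spawns child
streams from a single root in the fixed order cohort, counts, transcripts,
gene sets, phenotypes.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .types import (ARMS, VISIT_YEARS, VISITS, CohortConfig, EffectSpec,
                    PhenotypeTruth)

STRENGTH_VARS = ("peak_torque_60", "avg_power_60", "peak_torque_180", "avg_power_180")
_STRENGTH_BASE = {"peak_torque_60": 150.0, "avg_power_60": 90.0,
                  "peak_torque_180": 100.0, "avg_power_180": 130.0}
_STRENGTH_BASE_SD = 25.0
_STRENGTH_CHANGE_SD = 10.0   # Nm; raw scale of one SD of strength change
_BILATERAL_SD = 2.0


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw subjects and their attended biopsy visits.

    Returns ``(meta, subjects)``: one row per collected sample, one row per
    subject.  Arm assignment is fixed per subject; every subject attends
    baseline (unless the optional follow-up-only flag adds two CR subjects
    without a baseline) and drops each follow-up visit independently with
    ``config.dropout_prob`` — missingness never looks at expression or
    phenotype values, so it is missing-at-random by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cr + config.n_al
    subjects = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "group": ["CR"] * config.n_cr + ["AL"] * config.n_al,
        "age": np.round(rng.normal(config.age_mean, config.age_sd, n), 1),
        "bmi": np.round(rng.normal(config.bmi_mean, config.bmi_sd, n), 1),
        "sex": np.where(rng.random(n) < config.prop_female, "F", "M"),
        "race": rng.choice([f"race{i}" for i in range(len(config.race_probs))],
                           size=n, p=list(config.race_probs)),
        "batch": [f"batch{i}" for i in rng.integers(0, config.n_batches, n)],
    })
    followup_only: set[str] = set()
    if config.followup_only_subjects:
        followup_only = set(subjects.loc[subjects.group == "CR", "subject_id"].iloc[:2])

    rows = []
    for _, s in subjects.iterrows():
        for visit in VISITS:
            if visit == "Ba":
                attended = s.subject_id not in followup_only
            else:
                attended = rng.random() >= config.dropout_prob
            if attended:
                rows.append({
                    "sample_id": f"{s.subject_id}_{visit}",
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "visit": visit,
                    "time_years": VISIT_YEARS[visit],
                    "age": s.age, "bmi": s.bmi, "sex": s.sex,
                    "race": s.race, "batch": s.batch,
                })
    meta = pd.DataFrame(rows)
    return meta, subjects


def default_effects(n_genes: int = 1000, n_pathways: int = 20,
                    pathway_size: int = 25, n_active_pathways: int = 0,
                    active_slope: float = 0.5, seed: int = 0,
                    **kwargs) -> EffectSpec:
    """Build an :class:`EffectSpec` with disjoint pathways over the gene
    universe; the first ``n_active_pathways`` get interaction slope
    ``active_slope`` (log2-CPM per year) on all their members."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    pathways: dict[str, list[str]] = {}
    for p in range(n_pathways):
        members = order[p * pathway_size:(p + 1) * pathway_size]
        if len(members) < pathway_size:
            break
        pathways[f"PW{p:02d}"] = sorted(genes[i] for i in members)
    b1 = {}
    for p in range(n_active_pathways):
        for g in pathways[f"PW{p:02d}"]:
            b1[g] = active_slope
    spec = EffectSpec(n_genes=n_genes, b1=b1, pathways=pathways, **kwargs)
    spec.validate()
    return spec


def simulate_counts(meta: pd.DataFrame, effects: EffectSpec, seed: int = 0) -> pd.DataFrame:
    """Negative-binomial gene counts for the samples in ``meta``.

    The log2 mean of gene g in sample s is
    ``base_g + b1_g * CR_s * t_s + b3_g * t_s + u_{g,subject(s)} + e_{g,s}``
    converted to an expected count through a sample library size drawn
    log-normally (>=2-fold spread by default); counts are gamma-Poisson with
    gene-specific dispersion.
    """
    if meta.empty:
        raise ValueError("meta is empty")
    effects.validate()
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(effects.n_genes)]
    n_g, n_s = len(genes), len(meta)

    base = rng.normal(effects.baseline_log2cpm_mean, effects.baseline_log2cpm_sd, n_g)
    b3 = rng.normal(0.0, effects.time_slope_sd, n_g)
    b1 = np.array([effects.b1.get(g, 0.0) for g in genes])

    subj_codes, subj_idx = np.unique(meta["subject_id"], return_inverse=True)
    u = rng.normal(0.0, effects.subject_sd, (n_g, len(subj_codes)))
    eps = rng.normal(0.0, effects.residual_sd, (n_g, n_s))

    t = meta["time_years"].to_numpy()
    cr = (meta["group"] == "CR").to_numpy().astype(float)
    log2cpm = (base[:, None] + np.outer(b1, cr * t) + np.outer(b3, t)
               + u[:, subj_idx] + eps)

    lib = np.exp(rng.normal(np.log(effects.lib_size_mean), effects.lib_size_log_sd, n_s))
    mu = np.exp2(log2cpm) * (lib / 1e6)[None, :]
    shape = 1.0 / effects.dispersion
    lam = rng.gamma(shape, mu * effects.dispersion)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=meta["sample_id"].to_numpy())


def default_gene_map(genes: list[str], max_transcripts: int = 3,
                     seed: int = 0) -> pd.DataFrame:
    """Transcript->gene map with 1..max_transcripts isoforms per gene and
    field-typical transcript biotypes."""
    rng = np.random.default_rng(seed)
    biotypes = np.array(["protein_coding", "retained_intron",
                         "processed_transcript", "nonsense_mediated_decay"])
    bt_p = np.array([0.55, 0.15, 0.17, 0.13])
    rows = []
    for g in genes:
        k = int(rng.integers(1, max_transcripts + 1))
        for j in range(k):
            rows.append({"transcript_id": f"{g}.t{j}", "gene_id": g,
                         "biotype": "protein_coding" if j == 0
                         else str(rng.choice(biotypes, p=bt_p))})
    return pd.DataFrame(rows)


def simulate_transcripts(meta: pd.DataFrame, gene_map: pd.DataFrame, seed: int = 0,
                         usage_shift: dict[str, float] | None = None,
                         expression_shift: dict[str, float] | None = None,
                         quantifier_sigma: float = 0.15,
                         subject_sd: float = 0.3, residual_sd: float = 0.2,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two TPM quantifications of the same underlying transcript signal.

    Gene abundance follows the same log-linear trajectory model as counts;
    isoform proportions are Dirichlet at baseline, and genes in
    ``usage_shift`` drift their first isoform's log-weight by
    ``shift * CR * t`` (a differential-usage signal with no requirement of a
    gene-level expression change).  The two returned matrices share the true
    signal and differ by multiplicative lognormal quantifier noise of scale
    ``quantifier_sigma``; each column of each matrix sums to 1e6.
    """
    if gene_map.empty:
        raise ValueError("empty gene map")
    usage_shift = usage_shift or {}
    expression_shift = expression_shift or {}
    rng = np.random.default_rng(seed)
    genes = gene_map["gene_id"].unique().tolist()
    tx = gene_map["transcript_id"].to_numpy()
    gene_of_tx = gene_map["gene_id"].to_numpy()
    n_s = len(meta)

    t = meta["time_years"].to_numpy()
    cr = (meta["group"] == "CR").to_numpy().astype(float)
    subj_codes, subj_idx = np.unique(meta["subject_id"], return_inverse=True)

    # gene-level abundance (log2 TPM units, unnormalized)
    base = rng.normal(4.0, 1.5, len(genes))
    u = rng.normal(0.0, subject_sd, (len(genes), len(subj_codes)))
    shift = np.array([expression_shift.get(g, 0.0) for g in genes])
    log2_abund = (base[:, None] + np.outer(shift, cr * t) + u[:, subj_idx]
                  + rng.normal(0.0, residual_sd, (len(genes), n_s)))
    abund = np.exp2(log2_abund)

    # isoform proportions per gene x sample
    true_tpm = np.zeros((len(tx), n_s))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, idx in pd.Series(range(len(tx)), index=gene_of_tx).groupby(level=0):
        rows = idx.to_numpy()
        k = len(rows)
        gi = gene_index[g]
        logw = np.log(rng.dirichlet(np.full(k, 2.0)) + 1e-12)[:, None] * np.ones((k, n_s))
        if g in usage_shift and k >= 2:
            logw[0, :] += usage_shift[g] * cr * t
        w = np.exp(logw)
        props = w / w.sum(axis=0, keepdims=True)
        true_tpm[rows, :] = props * abund[gi][None, :]

    true_tpm *= 1e6 / true_tpm.sum(axis=0, keepdims=True)

    out = []
    for _ in range(2):
        noisy = true_tpm * np.exp(rng.normal(0.0, quantifier_sigma, true_tpm.shape)) \
            if quantifier_sigma > 0 else true_tpm.copy()
        noisy *= 1e6 / noisy.sum(axis=0, keepdims=True)
        out.append(pd.DataFrame(noisy, index=tx, columns=meta["sample_id"].to_numpy()))
    return out[0], out[1]


def expression_pathway_deltas(counts: pd.DataFrame, meta: pd.DataFrame,
                              pathways: dict[str, list[str]],
                              visits_attended: dict[str, list[str]]) -> pd.DataFrame:
    """Realized pathway-score changes derived from the simulated counts.

    Scores are per-sample means of z-scored log2-CPM over the pathway's
    genes; the delta is last attended follow-up minus baseline.  Feeding
    these into :func:`simulate_phenotypes` couples strength changes to the
    expression matrix itself, so downstream expression-derived scores carry
    genuine subject-level mediation signal.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    expr = np.log2(counts.to_numpy() / lib[None, :] * 1e6 + 1.0)
    expr = pd.DataFrame(expr, index=counts.index, columns=counts.columns)
    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
    sm = meta.set_index("sample_id")
    cols = {}
    for name, genes in pathways.items():
        present = [g for g in genes if g in z.index]
        score = z.loc[present].mean(axis=0)
        cols[name] = score
    scores = pd.DataFrame(cols)
    scores["subject_id"] = sm.loc[scores.index, "subject_id"].to_numpy()
    scores["visit"] = sm.loc[scores.index, "visit"].to_numpy()
    rows = {}
    for sid, vis in visits_attended.items():
        sub = scores[scores.subject_id == sid].set_index("visit")
        follow = "24mo" if "24mo" in vis else "12mo"
        rows[sid] = (sub.loc[follow, list(pathways)]
                     - sub.loc["Ba", list(pathways)]).astype(float)
    return pd.DataFrame(rows).T


def simulate_pathway_deltas(subjects: pd.DataFrame, pathway_names: list[str],
                            truth: PhenotypeTruth, seed: int = 0) -> pd.DataFrame:
    """True standardized pathway-expression changes per subject.

    Every pathway separates the arms by ``truth.pathway_shift`` SD (CR minus
    AL) on top of unit subject noise; which pathways actually transmit the
    CR strength effect is decided by ``truth.mediated_fractions``.
    """
    rng = np.random.default_rng(seed)
    cr = (subjects["group"] == "CR").to_numpy().astype(float)
    data = {p: truth.pathway_shift * cr + rng.normal(0.0, 1.0, len(subjects))
            for p in pathway_names}
    return pd.DataFrame(data, index=subjects["subject_id"].to_numpy())


def simulate_phenotypes(subjects: pd.DataFrame, visits_attended: dict[str, list[str]],
                        pathway_deltas: pd.DataFrame, truth: PhenotypeTruth,
                        seed: int = 0, bilateral_sd: float = _BILATERAL_SD) -> pd.DataFrame:
    """Leg lean mass and four knee-extension strength variables per visit.

    The subject's change to the last attended follow-up is
    ``direct*CR + sum_j gamma_j * DeltaPathway_j + mass_effect*z(DeltaMass)
    + noise`` in change-SD units, where ``gamma_j`` is sized so pathway j
    carries ``truth.mediated_fractions[j]`` of the total CR effect.  Mass
    change is more negative under CR.  Left/right strength values are the
    common value plus small bilateral noise.
    """
    truth.validate()
    for sid, vis in visits_attended.items():
        if "Ba" not in vis or not any(v in vis for v in ("12mo", "24mo")):
            raise ValueError(f"subject {sid} lacks baseline plus a follow-up; "
                             "phenotype change undefined")
    rng = np.random.default_rng(seed)
    subjects = subjects[subjects["subject_id"].isin(visits_attended)].reset_index(drop=True)
    n = len(subjects)
    cr = (subjects["group"] == "CR").to_numpy().astype(float)

    mass_ba = rng.normal(17.5, 2.5, n)
    dmass = truth.cr_mass_loss * cr + rng.normal(0.0, 0.4, n)
    zmass = (dmass - dmass.mean()) / dmass.std(ddof=1) if n > 1 else dmass * 0.0

    fracs = truth.mediated_fractions
    direct = truth.total_cr_effect * (1.0 - sum(fracs.values()))
    systematic = direct * cr + truth.mass_effect * zmass
    for p, f in fracs.items():
        pd_z = pathway_deltas.loc[subjects["subject_id"], p].to_numpy()
        pd_z = (pd_z - pd_z.mean()) / pd_z.std(ddof=1)
        # size the pathway coefficient against the realized arm separation
        # so the pathway carries exactly fraction f of the CR effect
        a = pd_z[cr == 1].mean() - pd_z[cr == 0].mean()
        if abs(a) < 1e-6:
            raise ValueError(f"pathway {p} has no arm separation; cannot "
                             "carry a mediated fraction")
        systematic = systematic + (truth.total_cr_effect * f / a) * pd_z

    rows = []
    for i, s in subjects.iterrows():
        base = {v: rng.normal(_STRENGTH_BASE[v], _STRENGTH_BASE_SD) for v in STRENGTH_VARS}
        dz = {v: systematic[i] + rng.normal(0.0, truth.noise_sd) for v in STRENGTH_VARS}
        vis = visits_attended[s.subject_id]
        last_follow = "24mo" if "24mo" in vis else "12mo"
        for visit in vis:
            if visit == "Ba":
                frac = 0.0
            elif visit == last_follow:
                frac = 1.0
            else:  # intermediate 12mo when 24mo also attended
                frac = VISIT_YEARS["12mo"] / VISIT_YEARS["24mo"]
            row = {"subject_id": s.subject_id, "group": s.group, "sex": s.sex,
                   "visit": visit,
                   "leg_lean_mass": mass_ba[i] + frac * dmass[i]}
            for v in STRENGTH_VARS:
                common = base[v] + frac * dz[v] * _STRENGTH_CHANGE_SD
                row[f"{v}_left"] = common + rng.normal(0.0, bilateral_sd)
                row[f"{v}_right"] = common + rng.normal(0.0, bilateral_sd)
            rows.append(row)
    return pd.DataFrame(rows)


def attended_visits(meta: pd.DataFrame, require_followup: bool = True) -> dict[str, list[str]]:
    """Map subject -> attended visits, optionally keeping only subjects with
    a baseline and at least one follow-up (the mediation-eligible subset)."""
    out: dict[str, list[str]] = {}
    for sid, grp in meta.groupby("subject_id"):
        vis = [v for v in VISITS if v in set(grp["visit"])]
        if require_followup and ("Ba" not in vis or len(vis) < 2):
            continue
        out[sid] = vis
    return out


def simulate_dataset(config: CohortConfig | None = None,
                     effects: EffectSpec | None = None,
                     truth: PhenotypeTruth | None = None,
                     n_noncoding: int = 0, seed: int = 0) -> dict:
    """Full bundle for an end-to-end run, with child seed streams spawned
    from one root in a documented order (cohort, counts, transcripts,
    phenotypes)."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_counts, s_tx, s_pheno = (int(c.generate_state(1)[0]) % (2**31)
                                         for c in ss.spawn(4))
    config = config or CohortConfig()
    config.seed = s_cohort
    effects = effects or default_effects(n_genes=800, n_pathways=16,
                                         n_active_pathways=3, seed=s_counts)
    truth = truth or PhenotypeTruth(mediated_fractions={"PW00": 0.3})

    meta, subjects = simulate_cohort(config)
    counts = simulate_counts(meta, effects, seed=s_counts)

    genes = list(counts.index)
    ann_rng = np.random.default_rng(s_counts)
    coding_map = default_gene_map(genes, seed=s_counts)
    annotation = pd.DataFrame({"gene_id": genes, "biotype": "protein_coding"})
    if n_noncoding:
        nc_genes = [f"nc{i:04d}" for i in range(n_noncoding)]
        nc_counts = pd.DataFrame(
            ann_rng.poisson(3.0, (n_noncoding, counts.shape[1])),
            index=nc_genes, columns=counts.columns)
        counts = pd.concat([counts, nc_counts])
        annotation = pd.concat([annotation,
                                pd.DataFrame({"gene_id": nc_genes, "biotype": "other"})])
    usage_genes = {g: 1.0 for g in effects.pathways.get("PW01", [])[:10]}
    tpm_a, tpm_b = simulate_transcripts(meta, coding_map, seed=s_tx,
                                        usage_shift=usage_genes,
                                        expression_shift=dict(effects.b1))

    vis = attended_visits(meta)
    pdelta = expression_pathway_deltas(counts, meta, effects.pathways, vis)
    phenotypes = simulate_phenotypes(subjects, vis, pdelta, truth, seed=s_pheno)

    return {"meta": meta, "subjects": subjects, "counts": counts,
            "annotation": annotation.reset_index(drop=True),
            "gene_map": coding_map, "tpm_a": tpm_a, "tpm_b": tpm_b,
            "gene_sets": effects.pathways, "phenotypes": phenotypes,
            "pathway_deltas": pdelta,
            "truth": {"b1": effects.b1, "usage_shift_genes": sorted(usage_genes),
                      "mediated_fractions": truth.mediated_fractions,
                      "total_cr_effect": truth.total_cr_effect, "seed": seed}}


def write_fixtures(dataset: dict, outdir: str | Path) -> None:
    """Write the bundle as plain-text fixtures; reading back reproduces the
    matrices exactly (values are written in full precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_matrix(dataset["counts"], outdir / "counts.tsv", "gene_id")
    io.write_matrix(dataset["tpm_a"], outdir / "tpm_quantifier_a.tsv", "transcript_id")
    io.write_matrix(dataset["tpm_b"], outdir / "tpm_quantifier_b.tsv", "transcript_id")
    io.write_table(dataset["gene_map"], outdir / "transcript_map.tsv")
    io.write_table(dataset["meta"], outdir / "sample_metadata.tsv")
    io.write_table(dataset["annotation"], outdir / "gene_annotation.tsv")
    io.write_table(dataset["phenotypes"], outdir / "phenotypes.tsv")
    io.write_gmt(dataset["gene_sets"], outdir / "gene_sets.gmt")
    io.write_json(dataset["truth"], outdir / "truth.json")
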