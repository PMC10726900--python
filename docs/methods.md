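# Methods

`crmuscle` re-implements, as a tested pipeline over synthetic cohorts, the
analysis chain used to ask whether two years of moderate calorie
restriction (CR) changes the human skeletal-muscle transcriptome and
whether those changes transmit part of CR's effect on mass-adjusted muscle
strength.  This note documents the models, the synthetic study conditions,
the numerical choices, and what the validation experiments do and do not
establish.

## Study design being emulated

A two-arm randomized trial: 57 subjects under ~12% sustained calorie
restriction and 33 ad-libitum (AL) controls, with vastus-lateralis biopsies
at baseline and two follow-ups.  Average biopsy intervals were 1.1 and 2.1
years, so "time" is continuous years `{0, 1.1, 2.1}`.  Follow-up biopsies
are frequently refused; refusal is unrelated to the muscle outcomes, so
missingness is missing-at-random (MAR) and a likelihood-based longitudinal
model remains valid without imputation.

## Per-gene mixed model

For each feature (gene on log2-CPM, transcript on log2(TPM+1) or usage
fractions):

    y_is = b0 + b1·Group_i×Time_s + b2·Group_i + b3·Time_s
           + b4·Age_i + b5·Bmi_i + b6·Sex_i + b7·Batch_i + b8·Race_i
           + u_i + e_is,     u_i ~ N(0, tau²),  e_is ~ N(0, sigma²)

`b1` — the CR-vs-AL trajectory-slope difference — is the effect of
interest; AL and baseline are reference levels.  A visit-indicator variant
replaces the linear term with per-visit contrasts and reports one row per
follow-up visit.  Fitting is REML.  Because the fixed design is shared
across thousands of features, the solver profiles out the single variance
ratio λ = tau²/sigma²: for V = sigma²(I + λZZ′) with a random intercept,
every GLS quantity reduces to per-subject sufficient statistics, leaving a
cheap bounded 1-D optimization per feature (~1 ms).  Agreement with
statsmodels' generic `MixedLM` (coefficients to 1e-4, variance components
to 1e-3) is asserted in the test suite.  Wald t tests use between-within
degrees of freedom, `n_subjects − rank(X)`; at 90 subjects the df choice
moves p-values negligibly, and the method used is recorded in the output.
The λ=0 boundary (and the one-observation-per-subject degenerate case,
where the criterion is flat in λ) is flagged and reduces to OLS.

DGE significance uses unadjusted p < 0.05 (p < 0.01 for the focused set);
transcript-level analyses use p < 0.01.  No FDR correction is applied at
the feature level by design — the enrichment stage consumes the full
ranking instead.

## Preprocessing

Non-protein-coding genes are removed, then genes with zero counts in ≥50%
of samples *in any* of the six arm-by-visit cells (the per-subgroup rule; a
`scope="total"` switch implements the pooled variant).  TMM scaling factors
use the standard double-trimmed (30% on M, 5% on A), inverse-variance-
weighted mean of log-ratios against the reference sample whose
upper-quartile fraction is closest to the mean; factors are renormalized to
geometric mean 1 and match edgeR's `calcNormFactors` to 1e-10 on fixtures.
log2-CPM uses a prior count of 1 (zeros map to 0, symmetric with the
transcript branch's log2(TPM+1)); the prior is configurable.

## Preranked GSEA with Monte-Carlo consensus

Genes are ranked by r = −log10(p)·sign(b1), p clipped at 1e-300, ties
broken lexicographically.  The enrichment score is the classic weighted
running-sum extremum (weight 1): hits add |r|^w normalized by the in-set
total, misses subtract 1/(N−n).  On exact magnitude ties between the
positive and negative extremum the positive one is taken (1e-12 tolerance).
The null permutes gene labels (in a preranked setting there is no phenotype
left to permute); p is two-sided on |ES|, p = (1 + #{|ES_perm| ≥
|ES|})/(nperm+1) — uniform under the null with attainable floor
1/(nperm+1).  NES divides ES by the mean |ES| of same-sign permutations.
BH adjustment is pooled across collections (per-collection switch
available); set sizes outside 10–500 after universe intersection are
skipped.

Permutation p-values near a decision threshold make the reported pathway
set run-to-run unstable.  The consensus layer re-runs the preranked
analysis `n_iter` times with child seeds and reports a pathway only if its
adjusted p < 0.05 in strictly more than 80% of iterations, together with
the median NES.

## Pathway scores and mediation

Pathway score = per-sample mean of leading-edge genes' z-scored (across all
samples) log2-CPM.  Subject changes take the 24-month value minus baseline,
falling back to 12 months when 24 is missing; subjects without baseline
plus a follow-up are dropped.  Changes of strength, mass and pathway scores
are Z-transformed, then:

    base:     ΔStrength ~ Group + ΔMass + Sex            (OLS)
    adjusted: base + ΔPathway_1 … ΔPathway_k,  k = 1..4

Percent mediation = 100·(|b_base| − |b_adj|)/|b_base|, using magnitudes so
sign flips count as full attenuation; negative values (suppression) are
possible.  Combinations reaching 20% are reported, along with the per-k
maximum and, when a pathway→category map is supplied, the best
category-distinct combination per k.  Near-collinear combinations
(|corr| > 0.999) are skipped.  This is the beta-attenuation criterion only
— no product-of-coefficients decomposition or bootstrap CI for indirect
effects is attempted, and attenuation by a CR-responsive but causally inert
pathway (a collinear proxy of the arm) cannot be distinguished from true
mediation at n = 44; the null-calibration experiment therefore uses
CR-unresponsive pathways as the clean null.

## Transcript branch

Transcripts must have TPM > 0 in ≥2 samples of *every* arm-by-visit cell;
genes left with one surviving isoform are dropped entirely.  DTE fits the
mixed model on log2(TPM+1); DTU on within-gene usage,
log2(TPM+1)/Σ_gene log2(TPM+1), which sums to 1 per gene-sample and is
undefined (treated as missing, not imputed) where the gene is silent in a
sample.  The denominator uses the surviving transcripts post-filter
(switchable).  Running both analyses on two independent quantifications of
the same samples and keeping transcripts with p < 0.01 in both guards
against quantifier-specific artifacts; the union of the DTE and DTU
intersections is the shared-variant set, tallied by transcript biotype and
cross-tabulated with gene-level DGE significance.

## Synthetic cohort generator

The generator defines the study conditions; its defaults were fixed once:

- Cohort: 57 CR / 33 AL; per-follow-up-visit dropout 0.6, chosen so the
  expected yield is 90 + 2·90·0.4 = 162 biopsies, the study's actual yield.
  Dropout draws never look at outcome values (MAR by construction).
  Covariates: age ~ N(39, 7²), BMI ~ N(25.4, 1.7²), 65% female, four race
  levels, three batches.  An optional flag adds two follow-up-only CR
  subjects (off by default).
- Counts: negative-binomial (gamma-Poisson) with dispersion 0.1 — typical
  bulk RNA-seq overdispersion — around a log-linear mean with baseline
  log2-CPM ~ N(5, 2²), subject random-intercept SD 0.3, extra lognormal
  noise SD 0.2, per-gene time slopes SD 0.05, and the planted Group×Time
  slopes in log2-CPM/year.  Library sizes are lognormal (σ_log 0.35, ≥2-fold
  spread).
- Transcripts: per-gene isoform proportions are Dirichlet(2); usage-shift
  genes drift their first isoform's log-weight by shift·CR·t.  The two
  quantifier matrices share the true signal and differ by multiplicative
  lognormal noise σ = 0.15 (no model of real Kallisto/RSEM disagreement
  exists; this is a plain noise model), each column renormalized to 1e6.
- Phenotypes: the subject's change to the last attended follow-up is
  direct·CR + Σ_j γ_j·ΔPathway_j + 0.4·z(ΔMass) + ε, with total CR effect
  0.8 change-SD, strength-change scale 10 Nm, ε SD 0.5, CR mass loss −0.8
  kg, bilateral measurement noise SD 2 Nm.  γ_j is sized against the
  realized standardized arm separation of ΔPathway_j so pathway j carries
  exactly its planted fraction of the CR effect.  In the full
  `simulate_dataset` bundle the ΔPathway values are computed from the
  simulated counts themselves (z-scored log2-CPM pathway means), so
  expression-derived scores downstream carry genuine subject-level
  mediation signal.
- Randomness: one root seed; child streams spawned in the documented order
  cohort, counts, transcripts, phenotypes.

What the generator does **not** emulate: gene-gene correlation beyond
pathway-structured means, batch effects beyond an additive covariate,
length/GC bias, read-level error, realistic quantifier-specific bias
(EM-convergence artifacts, multimapping), or informative dropout.  Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under its stated assumptions, not robustness to every failure
mode of real RNA-seq.

## Validation experiments and problem sizes

The acceptance script and `tests/test_acceptance.py` recompute, from
scratch: the printed-count filtering arithmetic (16,450 of 19,937 known
coding genes → 82.5% retained / 17.5% excluded); exactness of the streaming
ES against exhaustive prefix enumeration (100 random instances ≤50 genes)
and of TMM against an independent brute-force implementation (200-gene,
4-sample fixture with a DE block); type-I calibration of the interaction
test through the full NB-generator path (2000 genes, target [0.04, 0.06]);
recovery of a planted slope 0.5 (500 Gaussian fits, |bias| < 0.05);
consensus behavior over 100 iterations (planted pathway frequency 1.0,
null < 0.8); mediation calibration over 50 cohorts of 28 CR / 16 AL
(planted fraction 0.5 detected at k=1 in ≥80%, all-null cohorts unflagged
in ≥90%); the usage-sum invariant; recovery of 30 planted shared splice
variants across 20 simulated dual-quantifier runs (≥25); and the exact
rank-sum enumeration p = 1/20 for {1,2,3} vs {4,5,6}.  These sizes keep the
full suite comfortably within a desktop run while leaving the Monte-Carlo
bands narrow enough to be informative.

## Known limitations

- Satterthwaite df is not implemented; between-within df is a good
  approximation at this cohort size but will differ more in tiny cohorts.
- The consensus frequency is itself a Monte-Carlo estimate; with
  `n_iter=100` its resolution is 1%.
- Percent mediation is undefined when the base CR coefficient is ~0 and
  unstable when it is small; records carry the base coefficient so
  downstream consumers can filter.
- The DTU transform is scale-sensitive through the log2(TPM+1)
  nonlinearity: multiplying a sample's TPMs by a constant changes usage
  except in the large-TPM limit.
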