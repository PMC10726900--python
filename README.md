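# crmuscle

Longitudinal transcriptomics of calorie restriction (CR) in human skeletal
muscle, re-implemented as a tested, reusable pipeline and exercised on
synthetic cohorts with planted ground truth.

In the trial being emulated, 90 healthy adults (57 under ~12% sustained
calorie restriction, 33 ad-libitum controls) gave vastus-lateralis biopsies
at baseline and at 12- and 24-month follow-ups (with substantial,
missing-at-random refusal).  The scientific questions: which genes and
splice variants change differentially under CR, which biological pathways
they implicate, and whether those pathway-level expression changes mediate
CR's effect on mass-adjusted muscle strength.  The raw trial data live in a
controlled-access biorepository, so every stage here is validated against a
synthetic cohort generator that emulates the design and plants known
effects.

## What the pipeline computes

1. **Preprocess** — protein-coding restriction, an arm×visit zero-count
   filter, TMM normalization factors, log2-CPM.
2. **Mixed-model DGE** — per gene, REML fit of

   `GeneExp ~ β₀ + β₁·Group×Time + β₂·Group + β₃·Time + Age + Bmi + Sex + Batch + Race + uᵢ + εᵢ`

   with a subject random intercept; β₁ is the CR-vs-AL trajectory-slope
   difference (linear time in years, or per-visit contrasts).
3. **Consensus GSEA** — genes ranked by r = −log₁₀(p)·sign(β₁); weighted
   running-sum enrichment scores, gene-label permutation null, NES, pooled
   BH adjustment — all embedded in a Monte-Carlo ensemble that re-runs the
   analysis and reports a pathway only if adjusted-significant in >80% of
   iterations.
4. **Mediation** — pathway scores (mean z-scored log2-CPM of leading-edge
   genes), standardized subject-level changes, and an exhaustive k=1..4
   combination search for pathway sets whose inclusion attenuates the CR
   coefficient of `ΔStrength ~ Group + ΔMass + Sex` by ≥20%.
5. **Splicing** — transcript detection filters, differential transcript
   expression on log2(TPM+1) and usage on within-gene proportions, run on
   two independent quantifications and intersected at p<0.01, with biotype
   tallies.
6. **Phenotypes** — leg lean mass, bilateral averaging, paired-t and exact
   Wilcoxon change tests.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (seed 0), writing tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_differential_expression.py
python analysis/04_enrichment.py
python analysis/05_mediation.py
python analysis/06_splicing.py
python analysis/07_phenotype_changes.py
```

Selected output from an actual run:

```
cohort: 90 subjects, 146 biopsies (90 baseline)
planted: 75 genes with CR x time slopes, 10 usage-shift genes, mediated fractions {'PW00': 0.3}
...
 threshold  n_sig  n_up  n_down
      0.05    132    77      55
      0.01     76    60      16
planted CR-responsive genes recovered at p<0.01: 59/75
...
16 pathways tested, 3 reported by consensus:
  PW02: median NES +2.03, frequency 1.00, leading edge 24 genes
  PW00: median NES +2.01, frequency 1.00, leading edge 22 genes
  PW01: median NES +2.01, frequency 1.00, leading edge 24 genes
...
avg_power_180: base CR beta +1.14 (p=0.005, n=48), 1 combination(s) >= 20% mediation, max 20%
...
shared variants at p<0.01 in both quantifiers: 130 by DTE, 30 by DTU, 138 union, 22 in both analyses
leg lean mass, baseline -> 24mo:  CR paired t p = 2.16e-08, AL p = 0.613
```

Reading this: the cohort yields ~162 expected biopsies (146 realized at
this seed); the three planted CR-responsive pathways are exactly the three
the consensus reports (median NES ≈ +2, frequency 1.0); the planted
mediating pathway attenuates the CR strength coefficient; transcripts with
planted usage shifts surface in the dual-quantifier intersection; and only
the CR arm loses leg lean mass.

The same stages run from a YAML config through the CLI:

```bash
crmuscle simulate --seed 3 --out fixtures/
crmuscle run --config run.yaml --out out/
```

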