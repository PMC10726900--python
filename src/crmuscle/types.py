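"""Shared configuration and result containers.

Matrices travel as pandas DataFrames (features as rows, samples as columns);
sample metadata as a tidy DataFrame with one row per biopsy sample.  The
dataclasses here hold the knobs of the synthetic cohort generator and the
model design.
"""
from __future__ import annotations

from dataclasses import dataclass, field


VISITS = ("Ba", "12mo", "24mo")
#: Visit times in years from baseline (average biopsy intervals in the trial
#: were 1.1 y for the 12-month and 2.1 y for the 24-month follow-up).
VISIT_YEARS = {"Ba": 0.0, "12mo": 1.1, "24mo": 2.1}

ARMS = ("CR", "AL")

#: Required columns of the sample-metadata frame.
META_COLUMNS = (
    "sample_id", "subject_id", "group", "visit", "time_years",
    "age", "bmi", "sex", "race", "batch",
)


@dataclass
class CohortConfig:
    """Design of a synthetic two-arm longitudinal biopsy cohort.

    Defaults mirror the trial being emulated: 57 calorie-restriction (CR)
    and 33 ad-libitum (AL) subjects, three visits, and a per-follow-up-visit
    dropout probability of 0.6 so that the expected yield is
    90 + 2*90*0.4 = 162 biopsies.
    """

    n_cr: int = 57
    n_al: int = 33
    dropout_prob: float = 0.6
    seed: int = 0
    age_mean: float = 39.0
    age_sd: float = 7.0
    bmi_mean: float = 25.4
    bmi_sd: float = 1.7
    prop_female: float = 0.65
    race_probs: tuple[float, ...] = (0.78, 0.08, 0.08, 0.06)
    n_batches: int = 3
    followup_only_subjects: bool = False

    def validate(self) -> None:
        if self.n_cr < 1 or self.n_al < 1:
            raise ValueError("each arm needs at least one subject")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if abs(sum(self.race_probs) - 1.0) > 1e-9:
            raise ValueError("race_probs must sum to 1")


@dataclass
class EffectSpec:
    """Generative counterpart of the per-gene mixed model.

    ``b1`` holds the CR-vs-AL trajectory-difference slope per gene in
    log2-CPM units per year; genes absent from ``b1`` are null.  Counts are
    negative-binomial with gene-specific dispersion around a log-linear mean
    that includes a subject random intercept.
    """

    n_genes: int = 1000
    b1: dict[str, float] = field(default_factory=dict)
    pathways: dict[str, list[str]] = field(default_factory=dict)
    subject_sd: float = 0.3
    residual_sd: float = 0.2
    dispersion: float = 0.1
    baseline_log2cpm_mean: float = 5.0
    baseline_log2cpm_sd: float = 2.0
    time_slope_sd: float = 0.05
    lib_size_mean: float = 2.0e6
    lib_size_log_sd: float = 0.35

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for g, b in self.b1.items():
            if not (b == b and abs(b) < float("inf")):
                raise ValueError(f"non-finite interaction slope for {g}")


@dataclass
class PhenotypeTruth:
    """Ground truth for the strength-change mediation model.

    ``total_cr_effect`` is the CR-vs-AL difference in standardized strength
    change; ``mediated_fractions`` says how much of it flows through each
    pathway's expression change.  The residual fraction is direct.
    """

    total_cr_effect: float = 0.8
    mediated_fractions: dict[str, float] = field(default_factory=dict)
    mass_effect: float = 0.4
    cr_mass_loss: float = -0.8
    pathway_shift: float = 1.0
    noise_sd: float = 0.5

    def validate(self) -> None:
        fr = list(self.mediated_fractions.values())
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("mediated fractions must lie in [0, 1]")
        if sum(fr) > 1.0 + 1e-12:
            raise ValueError("mediated fractions must sum to <= 1")


@dataclass
class DesignSpec:
    """Fixed/random-effect layout of the per-feature mixed model.

    Fixed effects: Group x Time interaction, Group, Time, Age, Bmi, Sex,
    Batch, Race; random subject intercept.  ``time_coding`` switches between
    a continuous-years slope and per-visit indicator contrasts (baseline as
    reference, AL as reference arm).
    """

    time_coding: str = "linear_years"  # or "visit_indicators"
    covariates: tuple[str, ...] = ("age", "bmi", "sex", "race", "batch")

    def validate(self) -> None:
        if self.time_coding not in ("linear_years", "visit_indicators"):
            raise ValueError(f"unknown time coding {self.time_coding!r}")
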