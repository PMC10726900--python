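import numpy as np
import pandas as pd
import pytest

from crmuscle.simulate import simulate_cohort, simulate_counts, default_effects
from crmuscle.types import CohortConfig, EffectSpec


@pytest.fixture(scope="session")
def small_cohort():
    """12 CR / 8 AL subjects, no dropout: 60 samples."""
    meta, subjects = simulate_cohort(CohortConfig(n_cr=12, n_al=8,
                                                  dropout_prob=0.0, seed=101))
    return meta, subjects


@pytest.fixture(scope="session")
def full_cohort():
    """Study-sized cohort with default dropout."""
    return simulate_cohort(CohortConfig(seed=202))


@pytest.fixture(scope="session")
def small_counts(small_cohort):
    meta, _ = small_cohort
    effects = default_effects(n_genes=120, n_pathways=4, pathway_size=10,
                              n_active_pathways=1, active_slope=0.8, seed=7)
    return simulate_counts(meta, effects, seed=8), effects


def make_meta(n_subjects=20, n_per_arm=None, seed=0):
    """Small balanced complete-case metadata frame for direct model tests."""
    meta, _ = simulate_cohort(CohortConfig(
        n_cr=n_per_arm or n_subjects // 2, n_al=n_per_arm or n_subjects // 2,
        dropout_prob=0.0, seed=seed))
    return meta
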