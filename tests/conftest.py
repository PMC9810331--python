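"""Shared fixtures: synthetic cohorts and fits reused across test modules.

Everything is seeded; session-scoped fixtures amortize the cost of
simulating and fitting a 40-agent cohort across the analysis tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epinc.agents import CohortSpec, simulate_cohort
from epinc.analyses import build_analysis_table
from epinc.inference import HierarchicalLearningModel, transfer_subject_params
from epinc.samplers import SamplerConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

#: reduced sampler for desk-scale test fits
TINY = SamplerConfig(n_chains=2, n_warmup=250, n_draws=250)
FAST = SamplerConfig(n_chains=2, n_warmup=400, n_draws=400)


@pytest.fixture(scope="session")
def cohort40():
    """Default 40-agent cohort: RB2H learners (H = 0.05/0.10) with positive
    uncertainty-arbitration weights."""
    return simulate_cohort(CohortSpec(n_subjects=40), seed=101)


@pytest.fixture(scope="session")
def rb2h_fit(cohort40):
    deck_only = cohort40.trials[cohort40.trials["task"] == "deck_only"]
    return HierarchicalLearningModel("RB2H", sampler=FAST, seed=101).fit(deck_only)


@pytest.fixture(scope="session")
def table40(cohort40, rb2h_fit):
    combined = cohort40.trials[cohort40.trials["task"] == "deck_memory"]
    series = transfer_subject_params(rb2h_fit, combined)
    return build_analysis_table(cohort40.trials, series)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortSpec(n_subjects=6), seed=7)
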