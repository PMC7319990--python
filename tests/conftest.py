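"""Shared fixtures: small synthetic sessions and a trained cohort."""

from __future__ import annotations

import numpy as np
import pytest

from revlearn.config import AgentParams, PipelineConfig, SimConfig
from revlearn.synthetic import simulate_cohort, simulate_experiment


@pytest.fixture(scope="session")
def small_sessions():
    """One pre + two post sessions of 100 trials, default neuron cohort."""
    cfg = SimConfig(n_sessions_pre=1, n_sessions_post=2,
                    trials_per_session=100, seed=3)
    agent = AgentParams(reversal_trial=100, relearning_midpoint=200,
                        learning_slope=0.03)
    return simulate_experiment(cfg, agent=agent)


@pytest.fixture(scope="session")
def trained_cohort():
    """Three subjects through discrimination and reversal with a chance
    plateau after the reversal (relearning ramps up mid-way through the
    post-reversal sessions)."""
    cfg = SimConfig(n_sessions_pre=2, n_sessions_post=4, trials_per_session=150)
    agent = AgentParams(reversal_trial=300, relearning_midpoint=600,
                        learning_slope=0.025)
    return simulate_cohort(3, cfg, agent=agent, seed=11)


@pytest.fixture()
def fast_pipeline_config():
    return PipelineConfig(di_n_permutations=1000, eh_n_permutations=300,
                          n_boot=300)
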