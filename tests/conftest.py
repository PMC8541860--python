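"""Shared fixtures: small synthetic cohorts and survival draws."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wavprog.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A fast cohort: enough structure for every stage, small enough for CI."""
    return CohortConfig(
        n_tumor=120,
        n_normal=15,
        n_genes=400,
        n_probes=600,
        n_deg=60,
        n_dmp=70,
        n_prognostic=3,
        prognostic_beta=(0.9, -0.9, 0.8),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def simulate_survival(
    beta: float | np.ndarray,
    n: int,
    seed: int,
    censor_rate: float = 0.00625,
    baseline: float = 0.025,
):
    """Exponential survival with one (or several) standardized covariates."""
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, float))
    x = rng.normal(size=(len(beta), n))
    lp = beta @ x
    t_event = rng.exponential(1.0 / (baseline * np.exp(lp)))
    t_cens = (
        rng.exponential(1.0 / censor_rate, size=n)
        if censor_rate > 0
        else np.full(n, np.inf)
    )
    time = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    event = (t_event <= t_cens).astype(int)
    return x, time, event


@pytest.fixture
def survival_factory():
    return simulate_survival
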