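"""Shared fixtures. Expensive artifacts (trained networks, cohorts) are
session-scoped so the unit and acceptance suites share them."""

from __future__ import annotations

import numpy as np
import pytest

from corticomm.rnn.experiments import train_bistable_fixture, train_convergence_fixture
from corticomm.synthio import control_config, generate_cohort, reduced_connectivity_config


@pytest.fixture(scope="session")
def small_session():
    cfg = control_config(neurons_per_region=20, n_trials=40, seed=11)
    return generate_cohort(cfg, 1)[0]


@pytest.fixture(scope="session")
def medium_session():
    cfg = control_config(neurons_per_region=40, n_trials=60, seed=5)
    return generate_cohort(cfg, 1)[0]


@pytest.fixture(scope="session")
def cohort_pair():
    """Matched-seed control / reduced-connectivity cohorts (2 sessions each)."""
    kw = dict(neurons_per_region=30, n_trials=120)
    return (
        generate_cohort(control_config(seed=3, **kw), 2),
        generate_cohort(reduced_connectivity_config(seed=3, **kw), 2),
    )


@pytest.fixture(scope="session")
def convergence_rnn():
    """64-unit noise-free FORCE fixture: (model, targets, per-epoch MSE)."""
    return train_convergence_fixture(n=64, epochs=300, seed=0)


@pytest.fixture(scope="session")
def bistable_rnn():
    """64-unit noise-robust bistable fixture: (model, targets, per-epoch MSE)."""
    from corticomm.rnn.params import RNNParams
    from corticomm.rnn.targets import make_synthetic_targets

    params = RNNParams(
        n=64, epochs=300, seed=1, alpha_learn=1.0, noise_sd=0.25, p_init="inverse"
    )
    targets = make_synthetic_targets(params, seed=1, separation=0.8, baseline=0.1)
    model, targets, mse = train_bistable_fixture(seed=1, targets=targets)
    return model, targets, mse


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
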