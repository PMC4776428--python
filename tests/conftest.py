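"""Shared fixtures: planted-source data and a reusable small pipeline run."""

import numpy as np
import pytest

from stabica import RunConfig, make_fixture, run_pipeline


@pytest.fixture(scope="session")
def planted():
    """n=50, p=500 matrix with 3 planted non-Gaussian sources at SNR 10."""
    return make_fixture(50, 500, 3, snr=10.0, seed=1)


@pytest.fixture(scope="session")
def small_run(planted):
    """One full pipeline run at reduced size, shared across read-only tests."""
    X, S = planted
    cfg = RunConfig(n_runs=40, n_bootstrap=8, n_replace=5, n_inits=4, master_seed=7)
    return run_pipeline(X, cfg), S


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
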