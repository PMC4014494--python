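import numpy as np
import pytest

from popchaos import (DoseResponse, ExperimentConfig, LifeHistoryParams,
                      TreatmentConfig)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def small_treatment():
    """A short, cheap treatment config for bookkeeping tests."""
    return TreatmentConfig(concentration=0.0, n_days=120, n_runs=3, base_seed=7)


@pytest.fixture()
def small_experiment():
    """Two-concentration experiment long enough for the λ estimator."""
    return ExperimentConfig(concentrations=(0.0, 40.0), n_days=220, n_runs=4,
                            base_seed=11)


@pytest.fixture(scope="session")
def sine_series():
    return np.sin(2 * np.pi * np.arange(2000) / 40.0)
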