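import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from snpkpd import DEFAULT_DESIGN, default_params, simulate_trial
from snpkpd.population import VarianceComponents

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    """Published final-model estimates (theta, omega)."""
    return default_params("model")


@pytest.fixture(scope="session")
def table2_bootstrap():
    return default_params("bootstrap")


@pytest.fixture()
def rng():
    return np.random.default_rng(20150728)


@pytest.fixture(scope="session")
def small_design():
    return dataclasses.replace(DEFAULT_DESIGN, n_subjects=30)


@pytest.fixture(scope="session")
def noise_free_records(table2):
    """Deterministic dataset: all variances and residual error zero."""
    theta, _ = table2
    design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=12)
    omega0 = VarianceComponents()
    return simulate_trial(design, theta, omega0, np.random.default_rng(42))


@pytest.fixture(scope="session")
def simulated_records(table2):
    """A 60-subject dataset at the published values, fixed seed."""
    theta, omega = table2
    design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=60)
    return simulate_trial(design, theta, omega, np.random.default_rng(7))
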