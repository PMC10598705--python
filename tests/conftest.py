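import numpy as np
import pytest

from phenoflux import CohortConfig, STParams, generate_cohort


@pytest.fixture
def default_params() -> STParams:
    """Typical dark-acclimated single-turnover parameters."""
    return STParams(
        F0=1000.0, Fm=3000.0, sigma_PSII=500.0, rho=0.40,
        C0=0.0, alpha=0.6, tau1_us=600.0, tau2_us=12_000.0,
    )


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (no trace fitting; generation only)."""
    return generate_cohort(CohortConfig(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
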