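import numpy as np
import pytest

from soilstruct.hydraulics import KosugiBimodalParams
from soilstruct.synthetic import TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def ref_params() -> KosugiBimodalParams:
    """A well-separated two-domain parameter set used across the suite."""
    return KosugiBimodalParams(
        theta_r=0.05, theta_s=0.50, w=0.7, hm1=50.0, sigma1=0.8,
        hm2=2000.0, sigma2=1.2, Ks=100.0, tau=0.5,
    )


@pytest.fixture(scope="session")
def small_trial():
    """One-block trial bundle: 6 samples, enough to exercise every reader."""
    return simulate_trial(TrialDesign(seed=11, n_blocks=1))


@pytest.fixture(scope="session")
def random_params_pool():
    """A seeded pool of valid random parameter sets for property checks."""
    rng = np.random.default_rng(2024)
    pool = []
    for _ in range(40):
        theta_r = rng.uniform(0.0, 0.15)
        theta_s = rng.uniform(0.3, 0.6)
        pool.append(
            KosugiBimodalParams(
                theta_r=theta_r,
                theta_s=theta_s,
                w=rng.uniform(0.05, 0.95),
                hm1=10 ** rng.uniform(0.5, 3.0),
                sigma1=rng.uniform(0.3, 2.5),
                hm2=10 ** rng.uniform(1.0, 4.5),
                sigma2=rng.uniform(0.3, 2.5),
                Ks=10 ** rng.uniform(0.0, 3.0),
                tau=rng.uniform(-1.0, 2.0),
            )
        )
    return pool
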