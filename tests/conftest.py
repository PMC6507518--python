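import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aiptw.data import ClusteredDataset
from aiptw.simulate import (AssignmentCoefficients, ScenarioConfig,
                            generate_dataset)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def toy_dataset() -> ClusteredDataset:
    """Three clusters: one mixed, one all-control, one all-treated."""
    return ClusteredDataset(
        cluster_id=np.array(["A", "A", "A", "B", "B", "C", "C"], dtype=object),
        t=np.array([1, 0, 0, 0, 0, 1, 1]),
        y=np.array([10.0, 6.0, 6.0, 5.0, 7.0, 9.0, 11.0]),
    )


@pytest.fixture(scope="session")
def randomized_config() -> ScenarioConfig:
    """Completely randomized assignment (no confounding), moderate noise."""
    return ScenarioConfig(K=60, nk_lo=4, nk_hi=12, beta0=35.0, beta1=40.0,
                          sigma0=8.0, sigma1=8.0, rho=0.8, sigma_eps=20.0,
                          r0=0.0, r1=0.0, p=0.5, violation_frac=0.1)


@pytest.fixture(scope="session")
def null_coeffs() -> AssignmentCoefficients:
    """Pure-noise assignment mechanism: T is a fair coin everywhere."""
    return AssignmentCoefficients(0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def no_violation_dataset(randomized_config, null_coeffs) -> ClusteredDataset:
    """Randomized clusters large enough that every cluster shows both arms."""
    cfg = ScenarioConfig(K=40, nk_lo=20, nk_hi=30, beta0=35.0, beta1=40.0,
                         sigma0=8.0, sigma1=8.0, rho=0.8, sigma_eps=20.0,
                         r0=0.0, r1=0.0, p=0.5, violation_frac=0.0)
    gen = generate_dataset(cfg, null_coeffs, seed=2024)
    codes, _ = gen.dataset.cluster_codes()
    n = np.bincount(codes)
    n1 = np.bincount(codes, weights=gen.dataset.t)
    assert ((n1 > 0) & (n1 < n)).all(), "fixture must have no violating cluster"
    return gen.dataset
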