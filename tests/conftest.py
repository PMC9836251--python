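import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "batirt",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("batirt")

from batirt import (  # noqa: E402
    MCConfig,
    SegmentationJitter,
    adult_scene,
    crossover_scene,
    empirical_error_budget,
    grid_scan,
    neonate_scene,
)

REFERENCE_SIGMA_AREA = 10.0
REFERENCE_SIGMA_TEMP = 0.02


@pytest.fixture(scope="session")
def reference_grid():
    """Full 21x15 lattice at the grid-calibration sigmas, 1e5 draws/cell."""
    return grid_scan(
        MCConfig(
            sigma_area=REFERENCE_SIGMA_AREA,
            sigma_temp=REFERENCE_SIGMA_TEMP,
            n_samples=100_000,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def operator_jitter():
    return SegmentationJitter(magnitude=10.0)


@pytest.fixture(scope="session")
def neonate_budget(operator_jitter):
    return empirical_error_budget(
        neonate_scene(seed=0), operator_jitter, n_replicates=800, seed=0
    )


@pytest.fixture(scope="session")
def adult_budget(operator_jitter):
    return empirical_error_budget(
        adult_scene(seed=0), operator_jitter, n_replicates=800, seed=0
    )


@pytest.fixture(scope="session")
def crossover_budget(operator_jitter):
    return empirical_error_budget(
        crossover_scene(seed=0), operator_jitter, n_replicates=800, seed=0
    )
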