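import numpy as np
import pytest

from geudpred.dvh import CumulativeDVH
from geudpred.pipeline import PipelineConfig
from geudpred.synth import CohortConfig, generate_cohort


@pytest.fixture
def ramp_cdvh() -> CumulativeDVH:
    """Linear ramp: edges (0,10,20) Gy, volumes (100,50,0) cc."""
    return CumulativeDVH(np.array([0.0, 10.0, 20.0]), np.array([100.0, 50.0, 0.0]))


@pytest.fixture
def step_cdvh() -> CumulativeDVH:
    """Piecewise curve: edges (0,20,40,60) Gy, volumes (100,60,20,0) cc."""
    return CumulativeDVH(
        np.array([0.0, 20.0, 40.0, 60.0]), np.array([100.0, 60.0, 20.0, 0.0])
    )


def uniform_cdvh(dose_edge: float = 60.0, total_cc: float = 10.0) -> CumulativeDVH:
    """A structure irradiated uniformly; its single hot bin is centred at
    ``dose_edge + 0.5`` on a 1-Gy grid."""
    edges = np.arange(0.0, dose_edge + 2.0)
    vol = np.where(edges <= dose_edge, total_cc, 0.0)
    return CumulativeDVH(edges, vol)


@pytest.fixture(scope="session")
def default_cohort():
    """One labeled synthetic cohort at the default study conditions."""
    cohort, provenance = generate_cohort(CohortConfig(seed=11))
    return cohort, provenance


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()
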