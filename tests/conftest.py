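import numpy as np
import pytest

from rsndr.synthetic_data import CohortConfig, EffectSpec, simulate_cohort
from rsndr.volio import BrainMask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_mask():
    """3-voxel-radius ball in a 8x8x6 grid."""
    data = np.zeros((8, 8, 6), dtype=bool)
    ijk = np.indices(data.shape)
    data[((ijk[0] - 4) ** 2 + (ijk[1] - 4) ** 2 + (ijk[2] - 3) ** 2) <= 9] = True
    return BrainMask(data=data, affine=np.diag([4.0, 4.0, 4.0, 1.0]))


@pytest.fixture(scope="session")
def small_cohort():
    """Fast null cohort reused by read-only tests (do not mutate)."""
    cfg = CohortConfig(
        grid_shape=(16, 16, 12),
        n_patients=4,
        n_controls=4,
        t_points=60,
        n_networks=4,
        min_center_separation=4.0,
        brain_frac=0.8,
    )
    return simulate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def amplitude_cohorts():
    """Cohorts with a 2x amplitude effect on network 0, well-separated blobs."""
    cfg = CohortConfig(
        n_patients=10,
        n_controls=10,
        n_networks=6,
        width_range=(1.2, 1.5),
        min_center_separation=7.0,
        brain_frac=0.9,
        effects=(EffectSpec(network_index=0, amplitude_ratio=2.0),),
    )
    return [simulate_cohort(cfg, seed=s) for s in range(71, 76)]
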