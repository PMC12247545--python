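import numpy as np
import pytest

import somasearch as ss


@pytest.fixture(scope="session")
def small_grid():
    """12-cube grid with an ellipsoid mask — big enough for radius-2 spheres."""
    return ss.ellipsoid_mask_grid((12, 12, 12))


@pytest.fixture(scope="session")
def open_grid():
    """All-true mask on a 9-cube grid, for geometry oracles without clipping."""
    return ss.VolumeGrid(shape=(9, 9, 9), mask=np.ones((9, 9, 9), dtype=bool))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Seeded 6-subject cohort with one strong central signal ROI (16-cube)."""
    cfg = ss.default_config(
        n_subjects=6,
        shape=(16, 16, 16),
        roi_halfwidth=2,
        amplitude=float(np.sqrt(125)),  # per-voxel signal sd == noise sd
        noise_sd=1.0,
        seed=11,
    )
    maps, traits = ss.generate_cohort(cfg)
    return cfg, maps, traits
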