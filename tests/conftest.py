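import numpy as np
import pytest

from dyspredict.core import GridSpec, Tractogram
from dyspredict.pipeline import PipelineConfig, stage_disconnectome, stage_simulate
from dyspredict.disconnectome import RasterizedCohort


@pytest.fixture(scope="session")
def grid32():
    """32^3 grid with 2 mm voxels, origin-centred."""
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = -32.0
    return GridSpec((32, 32, 32), aff)


@pytest.fixture(scope="session")
def random_tractogram(grid32):
    """2000 random-walk streamlines crossing the grid."""
    rng = np.random.default_rng(7)
    sls = []
    for _ in range(2000):
        n = int(rng.integers(5, 60))
        pts = np.cumsum(rng.normal(0, 2.0, (n, 3)), axis=0) + rng.uniform(-40, 40, 3)
        sls.append(pts)
    return Tractogram("rand", sls)


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down pipeline configuration for fast end-to-end tests."""
    return PipelineConfig(
        n_parcels=16,
        n_subjects=6,
        n_patients=12,
        bundles=8,
        n_bundle_pairs=30,
        permutations=20,
        small_lesion_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return stage_simulate(small_cfg)


@pytest.fixture(scope="session")
def small_maps(small_cfg, small_cohort):
    raster = RasterizedCohort(small_cohort.tractograms, small_cohort.grid)
    psdms, tsdms, volumes, overlap = stage_disconnectome(small_cfg, small_cohort, raster)
    return raster, psdms, tsdms, volumes, overlap
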