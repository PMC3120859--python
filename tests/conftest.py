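import numpy as np
import pytest

from rhizotrack.synthetic import (
    DivisionModel,
    KinematicsParams,
    OpticsParams,
    evolve,
    simulate_root,
)


@pytest.fixture(scope="session")
def small_root():
    """A small static root used across segmentation/registration tests."""
    return simulate_root(radius=15.0, length=120.0, spacing=10.0, seed=11)


@pytest.fixture(scope="session")
def quiet_kinematics():
    """No drift, no jitter — frozen dynamics."""
    return KinematicsParams(
        expansion_rate_early=0.0,
        expansion_rate_late=0.0,
        rotation_rate=0.0,
        jitter_step_mean=0.0,
        jitter_step_sd=0.0,
    )


@pytest.fixture(scope="session")
def no_divisions():
    return DivisionModel(rate_peak=0.0)


@pytest.fixture(scope="session")
def coarse_optics():
    """Imaging model matched to a 30 µm-diameter root."""
    return OpticsParams.calibrated(30.0)


def make_record(idx, t, pos, **kw):
    from rhizotrack.types import NucleusRecord

    defaults = dict(
        max_intensity=100.0,
        mean_intensity=50.0,
        voxel_count=20,
        lateral_size=4.5,
        lateral_eccentricity=0.3,
        axial_size=3.2,
    )
    defaults.update(kw)
    return NucleusRecord(id=idx, time=t, centroid=np.asarray(pos, float), **defaults)
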