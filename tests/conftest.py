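import numpy as np
import pytest

from phasecorr.loc_data import RoiMask
from phasecorr.synthetic_data import BlinkModel, SceneSpec, generate_scene, sample_localizations


@pytest.fixture
def square_mask():
    """10 x 10 um analysis ROI on the default 25 nm grid."""
    return RoiMask.rectangle(10_000.0, 10_000.0)


@pytest.fixture
def small_mask():
    """5 x 5 um ROI for quicker correlation tests."""
    return RoiMask.rectangle(5_000.0, 5_000.0)


@pytest.fixture
def coclustered_scene():
    spec = SceneSpec(
        mode="co_clustered",
        fov_nm=(5000.0, 5000.0),
        n_discs=20,
        disc_radius_nm=50.0,
        molecules_per_disc=10,
        seed=11,
    )
    return generate_scene(spec)


@pytest.fixture
def coclustered_locs(coclustered_scene):
    blink = BlinkModel(mean_observations=15.0, n_frames=5000, localization_sigma=15.0)
    return sample_localizations(coclustered_scene, blink, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
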