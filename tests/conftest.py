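import numpy as np
import pytest
from scipy import ndimage

from incuscan.camera import CameraConfig, build_specimen
from incuscan.motion import StageConfig, VirtualStage
from incuscan.optics import derive_profile
from incuscan.plate import PlateSpec


@pytest.fixture
def plate6() -> PlateSpec:
    """A landmark-calibrated 6-well plate (geometry from the worked example)."""
    return PlateSpec(
        format=6, well_diameter=36.0, pitch_x=39.0, pitch_y=39.0, a1_center=(30.0, 28.0)
    )


@pytest.fixture
def profile_10x():
    """10x objective on the default sensor: FOV 1300 x 929 µm, 0.8 overlap."""
    return derive_profile(1.292, (1680, 1200), 0.8, label="10X")


@pytest.fixture
def survey_camera() -> CameraConfig:
    """Low-magnification rig used for motion validation: the 2.8 x 2 mm field
    keeps even a 1.3 mm realized move well inside one frame."""
    return CameraConfig(resolution=(840, 600), pixels_per_um=0.3, noise_sd=2.0, seed=1)


@pytest.fixture
def small_camera() -> CameraConfig:
    """Tiny noise-free sensor for fast geometric checks."""
    return CameraConfig(resolution=(400, 300), pixels_per_um=1.3, noise_sd=0.0)


@pytest.fixture
def cells_specimen():
    """Trackable monolayer texture spanning a 4 x 4 mm window."""
    return build_specimen("cells", n=120, window_mm=(4.0, 4.0), seed=5)


@pytest.fixture
def quiet_stage() -> VirtualStage:
    """Perfectly calibrated, noise-free stage."""
    return VirtualStage(StageConfig(position_noise_sd=0.0))


def make_edge_image(shape=(200, 200), angle_deg=5.0, sigma=0.0,
                    low=40.0, high=180.0) -> np.ndarray:
    """Slanted step edge sampled at pixel centres, optionally Gaussian-blurred."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    t = np.deg2rad(angle_deg)
    dist = (xx - w / 2) * np.cos(t) - (yy - h / 2) * np.sin(t)
    img = np.where(dist > 0, high, low).astype(float)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma)
    return img
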