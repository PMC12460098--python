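import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pensonar import CFPImage, SonarConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config() -> SonarConfig:
    """Coarse sonar geometry used throughout the fast tests (10 m range)."""
    return SonarConfig(
        n_bearings=120, n_range_bins=50, range_resolution=0.2,
        scan_period=8.0, exclusion_radius=0.6,
    )


@pytest.fixture
def default_config() -> SonarConfig:
    return SonarConfig()


def make_cfp(pixels: np.ndarray, config: SonarConfig, metres_per_pixel: float, **meta) -> CFPImage:
    """Wrap a raw raster as a CFP image (window/frame bookkeeping stubbed)."""
    side = pixels.shape[0]
    return CFPImage(
        pixels=pixels,
        centre=((side - 1) // 2, (side - 1) // 2),
        metres_per_pixel=metres_per_pixel,
        window=(0.0, 50.0),
        n_frames=1,
        config=config,
        **meta,
    )


def annulus_raster(
    config: SonarConfig,
    metres_per_pixel: float,
    inner_px: int,
    width_px: int = 20,
    value: float = 1.0,
) -> np.ndarray:
    """Clean annular echo band starting at ``inner_px`` from the centre."""
    half = int(np.ceil(config.max_range / metres_per_pixel))
    side = 2 * half + 1
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    radius = np.hypot(rr - half, cc - half)
    pixels = np.zeros((side, side))
    pixels[(radius >= inner_px) & (radius < inner_px + width_px)] = value
    # stay inside the instrumented disc: everything past max range must be 0
    pixels[radius * metres_per_pixel > config.max_range] = 0.0
    return pixels
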