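import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from radfilm import DosePlane, centered_plane, default_film_model

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def smooth_random_plane(
    seed: int,
    shape: tuple[int, int] = (48, 48),
    spacing_mm: float = 1.0,
    d_max_gy: float = 10.0,
    smooth_px: float = 4.0,
) -> DosePlane:
    """A seeded smooth, strictly positive dose plane for gamma testing."""
    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_px)
    raw -= raw.min()
    if raw.max() > 0:
        raw /= raw.max()
    dose = d_max_gy * (0.2 + 0.8 * raw)  # keep everything above the 10% threshold
    return centered_plane(dose, spacing_mm, provenance="plan")


@pytest.fixture(scope="session")
def film_model():
    return default_film_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
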