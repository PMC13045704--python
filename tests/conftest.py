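import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from PIL import Image

from spinecobb import SpineMask, SpinePhantomSpec, rasterize

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_band_mask(height=100, width=60, col_lo=10, col_hi=20, **kwargs) -> SpineMask:
    """Solid vertical band occupying columns [col_lo, col_hi] in every row."""
    v = np.zeros((height, width), dtype=np.uint8)
    v[:, col_lo : col_hi + 1] = 1
    return SpineMask(v, **kwargs)


@pytest.fixture
def band_mask():
    return make_band_mask()


@pytest.fixture
def band_mask_factory():
    return make_band_mask


@pytest.fixture
def s_curve_mask():
    """Rasterized s-curve phantom with analytic Cobb 50.463 degrees."""
    spec = SpinePhantomSpec(
        family="s_curve",
        params={"x0": 160.0, "amplitude": 30.0, "period": 400.0, "phase": 0.0},
        seed=3,
    )
    _, mask = rasterize(spec)
    return spec, mask


@pytest.fixture
def png_writer(tmp_path):
    """Write a 2-D uint8/uint16 array (or RGB) to a PNG, return the path."""

    def _write(arr, name="img.png"):
        p = tmp_path / name
        Image.fromarray(arr).save(p)
        return p

    return _write
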