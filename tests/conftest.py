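import numpy as np
import pytest

from fibrilcyte import CellPopulationModel, FibrilArraySpec, TipCalibration


@pytest.fixture
def small_spec():
    """A 300x300 um field at the default pixel size, axis along x."""
    return FibrilArraySpec(field_width=300.0, field_height=300.0)


@pytest.fixture
def default_calib():
    return TipCalibration()


@pytest.fixture
def aligned_model():
    return CellPopulationModel(orientation_kappa=8.0)


def rasterize_ellipse(a_um, b_um, theta_deg, pixel_size, pad_um=10.0):
    """Independent ellipse rasterizer used as measurement oracle input.

    Pixel centers at (i+0.5)*px in the x-right / y-down frame, matching the
    package's raster convention.
    """
    half = max(a_um, b_um) + pad_um
    npx = int(2 * half / pixel_size)
    yy, xx = np.mgrid[0:npx, 0:npx]
    x = (xx + 0.5) * pixel_size - half
    y = (yy + 0.5) * pixel_size - half
    t = np.deg2rad(theta_deg)
    u = x * np.cos(t) + y * np.sin(t)
    v = -x * np.sin(t) + y * np.cos(t)
    return ((u / a_um) ** 2 + (v / b_um) ** 2 <= 1).astype(np.int32)
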