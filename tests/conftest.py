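"""Shared fixtures: small geometries and reproducible random fields."""

import numpy as np
import pytest

from lamrec.geometry import LaminoGeometry


def make_geometry(
    n: int = 32,
    ntheta: int = 32,
    phi: float = 20.0,
    n3: int | None = None,
    center: float | None = None,
    span: float = 360.0,
) -> LaminoGeometry:
    n3 = n3 if n3 is not None else n // 2
    thetas = np.arange(ntheta) / ntheta * span
    return LaminoGeometry(
        phi=phi, thetas=thetas, det_nu=n, det_nv=n,
        vol_n1=n, vol_n2=n, vol_n3=n3, center=center,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geom32():
    return make_geometry(32, 32, 20.0)


def smooth_supported_volume(geom, rng, sigma=4.0):
    """Smooth random volume supported inside the reconstructible region
    (its projections stay on the detector for every angle)."""
    from scipy.ndimage import gaussian_filter

    n3, n2, n1 = geom.vol_shape
    z = (np.arange(n3) - n3 // 2) / (0.4 * n3)
    y = (np.arange(n2) - n2 // 2) / (0.4 * n2)
    x = (np.arange(n1) - n1 // 2) / (0.4 * n1)
    r2 = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    env = np.clip(1.2 * (1.0 - r2), 0.0, 1.0) ** 2
    return gaussian_filter(rng.standard_normal(geom.vol_shape), sigma) * env


def rel_rms(a, b):
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
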