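"""Beer-Lambert measurement simulation.

Converts line integrals of the attenuation field into raw detector counts:

    data = exp(-P mu) * (flat - dark) + dark,

optionally with Poisson counting noise applied to the pre-dark signal.
Running :func:`lamrec.recon.normalize_minus_log` on the result recovers the
noiseless line integrals exactly (the round trip is an identity).
"""

from __future__ import annotations

import numpy as np

from .geometry import LaminoGeometry, ProjectionStack, Volume3D
from .operators import forward_fourier, forward_line

__all__ = ["simulate_measurement"]


def simulate_measurement(
    vol: Volume3D,
    geom: LaminoGeometry,
    flat_level: float = 1.0,
    dark_level: float = 0.0,
    noise: str = "none",
    seed: int | None = None,
    projector: str = "fourier",
) -> ProjectionStack:
    """Simulate raw laminographic detector data for a volume.

    Parameters
    ----------
    flat_level, dark_level : float
        Detector counts with beam on (no sample) and beam off; must satisfy
        ``flat_level > dark_level >= 0``.  For Poisson noise, ``flat_level``
        sets the photon count per pixel (e.g. 1e4).
    noise : {'none', 'poisson'}
        Poisson noise is applied to the dark-subtracted signal.
    projector : {'fourier', 'line'}
        Which discretisation generates the line integrals.
    """
    if dark_level < 0 or flat_level <= dark_level:
        raise ValueError("need flat_level > dark_level >= 0")
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    if projector == "fourier":
        p = forward_fourier(vol, geom)
    elif projector == "line":
        p = forward_line(vol, geom)
    else:
        raise ValueError("projector must be 'fourier' or 'line'")

    signal = np.exp(-p) * (flat_level - dark_level)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        signal = rng.poisson(np.maximum(signal, 0.0)).astype(np.float64)
    data = signal + dark_level
    nv, nu = geom.det_nv, geom.det_nu
    dark = np.full((nv, nu), float(dark_level))
    flat = np.full((nv, nu), float(flat_level))
    return ProjectionStack(data=data, dark=dark, flat=flat, angles=geom.thetas.copy())
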