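"""Acquisition geometry and domain containers for parallel-beam computed
laminography.

Conventions
-----------
* The laminography tilt angle ``phi`` is the tilt of the rotation axis away
  from the vertical, in degrees; ``phi = 0`` is conventional parallel-beam
  tomography.  The axis is tilted along the beam.
* The sample volume ``mu(x1, x2, x3)`` is stored as an array of shape
  ``(n3, n2, n1)`` (x1 fastest); voxel coordinates are ``x_k = index - n_k//2``
  so the origin sits on an exact grid point.
* Projections ``d(theta, v, u)`` are indexed angle-slowest; the detector
  column through which the rotation axis projects is ``center`` (fractional,
  default ``det_nu / 2``), and the detector row origin is ``det_nv // 2``.
* Normalised frequencies are in cycles per voxel, in [-0.5, 0.5).

For rotation angle ``theta`` the 2D spectrum of a projection samples the 3D
object spectrum on the tilted plane

    xi1 =  su * cos(theta) + sv * sin(phi) * sin(theta)
    xi2 = -su * sin(theta) + sv * sin(phi) * cos(theta)
    xi3 =  sv * cos(phi)

where (su, sv) are the detector frequencies.  This map is a rotation of the
detector frequency plane, so it preserves the Euclidean norm, and for
``phi = 0`` it reduces to the classical Fourier-slice grid (``xi3 = sv``).
The union of these planes over a full turn misses the double cone of
directions within polar angle ``phi`` of the xi3 axis — the missing cone,
covering a solid-angle fraction ``1 - cos(phi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaminoGeometry",
    "Volume3D",
    "ProjectionStack",
    "FrequencyGrid",
    "CutPlan",
    "frequency_grid",
    "frequency_slice",
    "missing_cone_mask",
    "plan_slab_cuts",
]


@dataclass
class LaminoGeometry:
    """Laminographic acquisition geometry.

    Parameters
    ----------
    phi : float
        Tilt of the rotation axis from the vertical, degrees, 0 <= phi < 90.
    thetas : array of float
        Rotation angles in degrees, strictly increasing, spanning up to 360.
    det_nu, det_nv : int
        Detector columns and rows.
    vol_n1, vol_n2, vol_n3 : int
        Voxel counts of the reconstruction grid.
    center : float, optional
        Rotation-axis detector column (fractional); default ``det_nu / 2``.
    voxel_size : float
        Physical voxel edge length (arbitrary units).
    """

    phi: float
    thetas: np.ndarray
    det_nu: int
    det_nv: int
    vol_n1: int
    vol_n2: int
    vol_n3: int
    center: float | None = None
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=np.float64)
        if not (0.0 <= self.phi < 90.0):
            raise ValueError("phi must satisfy 0 <= phi < 90 degrees")
        if self.thetas.ndim != 1 or len(self.thetas) < 1:
            raise ValueError("thetas must be a non-empty 1D sequence")
        if len(self.thetas) > 1 and np.any(np.diff(self.thetas) <= 0):
            raise ValueError("thetas must be strictly increasing")
        if self.thetas[-1] - self.thetas[0] > 360.0:
            raise ValueError("thetas must span at most 360 degrees")
        for name in ("det_nu", "det_nv", "vol_n1", "vol_n2", "vol_n3"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.center is None:
            self.center = self.det_nu / 2.0
        if not (0.0 < self.center < self.det_nu):
            raise ValueError("center must lie strictly inside the detector")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.thetas)

    @property
    def phi_rad(self) -> float:
        return float(np.deg2rad(self.phi))

    @property
    def thetas_rad(self) -> np.ndarray:
        return np.deg2rad(self.thetas)

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        """Array shape (n3, n2, n1) of a matching volume."""
        return (self.vol_n3, self.vol_n2, self.vol_n1)

    @property
    def proj_shape(self) -> tuple[int, int, int]:
        """Array shape (n_angles, det_nv, det_nu) of a projection stack."""
        return (self.n_angles, self.det_nv, self.det_nu)

    def replace(self, **kw) -> "LaminoGeometry":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class Volume3D:
    """Attenuation field on a centred voxel grid, array shape (n3, n2, n1)."""

    values: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ProjectionStack:
    """Raw or corrected detector data d(theta, v, u) with dark/flat fields."""

    data: np.ndarray
    dark: np.ndarray
    flat: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.dark = np.asarray(self.dark)
        self.flat = np.asarray(self.flat)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3D (theta, v, u)")
        if self.data.shape[0] != len(self.angles):
            raise ValueError("data.shape[0] must equal len(angles)")
        if self.dark.shape != self.data.shape[1:] or self.flat.shape != self.data.shape[1:]:
            raise ValueError("dark/flat shapes must match one projection")


@dataclass
class FrequencyGrid:
    """Unequally spaced 3D frequencies (cycles/voxel) indexed (theta, sv, su)."""

    xi1: np.ndarray
    xi2: np.ndarray
    xi3: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.xi1.shape


@dataclass(frozen=True)
class CutPlan:
    """Sectioning plan for a large sample: pillars (tomography) vs slabs
    (laminography)."""

    sample_dims: tuple[float, float, float]
    pillar_width: float
    slab_thickness: float
    n_pillars: int
    n_slabs: int

    def __post_init__(self) -> None:
        if self.n_pillars < 1 or self.n_slabs < 1:
            raise ValueError("counts must be >= 1")
        if self.slab_thickness > self.pillar_width + 1e-12:
            raise ValueError("slab thickness cannot exceed pillar width")


def _sigma(n: int) -> np.ndarray:
    """Centred normalised frequency grid (cycles/sample) for size n."""
    return (np.arange(n) - n // 2) / float(n)


def frequency_slice(geom: LaminoGeometry, sv: float) -> tuple[np.ndarray, np.ndarray]:
    """(xi1, xi2) for one detector-row frequency ``sv``, arrays (ntheta, nu).

    Used by the Fourier operators, which process the volume spectrum one
    xi3-plane at a time (xi3 depends only on sv).
    """
    su = _sigma(geom.det_nu)[None, :]
    th = geom.thetas_rad[:, None]
    s = sv * np.sin(geom.phi_rad)
    xi1 = su * np.cos(th) + s * np.sin(th)
    xi2 = -su * np.sin(th) + s * np.cos(th)
    return xi1, xi2


def frequency_grid(geom: LaminoGeometry) -> FrequencyGrid:
    """Frequencies where projection spectra sample the object spectrum.

    Returns arrays of shape (n_angles, det_nv, det_nu).  At ``phi = 0`` the
    grid reduces to the parallel-beam Fourier-slice grid (xi3 == sv for all
    angles); the per-angle map (su, sv) -> xi is a rotation and preserves the
    Euclidean norm.
    """
    nv, nu = geom.det_nv, geom.det_nu
    sv = _sigma(nv)
    xi1 = np.empty((geom.n_angles, nv, nu))
    xi2 = np.empty_like(xi1)
    for iv, s in enumerate(sv):
        a, b = frequency_slice(geom, s)
        xi1[:, iv, :] = a
        xi2[:, iv, :] = b
    xi3 = np.broadcast_to(
        (sv * np.cos(geom.phi_rad))[None, :, None], xi1.shape
    ).copy()
    return FrequencyGrid(xi1=xi1, xi2=xi2, xi3=xi3)


def missing_cone_mask(
    geom: LaminoGeometry,
    grid_n: int,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Boolean mask of unsampled frequency directions and the missing
    solid-angle fraction.

    A direction ``s`` is sampled when some rotation angle makes the beam
    perpendicular to it, i.e. when ``|s3| sin(phi) <= sqrt(s1^2+s2^2)
    cos(phi)``; directions strictly inside the polar cone of half-angle
    ``phi`` about the xi3 axis are never sampled.  The mask is evaluated on a
    ``grid_n``^3 centred frequency grid; the solid-angle fraction is
    estimated by Monte Carlo over ``n_samples`` isotropic directions (it
    converges to ``1 - cos(phi)``).
    """
    if grid_n < 8:
        raise ValueError("grid_n must be >= 8")
    phi = geom.phi_rad
    f = _sigma(grid_n)
    x1, x2, x3 = np.meshgrid(f, f, f, indexing="ij")
    rho = np.hypot(x1, x2)
    mask = np.abs(x3) * np.sin(phi) > rho * np.cos(phi)

    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n_samples, 3))
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    missing = np.abs(s[:, 2]) * np.sin(phi) > np.hypot(s[:, 0], s[:, 1]) * np.cos(phi)
    return mask, float(missing.mean())


def plan_slab_cuts(
    sample_dims: tuple[float, float, float], w: float, phi: float
) -> CutPlan:
    """Plan sectioning of a box-shaped sample.

    Tomography cuts the sample into pillars of width ``w`` (the width that
    guarantees sufficient X-ray transmission); laminography cuts it into
    slabs of thickness ``t = w sin(phi)``, the thickness for which the
    maximal beam path through a slab tilted by ``phi`` equals ``w``.  For a
    12 x 11 x 8 mm sample with w = 1.2 mm this gives 100 pillars versus 20
    slabs at phi = 20 degrees, and 14 slabs (about 7x fewer cuts) at 30
    degrees.
    """
    dims = tuple(float(v) for v in sample_dims)
    if any(v <= 0 for v in dims) or w <= 0:
        raise ValueError("sample dimensions and pillar width must be positive")
    if not (0.0 < phi <= 90.0):
        raise ValueError("phi must be in (0, 90] degrees")
    t = w * np.sin(np.deg2rad(phi))
    n_pillars = int(np.ceil(dims[0] / w)) * int(np.ceil(dims[1] / w))
    n_slabs = int(np.ceil(dims[2] / t))
    return CutPlan(
        sample_dims=dims,
        pillar_width=w,
        slab_thickness=float(t),
        n_pillars=n_pillars,
        n_slabs=n_slabs,
    )
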