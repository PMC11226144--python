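"""Laminographic forward projection and backprojection.

Two interchangeable discretisations of the same line-integral operator are
provided:

``forward_line`` / ``adjoint_line``
    Direct discretisation: each detector ray is stepped through the volume
    at one-voxel increments with trilinear interpolation; the adjoint smears
    projection values back along the same rays with transposed weights.
    Complexity O(N^3 N_theta).

``forward_fourier`` / ``adjoint_fourier``
    Fourier form: by the projection-slice theorem the 2D spectrum of the
    projection at angle theta equals the object spectrum on a tilted plane
    (see :mod:`lamrec.geometry`).  The forward operator evaluates the volume
    spectrum on these planes with a 3D unequally spaced FFT (split into
    batched 1D + 2D stages) and inverse-2D-FFTs each angle; the adjoint runs
    the exact conjugate-transposed chain.  Complexity O(N^3 log N).

Both pairs pass dot tests; the two discretisations agree to ~1% relative
RMS on smooth volumes.  For ``phi = 0`` they reduce to slice-by-slice
parallel-beam tomography.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from . import _kernels
from .geometry import LaminoGeometry, Volume3D, frequency_slice, _sigma
from .usfft import USFFTPlan, usfft3_split_forward, usfft3_split_adjoint

__all__ = [
    "forward_line",
    "adjoint_line",
    "forward_fourier",
    "adjoint_fourier",
    "backproject_slice",
]


def _vol_values(vol) -> np.ndarray:
    v = vol.values if isinstance(vol, Volume3D) else np.asarray(vol)
    if v.ndim != 3:
        raise ValueError("volume must be 3D (n3, n2, n1)")
    return v


def _check_vol(v: np.ndarray, geom: LaminoGeometry) -> None:
    if v.shape != geom.vol_shape:
        raise ValueError(f"volume shape {v.shape} != geometry {geom.vol_shape}")


def forward_line(vol, geom: LaminoGeometry) -> np.ndarray:
    """Ray-driven laminographic projection, shape (n_angles, det_nv, det_nu).

    Rays that miss the volume produce exactly zero.
    """
    v = np.ascontiguousarray(_vol_values(vol), dtype=np.float64)
    _check_vol(v, geom)
    out = np.zeros(geom.proj_shape, dtype=np.float64)
    _kernels.forward_line_kernel(
        v, out, geom.thetas_rad, geom.phi_rad, float(geom.center), float(geom.det_nv // 2)
    )
    return out


def adjoint_line(proj, geom: LaminoGeometry) -> np.ndarray:
    """Exact transpose of :func:`forward_line`, shape (n3, n2, n1)."""
    p = np.ascontiguousarray(np.asarray(proj), dtype=np.float64)
    if p.shape != geom.proj_shape:
        raise ValueError(f"projection shape {p.shape} != geometry {geom.proj_shape}")
    vol = np.zeros(geom.vol_shape, dtype=np.float64)
    _kernels.adjoint_line_kernel(
        vol, p, geom.thetas_rad, geom.phi_rad, float(geom.center), float(geom.det_nv // 2)
    )
    return vol


def _detector_phase(geom: LaminoGeometry) -> np.ndarray:
    """Phase linking physical detector coordinates to array indices.

    The detector samples at u = iu - center, v = iv - nv//2; a projection's
    index-space DFT therefore equals its physical-coordinate spectrum times
    exp(-2 pi i (su center + sv nv//2)).
    """
    su = _sigma(geom.det_nu)
    sv = _sigma(geom.det_nv)
    return np.exp(
        -2j * np.pi * (su[None, :] * geom.center + sv[:, None] * (geom.det_nv // 2))
    )


def _plans(geom: LaminoGeometry, plan: USFFTPlan | None):
    if plan is None:
        return USFFTPlan((geom.vol_n2, geom.vol_n1)), USFFTPlan((geom.vol_n3,))
    return (
        USFFTPlan((geom.vol_n2, geom.vol_n1), plan.oversampling, plan.kernel_width, plan.kernel_shape),
        USFFTPlan((geom.vol_n3,), plan.oversampling, plan.kernel_width, plan.kernel_shape),
    )


def _xi3(geom: LaminoGeometry) -> np.ndarray:
    return _sigma(geom.det_nv) * np.cos(geom.phi_rad)


def _pts_fn(geom: LaminoGeometry):
    sv = _sigma(geom.det_nv)

    def pts(iv: int) -> np.ndarray:
        xi1, xi2 = frequency_slice(geom, sv[iv])
        return np.stack([xi2.ravel(), xi1.ravel()], axis=1)

    return pts


def _edge_pts_fn(geom: LaminoGeometry):
    """Points mirroring the su = -1/2 detector column of the conjugate
    plane: the (xi2, xi1) of this plane evaluated at su = +1/2 (not an
    index-grid frequency), one point per angle."""
    sv = _sigma(geom.det_nv)
    th = geom.thetas_rad
    sphi = np.sin(geom.phi_rad)

    def pts(iv: int) -> np.ndarray:
        s = sv[iv] * sphi
        xi1 = 0.5 * np.cos(th) + s * np.sin(th)
        xi2 = -0.5 * np.sin(th) + s * np.cos(th)
        return np.stack([xi2, xi1], axis=1)

    return pts


def forward_fourier(
    vol,
    geom: LaminoGeometry,
    plan: USFFTPlan | None = None,
    chunk_angles: int | None = None,
    chunk_slices: int | None = None,
    chunk_columns: int | None = None,
) -> np.ndarray:
    """Fourier-form laminographic projection.

    Evaluates the 3D USFFT of the volume on the laminographic frequency
    grid, applies the detector phase, and inverse-2D-FFTs per angle.  Chunk
    sizes bound the working set of each stage without changing the result.
    """
    v = _vol_values(vol)
    _check_vol(v, geom)
    v = np.ascontiguousarray(v, dtype=np.float32 if v.dtype.itemsize <= 4 else np.float64)
    plan_u, plan_v = _plans(geom, plan)
    spec = usfft3_split_forward(
        v, _xi3(geom), _pts_fn(geom), (geom.n_angles, geom.det_nu),
        plan_u=plan_u, plan_v=plan_v,
        chunk_columns=chunk_columns, chunk_slices=chunk_slices,
        hermitian_v=True, edge_pts_fn=_edge_pts_fn(geom),
    )
    phase = _detector_phase(geom).astype(spec.dtype)
    out = np.empty(geom.proj_shape, dtype=v.dtype)
    nt = geom.n_angles
    step = nt if chunk_angles is None else max(1, min(int(chunk_angles), nt))
    for lo in range(0, nt, step):
        hi = min(lo + step, nt)
        s = sfft.ifft2(sfft.ifftshift(spec[lo:hi] * phase[None], axes=(1, 2)), axes=(1, 2))
        out[lo:hi] = s.real
    return out


def adjoint_fourier(
    proj,
    geom: LaminoGeometry,
    plan: USFFTPlan | None = None,
    chunk_angles: int | None = None,
    chunk_slices: int | None = None,
    chunk_columns: int | None = None,
) -> np.ndarray:
    """Exact adjoint of :func:`forward_fourier` (laminographic
    backprojection in Fourier form)."""
    p = np.asarray(proj)
    if p.shape != geom.proj_shape:
        raise ValueError(f"projection shape {p.shape} != geometry {geom.proj_shape}")
    p = np.ascontiguousarray(p, dtype=np.float32 if p.dtype.itemsize <= 4 else np.float64)
    cplx = np.complex64 if p.dtype == np.float32 else np.complex128
    phase = _detector_phase(geom).astype(cplx)
    nt, nv, nu = geom.proj_shape
    spec = np.empty((nt, nv, nu), dtype=cplx)
    step = nt if chunk_angles is None else max(1, min(int(chunk_angles), nt))
    for lo in range(0, nt, step):
        hi = min(lo + step, nt)
        # adjoint of Re(ifft2(ifftshift(phase * .))) is conj(phase) *
        # fftshift(fft2(.)) / (nu nv)
        s = sfft.fftshift(sfft.fft2(p[lo:hi].astype(cplx), axes=(1, 2)), axes=(1, 2))
        spec[lo:hi] = s * np.conj(phase)[None] / (nu * nv)
    plan_u, plan_v = _plans(geom, plan)
    vol = usfft3_split_adjoint(
        spec, _xi3(geom), _pts_fn(geom), geom.vol_shape,
        plan_u=plan_u, plan_v=plan_v,
        chunk_columns=chunk_columns, chunk_slices=chunk_slices,
        hermitian_v=True, edge_pts_fn=_edge_pts_fn(geom),
    )
    return np.ascontiguousarray(vol.real, dtype=p.dtype)


def backproject_slice(
    filtered: np.ndarray, geom: LaminoGeometry, x3: float = 0.0
) -> np.ndarray:
    """Voxel-driven backprojection of a single horizontal slice.

    Samples each filtered projection bilinearly at the detector position of
    every voxel of the plane ``x3 = const``.  Used by the alignment sweeps,
    which only need one slice per candidate.
    """
    p = np.ascontiguousarray(filtered, dtype=np.float64)
    if p.shape != geom.proj_shape:
        raise ValueError(f"projection shape {p.shape} != geometry {geom.proj_shape}")
    out = np.zeros((geom.vol_n2, geom.vol_n1), dtype=np.float64)
    _kernels.backproject_slice_kernel(
        p, out, geom.thetas_rad, geom.phi_rad,
        float(geom.center), float(geom.det_nv // 2), float(x3),
    )
    return out
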