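"""Iterative reconstruction with isotropic total-variation regularisation.

Solves

    min_mu  1/2 ||L mu - d||^2 + lambda * TV(mu),
    TV(mu) = sum_x ||grad mu(x)||_2,

by ADMM on the splitting z = grad(mu), built on the Fourier-form
laminography operators.  The TV term fills in the frequencies lost to the
missing cone by promoting piecewise-constant solutions, which suppresses
the "tail" artifacts of plain FBP at large tilt angles.

Each outer iteration:

1. mu-step — conjugate-gradient steps on the quadratic subproblem
   ``(L^T L + rho grad^T grad) mu = L^T d + rho grad^T (z - w)``, each
   costing exactly one forward and one adjoint application.  The
   normal-equation residual is seeded by one operator pair at the start
   of the run and thereafter maintained recursively from quantities the
   CG steps compute anyway, so the total budget is exactly
   ``outer_iters * inner_iters`` forward and adjoint applications — e.g.
   256 each for the default 64 x 4 schedule.
2. z-step — per-voxel soft shrinkage of the gradient-field magnitude by
   lambda / rho.
3. scaled dual update ``w += grad mu - z``.

With ``lam = 0`` the splitting is bypassed (rho term dropped, z/w frozen)
and the scheme is exactly plain CG on the least-squares normal equations
within the same operator budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import LaminoGeometry, Volume3D
from .operators import adjoint_fourier, forward_fourier
from .recon import ReconConfig, fbp_reconstruct
from .usfft import USFFTPlan

__all__ = ["TVConfig", "grad3", "div3", "shrink", "admm_tv", "DivergenceError"]

log = logging.getLogger(__name__)


@dataclass
class TVConfig:
    """ADMM-TV parameters.

    lam : TV weight (>= 0; 0 disables the regulariser).
    outer_iters, inner_iters : iteration schedule; the operator budget is
        exactly outer*inner forward and adjoint applications each.
    rho : ADMM penalty (> 0).
    init : 'zero' or 'fbp' starting volume.
    """

    lam: float = 1e-3
    outer_iters: int = 64
    inner_iters: int = 4
    rho: float = 1.0
    init: str = "zero"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.outer_iters < 1 or self.inner_iters < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.init not in ("zero", "fbp"):
            raise ValueError("init must be 'zero' or 'fbp'")


class DivergenceError(RuntimeError):
    """Raised when the objective increases for several consecutive outer
    iterations; carries the objective log in ``.log``."""

    def __init__(self, message: str, log_: dict):
        super().__init__(message)
        self.log = log_


def grad3(vol: np.ndarray) -> np.ndarray:
    """Forward-difference gradient, shape (3, n3, n2, n1), zero-flux edge."""
    v = np.asarray(vol)
    g = np.zeros((3,) + v.shape, dtype=v.dtype)
    g[0, :-1] = v[1:] - v[:-1]
    g[1, :, :-1] = v[:, 1:] - v[:, :-1]
    g[2, :, :, :-1] = v[:, :, 1:] - v[:, :, :-1]
    return g


def div3(field: np.ndarray) -> np.ndarray:
    """Discrete divergence, the exact negative transpose of :func:`grad3`
    (backward differences; satisfies <grad x, y> = -<x, div y> identically)."""
    f = np.asarray(field)
    out = np.zeros(f.shape[1:], dtype=f.dtype)
    for ax in range(3):
        c = f[ax]
        sl_mid = [slice(None)] * 3
        sl_mid[ax] = slice(0, f.shape[1 + ax] - 1)
        out[tuple(sl_mid)] += c[tuple(sl_mid)]
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = slice(1, None)
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = slice(0, -1)
        out[tuple(sl_lo)] -= c[tuple(sl_hi)]
    return out


def shrink(field: np.ndarray, thresh: float) -> np.ndarray:
    """Isotropic soft shrinkage of a (3, ...) gradient field by ``thresh``.

    Scales each voxel's gradient vector by max(1 - thresh/|g|, 0); the map
    is 1-Lipschitz and preserves the direction (hence sign) of each vector.
    """
    mag = np.sqrt(np.sum(np.square(field), axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > thresh, 1.0 - thresh / np.maximum(mag, 1e-300), 0.0)
    return field * scale[None]


def _tv(field: np.ndarray) -> float:
    return float(np.sum(np.sqrt(np.sum(np.square(field), axis=0)), dtype=np.float64))


def _dot(a: np.ndarray, b: np.ndarray) -> float:
    """Float64-accumulated inner product (safe for float32 volumes)."""
    return float(np.einsum("i,i->", a.ravel(), b.ravel(), dtype=np.float64))


def admm_tv(
    data: np.ndarray,
    geom: LaminoGeometry,
    tvcfg: TVConfig | None = None,
    plan: USFFTPlan | None = None,
    chunk_angles: int | None = None,
    chunk_slices: int | None = None,
    chunk_columns: int | None = None,
    callback=None,
) -> tuple[Volume3D, dict]:
    """TV-regularised reconstruction of pre-processed (minus-log) data.

    Returns the volume and a log dict with the per-outer-iteration
    objective values and the exact operator call counts
    (``n_forward == n_adjoint == outer_iters * inner_iters``).
    """
    tvcfg = tvcfg or TVConfig()
    data = np.asarray(data)
    if data.dtype not in (np.float32, np.float64):
        data = data.astype(np.float64)
    if data.shape != geom.proj_shape:
        raise ValueError(f"data shape {data.shape} != geometry {geom.proj_shape}")

    counts = {"forward": 0, "adjoint": 0}
    opkw = dict(plan=plan, chunk_angles=chunk_angles,
                chunk_slices=chunk_slices, chunk_columns=chunk_columns)

    def fwd(x):
        counts["forward"] += 1
        return forward_fourier(x, geom, **opkw)

    def adj(y):
        counts["adjoint"] += 1
        return adjoint_fourier(y, geom, **opkw)

    lam, rho = tvcfg.lam, (tvcfg.rho if tvcfg.lam > 0 else 0.0)
    dtype = data.dtype
    if tvcfg.init == "fbp":
        x = fbp_reconstruct(data, geom, ReconConfig(
            chunk_angles=chunk_angles, chunk_slices=chunk_slices,
            chunk_columns=chunk_columns), plan=plan).values.astype(dtype)
    else:
        x = np.zeros(geom.vol_shape, dtype=dtype)
    z = np.zeros((3,) + geom.vol_shape, dtype=dtype)
    w = np.zeros_like(z)

    objectives = []
    n_bad = 0

    # One operator pair seeds the exact data-space and normal-equation
    # residuals; both are then maintained recursively from quantities the
    # CG steps compute anyway, so every remaining pair is a full CG step
    # and the total budget is exactly outer_iters * inner_iters pairs.
    u = fwd(x)  # L x (zero volume in, zeros out, for the default init)
    s = -adj(u - data)  # L^T (d - L x)

    r = p = None
    rr = 0.0
    for outer in range(tvcfg.outer_iters):
        res = u - data
        obj = 0.5 * _dot(res, res) + lam * _tv(grad3(x))
        objectives.append(obj)
        # ADMM's primal objective is not strictly monotone: small wiggles
        # near the plateau are normal, so only count meaningful growth
        if len(objectives) > 1 and obj > objectives[-2] * (1 + 1e-3):
            n_bad += 1
            if n_bad >= 5:
                raise DivergenceError(
                    "objective increased for 5 consecutive outer iterations",
                    {"objective": objectives, **counts},
                )
        else:
            n_bad = 0

        if rho > 0 or r is None:
            # the rho-part of the residual changes with z and w, so the CG
            # direction restarts each outer iteration; for lam = 0 the
            # subproblem never changes and CG continues uninterrupted
            r = s.copy()
            if rho > 0:
                r += rho * div3(grad3(x) - z + w)
            rr = _dot(r, r)
            p = r.copy()

        steps = tvcfg.inner_iters - 1 if outer == 0 else tvcfg.inner_iters
        for _ in range(steps):
            if rr == 0.0:
                # subproblem solved exactly; spend the remaining budget on
                # no-op pairs to keep the operator accounting deterministic
                fwd(np.zeros_like(x))
                adj(np.zeros(geom.proj_shape, dtype=dtype))
                continue
            lp = fwd(p)
            q_data = adj(lp)
            q = q_data if rho == 0 else q_data - rho * div3(grad3(p))
            alpha = rr / _dot(p, q)
            a = dtype.type(alpha)
            x += a * p
            u += a * lp
            s -= a * q_data
            r -= a * q
            rr_new = _dot(r, r)
            p = r + dtype.type(rr_new / rr) * p
            rr = rr_new

        # --- z-step and dual update --------------------------------------
        if lam > 0:
            gx = grad3(x)
            z = shrink(gx + w, lam / rho)
            w += gx - z
        if callback is not None:
            callback(outer, x, obj)

    log_ = {"objective": objectives, "n_forward": counts["forward"],
            "n_adjoint": counts["adjoint"]}
    log.info("ADMM-TV finished: %d forward / %d adjoint applications",
             counts["forward"], counts["adjoint"])
    return Volume3D(values=x, voxel_size=geom.voxel_size), log_
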