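"""Numba-jitted inner kernels: Gaussian gather/scatter for the USFFT and
ray-driven / voxel-driven projection kernels.

All kernels are serial and dtype-generic (numba specialises per call-site
dtype).  The gather and scatter share one weight formula so the transform
pair is an exact transpose; likewise the ray-marching forward and adjoint
share one traversal.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# USFFT gather / scatter (2D)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True, inline="always")
def _axis_weights(x, m, a, width, qsq, w, idx):
    """Truncated-Gaussian weights of one axis via the separable recurrence
    exp(-pi^2 (d0 - j/m)^2 / a) = exp(-pi^2 d0^2/a) * r^j * q^(j^2)."""
    nw = 2 * width + 1
    k0 = int(np.rint(x * m))
    d0 = x - k0 / m
    pi2 = np.pi * np.pi
    e0 = np.exp(-pi2 * d0 * d0 / a)
    r = np.exp(2.0 * pi2 * d0 / (a * m))
    rp = 1.0
    for j in range(width + 1):
        w[width + j] = e0 * rp * qsq[j]
        idx[width + j] = (k0 + j) % m
        rp *= r
    rinv = 1.0 / r
    rp = rinv
    for j in range(1, width + 1):
        w[width - j] = e0 * rp * qsq[j]
        idx[width - j] = (k0 - j) % m
        rp *= rinv
    return nw


@njit(cache=True, fastmath=True)
def _qsq(m, a, width):
    """q^(j^2) table, q = exp(-pi^2 / (a m^2))."""
    q = np.exp(-np.pi * np.pi / (a * m * m))
    out = np.empty(width + 1)
    for j in range(width + 1):
        out[j] = q ** (j * j)
    return out


@njit(cache=True, fastmath=True)
def gather2(buf, pts, out, m0, m1, a0, a1, width, cnorm):
    """out[i] = cnorm * sum_j G(xi_i - k_j/M) * buf[k_j mod M] (2D)."""
    nw = 2 * width + 1
    w0 = np.empty(nw)
    w1 = np.empty(nw)
    i0 = np.empty(nw, dtype=np.int64)
    i1 = np.empty(nw, dtype=np.int64)
    q0 = _qsq(m0, a0, width)
    q1 = _qsq(m1, a1, width)
    for i in range(pts.shape[0]):
        _axis_weights(pts[i, 0], m0, a0, width, q0, w0, i0)
        _axis_weights(pts[i, 1], m1, a1, width, q1, w1, i1)
        acc = complex(0.0, 0.0)
        for j0 in range(nw):
            row = buf[i0[j0]]
            part = complex(0.0, 0.0)
            for j1 in range(nw):
                part += w1[j1] * row[i1[j1]]
            acc += w0[j0] * part
        out[i] = cnorm * acc


@njit(cache=True, fastmath=True)
def scatter2(buf, pts, coeffs, m0, m1, a0, a1, width, cnorm):
    """Exact transpose of :func:`gather2` (weights are real)."""
    nw = 2 * width + 1
    w0 = np.empty(nw)
    w1 = np.empty(nw)
    i0 = np.empty(nw, dtype=np.int64)
    i1 = np.empty(nw, dtype=np.int64)
    q0 = _qsq(m0, a0, width)
    q1 = _qsq(m1, a1, width)
    for i in range(pts.shape[0]):
        _axis_weights(pts[i, 0], m0, a0, width, q0, w0, i0)
        _axis_weights(pts[i, 1], m1, a1, width, q1, w1, i1)
        c = cnorm * coeffs[i]
        for j0 in range(nw):
            cw = c * w0[j0]
            for j1 in range(nw):
                buf[i0[j0], i1[j1]] += cw * w1[j1]


# ---------------------------------------------------------------------------
# Ray-driven line-integral projector and its exact adjoint
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _ray_range(p1, p2, p3, d1, d2, d3, n1, n2, n3):
    """Parameter interval where the ray can touch nonzero voxels."""
    tmin = -1.0e30
    tmax = 1.0e30
    for p, d, n in ((p1, d1, n1), (p2, d2, n2), (p3, d3, n3)):
        lo = -1.0
        hi = float(n)
        if abs(d) < 1.0e-12:
            if p <= lo or p >= hi:
                return 1.0, 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
    return tmin, tmax


@njit(cache=True, fastmath=True)
def forward_line_kernel(vol, out, thetas, phi, center, cv):
    """Line-integral laminographic projection, unit step, trilinear samples.

    vol: (n3, n2, n1); out: (ntheta, nv, nu).  Detector u = iu - center,
    v = iv - cv.  The ray through (u, v) has, in the sample frame, origin
    (u ct + v sphi st, -u st + v sphi ct, v cphi) and direction
    (cphi st, cphi ct, -sphi).
    """
    n3, n2, n1 = vol.shape
    ntheta, nv, nu = out.shape
    sphi = np.sin(phi)
    cphi = np.cos(phi)
    for it in range(ntheta):
        ct = np.cos(thetas[it])
        st = np.sin(thetas[it])
        d1 = cphi * st
        d2 = cphi * ct
        d3 = -sphi
        for iv in range(nv):
            v = iv - cv
            for iu in range(nu):
                u = iu - center
                p1 = u * ct + v * sphi * st + n1 // 2
                p2 = -u * st + v * sphi * ct + n2 // 2
                p3 = v * cphi + n3 // 2
                tmin, tmax = _ray_range(p1, p2, p3, d1, d2, d3, n1, n2, n3)
                acc = 0.0
                if tmax > tmin:
                    nsteps = int(np.ceil(tmax - tmin))
                    for j in range(nsteps):
                        t = tmin + j + 0.5
                        if t >= tmax:
                            break
                        q1 = p1 + t * d1
                        q2 = p2 + t * d2
                        q3 = p3 + t * d3
                        ix = int(np.floor(q1))
                        iy = int(np.floor(q2))
                        iz = int(np.floor(q3))
                        fx = q1 - ix
                        fy = q2 - iy
                        fz = q3 - iz
                        for c3 in range(2):
                            z = iz + c3
                            if z < 0 or z >= n3:
                                continue
                            wz = fz if c3 == 1 else 1.0 - fz
                            for c2 in range(2):
                                y = iy + c2
                                if y < 0 or y >= n2:
                                    continue
                                wy = fy if c2 == 1 else 1.0 - fy
                                for c1 in range(2):
                                    x = ix + c1
                                    if x < 0 or x >= n1:
                                        continue
                                    wx = fx if c1 == 1 else 1.0 - fx
                                    acc += wz * wy * wx * vol[z, y, x]
                out[it, iv, iu] = acc


@njit(cache=True, fastmath=True)
def adjoint_line_kernel(vol, proj, thetas, phi, center, cv):
    """Exact transpose of :func:`forward_line_kernel` (smears rays back)."""
    n3, n2, n1 = vol.shape
    ntheta, nv, nu = proj.shape
    sphi = np.sin(phi)
    cphi = np.cos(phi)
    for it in range(ntheta):
        ct = np.cos(thetas[it])
        st = np.sin(thetas[it])
        d1 = cphi * st
        d2 = cphi * ct
        d3 = -sphi
        for iv in range(nv):
            v = iv - cv
            for iu in range(nu):
                g = proj[it, iv, iu]
                if g == 0.0:
                    continue
                u = iu - center
                p1 = u * ct + v * sphi * st + n1 // 2
                p2 = -u * st + v * sphi * ct + n2 // 2
                p3 = v * cphi + n3 // 2
                tmin, tmax = _ray_range(p1, p2, p3, d1, d2, d3, n1, n2, n3)
                if tmax <= tmin:
                    continue
                nsteps = int(np.ceil(tmax - tmin))
                for j in range(nsteps):
                    t = tmin + j + 0.5
                    if t >= tmax:
                        break
                    q1 = p1 + t * d1
                    q2 = p2 + t * d2
                    q3 = p3 + t * d3
                    ix = int(np.floor(q1))
                    iy = int(np.floor(q2))
                    iz = int(np.floor(q3))
                    fx = q1 - ix
                    fy = q2 - iy
                    fz = q3 - iz
                    for c3 in range(2):
                        z = iz + c3
                        if z < 0 or z >= n3:
                            continue
                        wz = fz if c3 == 1 else 1.0 - fz
                        for c2 in range(2):
                            y = iy + c2
                            if y < 0 or y >= n2:
                                continue
                            wy = fy if c2 == 1 else 1.0 - fy
                            for c1 in range(2):
                                x = ix + c1
                                if x < 0 or x >= n1:
                                    continue
                                wx = fx if c1 == 1 else 1.0 - fx
                                vol[z, y, x] += g * wz * wy * wx


@njit(cache=True, fastmath=True)
def backproject_slice_kernel(filtered, out, thetas, phi, center, cv, x3):
    """Voxel-driven backprojection of one horizontal slice (x3 fixed).

    For voxel (x1, x2, x3) the detector coordinates at angle theta are
    u = x1 ct - x2 st and v = (x1 st + x2 ct) sphi + x3 cphi; the filtered
    projection is sampled bilinearly (zero outside the detector).
    """
    ntheta, nv, nu = filtered.shape
    n2, n1 = out.shape
    sphi = np.sin(phi)
    cphi = np.cos(phi)
    for it in range(ntheta):
        ct = np.cos(thetas[it])
        st = np.sin(thetas[it])
        for i2 in range(n2):
            x2 = i2 - n2 // 2
            for i1 in range(n1):
                x1 = i1 - n1 // 2
                u = x1 * ct - x2 * st + center
                v = (x1 * st + x2 * ct) * sphi + x3 * cphi + cv
                iu = int(np.floor(u))
                iv = int(np.floor(v))
                fu = u - iu
                fv = v - iv
                acc = 0.0
                for cvv in range(2):
                    y = iv + cvv
                    if y < 0 or y >= nv:
                        continue
                    wv = fv if cvv == 1 else 1.0 - fv
                    for cuu in range(2):
                        x = iu + cuu
                        if x < 0 or x >= nu:
                            continue
                        wu = fu if cuu == 1 else 1.0 - fu
                        acc += wv * wu * filtered[it, y, x]
                out[i2, i1] += acc
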