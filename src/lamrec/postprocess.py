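"""Resolution estimation by Fourier ring correlation and mosaic stitching.

FRC
---
Two reconstructions from statistically independent measurements share
signal but not noise; the normalised cross-correlation of their 2D spectra
per frequency shell (ring) therefore decays from ~1 to ~0 at the frequency
where signal drops below noise.  The resolution is read off at the first
crossing with the 1/2-bit information threshold (Van Heel & Schatz),

    T(n) = (0.2071 + 1.9102 / sqrt(n)) / (1.2071 + 0.9102 / sqrt(n)),

with n the number of samples in the shell; for large n the threshold tends
to 0.2071/1.2071 ~ 0.1716.  For thin slab volumes the FRC is evaluated per
slice and the worst (largest) resolution is reported.

Stitching
---------
Mosaic scans acquire overlapping projection tiles.  Translation offsets
are recovered on the overlap strips by normalised cross-correlation with
parabolic sub-pixel refinement, and tiles are blended with weights that
ramp linearly from 0 to 1 across each overlap (separable products at
corner overlaps) and are normalised to sum to one everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy import ndimage

__all__ = [
    "FRCCurve",
    "frc",
    "halfbit_threshold",
    "ResolutionEstimate",
    "resolution_estimate",
    "resolution_estimate_volume",
    "TilePlacement",
    "estimate_shift",
    "blend_stitch",
    "plan_mosaic",
    "RegistrationError",
]


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------


@dataclass
class FRCCurve:
    """Per-shell correlation of two images' spectra.

    freqs : shell centre frequencies, cycles/pixel (increasing).
    frc : correlation per shell, in [-1, 1].
    halfbit : 1/2-bit threshold per shell.
    n_per_shell : number of spectral samples per shell.
    """

    freqs: np.ndarray
    frc: np.ndarray
    halfbit: np.ndarray
    n_per_shell: np.ndarray


def halfbit_threshold(n: np.ndarray) -> np.ndarray:
    """Van Heel & Schatz 1/2-bit information threshold for shell size n."""
    n = np.maximum(np.asarray(n, dtype=np.float64), 1.0)
    s = np.sqrt(n)
    return (0.2071 + 1.9102 / s) / (1.2071 + 0.9102 / s)


def frc(slice_a: np.ndarray, slice_b: np.ndarray) -> FRCCurve:
    """Fourier ring correlation of two equally shaped real 2D images.

    Shell width is one frequency bin; shell k collects spectral samples at
    radius [k - 1/2, k + 1/2) bins.  The curve is symmetric in its
    arguments and invariant to a global intensity scale of either input.
    """
    a = np.asarray(slice_a, dtype=np.float64)
    b = np.asarray(slice_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("inputs must be two real 2D arrays of equal shape")
    fa = sfft.fftshift(sfft.fft2(a))
    fb = sfft.fftshift(sfft.fft2(b))
    n = min(a.shape)
    fy = sfft.fftshift(sfft.fftfreq(a.shape[0]))
    fx = sfft.fftshift(sfft.fftfreq(a.shape[1]))
    radius = np.hypot(fy[:, None], fx[None, :]) * n  # in bins of the short axis
    shell = np.rint(radius).astype(np.intp)
    n_shells = n // 2 + 1
    sel = shell < n_shells
    shells = shell[sel]
    num = np.bincount(shells, (fa * np.conj(fb)).real[sel], minlength=n_shells)
    pa = np.bincount(shells, np.abs(fa[sel]) ** 2, minlength=n_shells)
    pb = np.bincount(shells, np.abs(fb[sel]) ** 2, minlength=n_shells)
    counts = np.bincount(shells, minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(pa * pb)
    corr[~np.isfinite(corr)] = 0.0
    return FRCCurve(
        freqs=np.arange(n_shells) / n,
        frc=corr,
        halfbit=halfbit_threshold(counts),
        n_per_shell=counts,
    )


@dataclass
class ResolutionEstimate:
    """Resolution length with provenance of the threshold crossing."""

    resolution: float
    crossing_freq: float
    crossed: bool  # False: no crossing found, band-limit returned


def resolution_estimate(curve: FRCCurve, pixel_size: float = 1.0) -> ResolutionEstimate:
    """Resolution from the first crossing of the FRC below the 1/2-bit curve.

    The crossing frequency is linearly interpolated between shells and
    converted to a length ``pixel_size / freq``.  If the FRC never drops
    below the threshold the band limit (2 x pixel_size, Nyquist) is
    returned with ``crossed=False``.
    """
    d = curve.frc - curve.halfbit
    for i in range(1, len(d)):
        if d[i] < 0:
            f0, f1 = curve.freqs[i - 1], curve.freqs[i]
            t = d[i - 1] / (d[i - 1] - d[i]) if d[i - 1] != d[i] else 0.0
            fc = f0 + t * (f1 - f0)
            if fc <= 0:
                fc = f1
            return ResolutionEstimate(float(pixel_size / fc), float(fc), True)
    return ResolutionEstimate(2.0 * pixel_size, 0.5, False)


def resolution_estimate_volume(
    vol_a: np.ndarray, vol_b: np.ndarray, pixel_size: float = 1.0
) -> ResolutionEstimate:
    """Per-slice FRC of a thin volume; reports the worst (largest) slice
    resolution, the conservative choice for slab-shaped reconstructions."""
    a = np.asarray(vol_a)
    b = np.asarray(vol_b)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("inputs must be two 3D arrays of equal shape")
    worst = None
    for ia in range(a.shape[0]):
        est = resolution_estimate(frc(a[ia], b[ia]), pixel_size)
        if worst is None or est.resolution > worst.resolution:
            worst = est
    return worst


# ---------------------------------------------------------------------------
# Mosaic stitching
# ---------------------------------------------------------------------------


class RegistrationError(RuntimeError):
    """Raised when the overlap is too featureless to register; supply a
    manual offset instead."""


@dataclass
class TilePlacement:
    """Placement of one tile in the mosaic.

    row, col : grid position.
    y0, x0 : pixel offset of the tile origin in the stitched frame
        (possibly fractional).
    overlaps : (top, bottom, left, right) overlap extents in pixels used
        for the blending ramps.
    """

    row: int
    col: int
    y0: float
    x0: float
    overlaps: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.overlaps):
            raise ValueError("overlaps must be non-negative")


def estimate_shift(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_overlap: int,
    axis: int = 1,
    min_correlation: float = 0.3,
) -> tuple[float, float]:
    """Translation of ``tile_b`` relative to its nominal placement next to
    ``tile_a`` along ``axis``, from the overlap strips.

    The trailing ``nominal_overlap`` pixels of ``tile_a`` and the leading
    ones of ``tile_b`` are correlated (FFT cross-correlation of
    mean-subtracted strips, parabolic sub-pixel peak refinement).  Raises
    :class:`RegistrationError` when the normalised correlation peak falls
    below ``min_correlation`` (featureless overlap).
    """
    a = np.asarray(tile_a, dtype=np.float64)
    b = np.asarray(tile_b, dtype=np.float64)
    if nominal_overlap < 1:
        raise ValueError("nominal_overlap must be >= 1")
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    sl_a = [slice(None)] * 2
    sl_b = [slice(None)] * 2
    sl_a[axis] = slice(a.shape[axis] - nominal_overlap, None)
    sl_b[axis] = slice(0, nominal_overlap)
    sa = a[tuple(sl_a)] - a[tuple(sl_a)].mean()
    sb = b[tuple(sl_b)] - b[tuple(sl_b)].mean()
    if sa.shape != sb.shape:
        raise ValueError("overlap strips have different shapes")

    shape = [sfft.next_fast_len(2 * s) for s in sa.shape]
    fa = sfft.fft2(sa, shape)
    fb = sfft.fft2(sb, shape)
    cc = sfft.ifft2(fa * np.conj(fb)).real
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    norm = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if norm <= 0 or cc[peak] / norm < min_correlation:
        raise RegistrationError(
            "overlap registration failed (correlation peak "
            f"{cc[peak] / max(norm, 1e-300):.3f} < {min_correlation}); "
            "provide the offset manually"
        )

    shift = []
    for ax, p in enumerate(peak):
        m = cc.shape[ax]
        c0 = cc[tuple(np.mod(np.subtract(peak, np.eye(2, dtype=int)[ax]), cc.shape))]
        c2 = cc[tuple(np.mod(np.add(peak, np.eye(2, dtype=int)[ax]), cc.shape))]
        c1 = cc[peak]
        denom = c0 - 2 * c1 + c2
        frac = 0.5 * (c0 - c2) / denom if denom != 0 else 0.0
        s = p + frac
        if s > m / 2:
            s -= m
        # positive = tile_b's field of view sits at +s of its nominal
        # position; add the result to the nominal placement when stitching
        shift.append(s)
    return float(shift[0]), float(shift[1])


def _ramp(n: int, o_lo: int, o_hi: int) -> np.ndarray:
    """1D blending weight: linear 0->1 over the leading ``o_lo`` pixels,
    1->0 over the trailing ``o_hi`` pixels, 1 between.  Two abutting ramps
    over the same overlap sum to exactly 1."""
    w = np.ones(n)
    if o_lo > 0:
        w[:o_lo] = (np.arange(o_lo) + 0.5) / o_lo
    if o_hi > 0:
        w[n - o_hi :] = ((np.arange(o_hi) + 0.5) / o_hi)[::-1]
    return w


def blend_stitch(
    tiles: list[np.ndarray],
    placements: list[TilePlacement],
) -> np.ndarray:
    """Blend overlapping tiles into one projection.

    Each tile carries a separable weight map that ramps linearly across its
    overlaps; the mosaic is the weight-normalised sum, so the weights form
    an exact partition of unity wherever at least one tile contributes.
    Fractional placements are handled by bilinear shifting of tile and
    weights.  Pixels covered by no tile raise an error.
    """
    if len(tiles) != len(placements):
        raise ValueError("one placement per tile required")
    # the canvas origin is the minimum placement (offsets may be negative)
    y_org = float(np.floor(min(p.y0 for p in placements)))
    x_org = float(np.floor(min(p.x0 for p in placements)))
    hmax = max(p.y0 - y_org + t.shape[0] for t, p in zip(tiles, placements))
    wmax = max(p.x0 - x_org + t.shape[1] for t, p in zip(tiles, placements))
    H, W = int(np.ceil(hmax)), int(np.ceil(wmax))
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    for t, p in zip(tiles, placements):
        t = np.asarray(t, dtype=np.float64)
        ot, ob, ol, orr = p.overlaps
        wy = _ramp(t.shape[0], ot, ob)
        wx = _ramp(t.shape[1], ol, orr)
        wt = wy[:, None] * wx[None, :]
        y0, x0 = p.y0 - y_org, p.x0 - x_org
        iy, fy = int(np.floor(y0)), y0 - np.floor(y0)
        ix, fx = int(np.floor(x0)), x0 - np.floor(x0)
        if fy or fx:
            t = ndimage.shift(t * wt, (fy, fx), order=1, prefilter=False)
            wt = ndimage.shift(wt, (fy, fx), order=1, prefilter=False)
        else:
            t = t * wt
        h = min(t.shape[0], H - iy)
        w_ = min(t.shape[1], W - ix)
        acc[iy : iy + h, ix : ix + w_] += t[:h, :w_]
        wacc[iy : iy + h, ix : ix + w_] += wt[:h, :w_]
    # stage errors make the mosaic boundary ragged: crop the canvas to the
    # rectangle guaranteed by the outermost tiles, then any remaining hole
    # is a genuine gap between tiles
    row_max = max(p.row for p in placements)
    col_max = max(p.col for p in placements)
    r0 = int(np.ceil(max(p.y0 - y_org for p in placements if p.row == 0)))
    c0 = int(np.ceil(max(p.x0 - x_org for p in placements if p.col == 0)))
    r1 = int(np.floor(min(p.y0 - y_org + t.shape[0]
                          for t, p in zip(tiles, placements) if p.row == row_max)))
    c1 = int(np.floor(min(p.x0 - x_org + t.shape[1]
                          for t, p in zip(tiles, placements) if p.col == col_max)))
    acc = acc[r0:r1, c0:c1]
    wacc = wacc[r0:r1, c0:c1]
    uncovered = wacc < 1e-9
    if np.any(uncovered):
        raise ValueError(
            f"{int(uncovered.sum())} mosaic pixels are covered by no tile "
            "(gap between placements)"
        )
    return acc / wacc


def plan_mosaic(
    grid_shape: tuple[int, int],
    tile_shape: tuple[int, int],
    overlap: int,
    offsets: dict | None = None,
) -> list[TilePlacement]:
    """Nominal placements for a regular mosaic with constant overlap.

    ``offsets`` optionally maps (row, col) to an extra (dy, dx) measured by
    :func:`estimate_shift` (or supplied manually).
    """
    rows, cols = grid_shape
    th, tw = tile_shape
    out = []
    for r in range(rows):
        for c in range(cols):
            dy, dx = (offsets or {}).get((r, c), (0.0, 0.0))
            out.append(
                TilePlacement(
                    row=r, col=c,
                    y0=r * (th - overlap) + dy,
                    x0=c * (tw - overlap) + dx,
                    overlaps=(
                        overlap if r > 0 else 0,
                        overlap if r < rows - 1 else 0,
                        overlap if c > 0 else 0,
                        overlap if c < cols - 1 else 0,
                    ),
                )
            )
    return out
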