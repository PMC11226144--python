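"""Pre-processing, filtered backprojection, alignment sweeps and the
chunked execution contract.

The FBP chain is: dark/flat-field correction and minus-log transform,
per-row ramp (or apodised) filtering along the detector column coordinate,
then the laminographic backprojection.  With angles covering the full
circle every frequency plane is visited twice, so the reconstruction
weight is ``delta_theta * cos(phi) / 2`` per angle (``delta_theta / 2 =
pi / N_theta``); for a half-circle tomographic scan the double-coverage
factor drops out.

Rotation axis and tilt angle are usually only approximately known.  The
``try_rotation_axis`` / ``try_lamino_angle`` sweeps reconstruct a single
slice for a range of candidate values and write one image per candidate;
an automatic sharpness ranking is provided, but all images are returned
for visual selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .geometry import LaminoGeometry, ProjectionStack, Volume3D
from .operators import adjoint_fourier, backproject_slice
from .usfft import USFFTPlan

__all__ = [
    "ReconConfig",
    "normalize_minus_log",
    "preprocess",
    "fbp_filter",
    "fbp_reconstruct",
    "try_rotation_axis",
    "try_lamino_angle",
    "TrySweep",
    "chunked_execute",
    "sharpness",
]

log = logging.getLogger(__name__)

FILTERS = ("ramp", "shepp", "parzen")


@dataclass
class ReconConfig:
    """Reconstruction parameters (mirrors the command-line interface)."""

    filter_name: str = "ramp"
    rotation_axis: float | None = None
    lamino_angle: float | None = None
    search_width_axis: float = 20.0
    search_step_axis: float = 0.5
    search_width_angle: float = 2.0
    search_step_angle: float = 0.25
    chunk_angles: int | None = None
    chunk_slices: int | None = None
    chunk_columns: int | None = None
    reconstruction_type: str = "full"

    def __post_init__(self) -> None:
        if self.filter_name not in FILTERS:
            raise ValueError(f"unknown filter {self.filter_name!r}; choose from {FILTERS}")
        if self.search_step_axis <= 0 or self.search_step_angle <= 0:
            raise ValueError("search steps must be positive")
        if self.search_width_axis < 0 or self.search_width_angle < 0:
            raise ValueError("search widths must be non-negative")
        for name in ("chunk_angles", "chunk_slices", "chunk_columns"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.reconstruction_type not in ("try", "try-lamino", "full"):
            raise ValueError("reconstruction_type must be try|try-lamino|full")


def normalize_minus_log(
    raw: np.ndarray,
    dark: np.ndarray,
    flat: np.ndarray,
    floor: float = 1e-6,
) -> np.ndarray:
    """Dark/flat-field correction followed by the minus-log transform.

    Computes ``-log((raw - dark) / (flat - dark))`` with the transmission
    clamped to ``floor`` (relative) before the logarithm, so saturated or
    dead pixels yield a large finite attenuation instead of inf/nan.
    """
    raw = np.asarray(raw, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    flat = np.asarray(flat, dtype=np.float64)
    denom = flat - dark
    bad = denom <= 0
    if np.any(bad):
        raise ValueError(
            f"flat field not above dark field on {int(bad.sum())} detector pixels"
        )
    trans = (raw - dark) / denom
    n_clamped = int(np.count_nonzero(trans < floor))
    if n_clamped:
        log.warning("clamped %d non-positive transmission values to %.1e", n_clamped, floor)
    return -np.log(np.maximum(trans, floor))


def preprocess(
    stack: ProjectionStack,
    ring_removal_hook=None,
    paganin_hook=None,
) -> np.ndarray:
    """Standard pre-processing chain: minus-log plus optional hook points.

    ``ring_removal_hook`` and ``paganin_hook`` are hook points for stripe
    suppression and single-distance phase retrieval; both default to None
    (no operation) and, when given, must map a (theta, v, u) array to an
    array of the same shape.
    """
    data = normalize_minus_log(stack.data, stack.dark, stack.flat)
    for hook in (ring_removal_hook, paganin_hook):
        if hook is not None:
            data = hook(data)
    return data


def _ramp_transfer(npad: int) -> np.ndarray:
    """Transfer function of the standard discrete ramp kernel.

    Built as the DFT of the band-limited ramp's impulse response
    (h[0] = 1/4, h[odd k] = -1/(pi k)^2, h[even] = 0), which equals |sigma|
    up to discretisation; the DC bin is forced to zero so constant rows
    filter to exactly zero.
    """
    h = np.zeros(npad)
    k = np.arange(1, npad // 2 + 1)
    odd = k[k % 2 == 1]
    h[0] = 0.25
    h[odd] = -1.0 / (np.pi * odd) ** 2
    h[-odd] = -1.0 / (np.pi * odd) ** 2
    transfer = np.real(sfft.fft(h))
    transfer[0] = 0.0
    return transfer


def _parzen_window(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    w = np.zeros_like(ax)
    inner = ax <= 0.5
    outer = (ax > 0.5) & (ax <= 1.0)
    w[inner] = 1.0 - 6.0 * ax[inner] ** 2 * (1.0 - ax[inner])
    w[outer] = 2.0 * (1.0 - ax[outer]) ** 3
    return w


def fbp_filter(data: np.ndarray, filter_name: str, geom: LaminoGeometry | None = None) -> np.ndarray:
    """1D filtering along the detector column coordinate u, per (theta, v) row.

    ``ramp`` is the band-limited |sigma| response; ``shepp`` (Shepp-Logan)
    and ``parzen`` apodise it to trade resolution for noise suppression.
    """
    if filter_name not in FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    data = np.asarray(data)
    nu = data.shape[-1]
    npad = sfft.next_fast_len(2 * nu)
    transfer = _ramp_transfer(npad)
    sigma = sfft.fftfreq(npad)  # cycles per sample, |sigma| <= 0.5
    if filter_name == "shepp":
        transfer = transfer * np.sinc(sigma)
    elif filter_name == "parzen":
        transfer = transfer * _parzen_window(sigma / 0.5)
    # edge padding: a constant row stays constant over the padded window,
    # so the zeroed DC bin annihilates it exactly, and real projections
    # avoid the step-edge ringing of zero padding
    lp = (npad - nu) // 2
    pad_spec = [(0, 0)] * (data.ndim - 1) + [(lp, npad - nu - lp)]
    padded = np.pad(data, pad_spec, mode="edge")
    spec = sfft.rfft(padded, axis=-1)
    spec *= transfer[: npad // 2 + 1]
    out = sfft.irfft(spec, n=npad, axis=-1)[..., lp : lp + nu]
    return np.ascontiguousarray(out, dtype=data.dtype if data.dtype.kind == "f" else np.float64)


def _fbp_scale(geom: LaminoGeometry) -> float:
    """Angular quadrature weight: delta_theta * cos(phi) / coverage."""
    th = geom.thetas_rad
    dtheta = (th[-1] - th[0]) / max(len(th) - 1, 1) if len(th) > 1 else 2 * np.pi
    span = (th[-1] - th[0]) + dtheta
    coverage = 2.0 if span > 1.5 * np.pi else 1.0
    return float(dtheta * np.cos(geom.phi_rad) / coverage)


def fbp_reconstruct(
    proj,
    geom: LaminoGeometry,
    config: ReconConfig | None = None,
    plan: USFFTPlan | None = None,
) -> Volume3D:
    """Filtered backprojection of pre-processed (minus-log) data.

    Uses the Fourier-form backprojection; chunk sizes in ``config`` bound
    the working set without changing the result.
    """
    config = config or ReconConfig()
    data = proj.data if isinstance(proj, ProjectionStack) else np.asarray(proj)
    if config.rotation_axis is not None:
        geom = geom.replace(center=config.rotation_axis)
    if config.lamino_angle is not None:
        geom = geom.replace(phi=config.lamino_angle)
    filtered = fbp_filter(data, config.filter_name, geom)
    vol = adjoint_fourier(
        filtered, geom, plan=plan,
        chunk_angles=config.chunk_angles,
        chunk_slices=config.chunk_slices,
        chunk_columns=config.chunk_columns,
    )
    vol *= _fbp_scale(geom)
    return Volume3D(values=vol, voxel_size=geom.voxel_size)


def sharpness(image: np.ndarray, region: str = "full") -> float:
    """Total gradient magnitude of an image (optionally of its border or
    central region only)."""
    img = np.asarray(image, dtype=np.float64)
    gy, gx = np.gradient(img)
    gm = np.hypot(gy, gx)
    if region == "border":
        h, w = img.shape
        q_h, q_w = h // 4, w // 4
        mask = np.ones(img.shape, dtype=bool)
        mask[q_h : h - q_h, q_w : w - q_w] = False
        gm = gm[mask]
    elif region == "center":
        h, w = img.shape
        gm = gm[h // 4 : -h // 4, w // 4 : -w // 4]
    return float(np.sum(gm))


def _axis_score(image: np.ndarray) -> float:
    """Focus score of the rotation-axis sweep: image variance.

    A correct axis adds each feature's contributions coherently; axis error
    splits and blurs them, lowering the slice energy.  Variance is a more
    reliable ranking than raw gradient magnitude, whose response to streak
    artifacts grows with misalignment.
    """
    img = np.asarray(image, dtype=np.float64)
    return float(img.var())


def _tilt_score(image: np.ndarray) -> float:
    """Focus score of the tilt-angle sweep: border sharpness.

    Tilt error defocuses the slice proportionally to the lateral radius,
    so the outer quarter frame of the image carries the signal while the
    middle is insensitive."""
    return sharpness(image, region="border")


@dataclass
class TrySweep:
    """Result of a parameter sweep: one single-slice image per candidate."""

    parameter: str
    candidates: np.ndarray
    images: list
    scores: np.ndarray

    @property
    def best(self) -> float:
        """Candidate with the highest sharpness score (automatic ranking;
        the images remain available for manual selection)."""
        return float(self.candidates[int(np.argmax(self.scores))])


def _sweep_candidates(center: float, width: float, step: float) -> np.ndarray:
    if width <= 0:
        raise ValueError("search width must be positive for a sweep")
    return np.arange(center - width, center + width - 1e-9, step)


def try_rotation_axis(
    proj,
    geom: LaminoGeometry,
    config: ReconConfig | None = None,
    out_dir=None,
) -> TrySweep:
    """Reconstruct the central slice for a range of candidate rotation axes.

    Candidates cover [axis - w, axis + w) at ``search_step_axis``.  The
    middle of the slice is insensitive to tilt-angle error, so the axis can
    be judged independently of the tilt.
    """
    config = config or ReconConfig()
    data = proj.data if isinstance(proj, ProjectionStack) else np.asarray(proj)
    axis = config.rotation_axis if config.rotation_axis is not None else geom.center
    if config.lamino_angle is not None:
        geom = geom.replace(phi=config.lamino_angle)
    candidates = _sweep_candidates(axis, config.search_width_axis, config.search_step_axis)
    filtered = fbp_filter(data, config.filter_name, geom)
    scale = _fbp_scale(geom)
    images, scores = [], []
    for c in candidates:
        img = backproject_slice(filtered, geom.replace(center=float(c)), x3=0.0) * scale
        images.append(img)
        scores.append(_axis_score(img))
    sweep = TrySweep("rotation_axis", candidates, images, np.asarray(scores))
    if out_dir is not None:
        _write_sweep(sweep, out_dir, "try_center")
    return sweep


def try_lamino_angle(
    proj,
    geom: LaminoGeometry,
    config: ReconConfig | None = None,
    out_dir=None,
) -> TrySweep:
    """Reconstruct the central slice for a range of candidate tilt angles
    with the rotation axis held fixed.  The borders of the slice respond to
    tilt error, so candidates are judged there."""
    config = config or ReconConfig()
    data = proj.data if isinstance(proj, ProjectionStack) else np.asarray(proj)
    angle = config.lamino_angle if config.lamino_angle is not None else geom.phi
    if config.rotation_axis is not None:
        geom = geom.replace(center=config.rotation_axis)
    candidates = _sweep_candidates(angle, config.search_width_angle, config.search_step_angle)
    filtered = fbp_filter(data, config.filter_name, geom)
    images, scores = [], []
    for a in candidates:
        g = geom.replace(phi=float(a))
        img = backproject_slice(filtered, g, x3=0.0) * _fbp_scale(g)
        images.append(img)
        scores.append(_tilt_score(img))
    sweep = TrySweep("lamino_angle", candidates, images, np.asarray(scores))
    if out_dir is not None:
        _write_sweep(sweep, out_dir, "try_lamino")
    return sweep


def _write_sweep(sweep: TrySweep, out_dir, prefix: str) -> None:
    from .io import write_tiff_stack

    names = [f"{prefix}_{c:010.4f}" for c in sweep.candidates]
    write_tiff_stack(out_dir, sweep.images, names=names)


def chunked_execute(func, data: np.ndarray, axis: int, chunk: int | None, combine: str = "concat"):
    """Apply ``func`` to ``data`` in chunks along ``axis``.

    The peak working set of the loop body is bounded by
    ``chunk / data.shape[axis]`` of the unchunked input plus whatever
    ``func`` allocates for a chunk-sized input; outputs are identical to
    the unchunked call because chunks are processed independently and
    recombined by concatenation (or summed, for reductions over the chunk
    axis).  A chunk larger than the data is clipped, not an error.
    """
    data = np.asarray(data)
    n = data.shape[axis]
    chunk = n if chunk is None else max(1, min(int(chunk), n))
    pieces = []
    for lo in range(0, n, chunk):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(lo, min(lo + chunk, n))
        pieces.append(func(data[tuple(sl)]))
    if combine == "concat":
        return np.concatenate(pieces, axis=axis)
    if combine == "sum":
        out = pieces[0].astype(np.result_type(pieces[0]), copy=True)
        for p in pieces[1:]:
            out += p
        return out
    raise ValueError("combine must be 'concat' or 'sum'")
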