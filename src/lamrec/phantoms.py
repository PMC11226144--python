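"""Synthetic phantoms for laminography simulation studies.

Two slab-shaped test objects are provided, chosen to bracket the behaviour
of real samples with respect to missing-cone artifacts:

* :func:`ic_phantom` — an integrated-circuit-like object: a few flat,
  high-amplitude "metal" layers carrying rectangular wiring segments,
  connected by vias.  Its strong, sharp features launch the characteristic
  "tail" artifacts at large tilt angles.
* :func:`brain_phantom` — a stained-tissue-like object: a bright smooth
  matrix containing many small low-contrast dark inclusions (axon-like
  dots).  Its homogeneous texture is far less sensitive to the missing
  cone.

Both are deterministic for a fixed seed, take values in [0, 1] on a zero
background, and scale their feature sizes with the grid so the same
generator serves reduced-size test runs.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Volume3D

__all__ = ["ic_phantom", "brain_phantom"]


def _shape_zyx(shape) -> tuple[int, int, int]:
    n1, n2, n3 = (int(v) for v in shape)
    if min(n1, n2, n3) < 8:
        raise ValueError("phantom sides must be >= 8 voxels")
    return n3, n2, n1


def ic_phantom(shape=(256, 256, 128), seed: int = 0) -> Volume3D:
    """Integrated-circuit-like layered phantom.

    Parameters
    ----------
    shape : (n1, n2, n3)
        Voxel counts; the third axis is the thin (layer-normal) direction.
    seed : int
        Seeds all random structure; calls are bit-reproducible.

    The volume contains 4 metal layers (amplitude ~0.9) with rectangular
    wiring routed alternately along x1 and x2, random pads, and vertical
    vias joining adjacent layers, giving a strongly bimodal histogram
    (background 0 vs metal ~0.9).
    """
    n3, n2, n1 = _shape_zyx(shape)
    rng = np.random.default_rng(seed)
    vol = np.zeros((n3, n2, n1), dtype=np.float32)

    n_layers = 4
    layer_t = max(2, n3 // 24)
    # keep layers inside the central 60% so projections stay on the detector
    zs = np.linspace(0.25 * n3, 0.75 * n3 - layer_t, n_layers).astype(int)
    # lateral support margin (inscribed square of the reconstructible cylinder)
    m1, m2 = int(0.18 * n1), int(0.18 * n2)
    wire_w = max(2, n1 // 64)

    for li, z0 in enumerate(zs):
        layer = np.zeros((n2, n1), dtype=np.float32)
        n_wires = max(4, n1 // 16)
        for _ in range(n_wires):
            amp = rng.uniform(0.8, 1.0)
            if li % 2 == 0:  # route along x1
                r = rng.integers(m2, n2 - m2 - wire_w)
                c0 = rng.integers(m1, n1 // 2)
                c1 = rng.integers(n1 // 2, n1 - m1)
                layer[r : r + wire_w, c0:c1] = amp
            else:  # route along x2
                c = rng.integers(m1, n1 - m1 - wire_w)
                r0 = rng.integers(m2, n2 // 2)
                r1 = rng.integers(n2 // 2, n2 - m2)
                layer[r0:r1, c : c + wire_w] = amp
        for _ in range(max(3, n1 // 32)):  # pads
            r = rng.integers(m2, n2 - m2 - 3 * wire_w)
            c = rng.integers(m1, n1 - m1 - 3 * wire_w)
            layer[r : r + 3 * wire_w, c : c + 3 * wire_w] = rng.uniform(0.85, 1.0)
        vol[z0 : z0 + layer_t] = layer[None]

    # vias between adjacent layers
    via_r = max(1, wire_w // 2)
    for li in range(n_layers - 1):
        for _ in range(max(4, n1 // 24)):
            r = rng.integers(m2 + via_r, n2 - m2 - via_r)
            c = rng.integers(m1 + via_r, n1 - m1 - via_r)
            vol[zs[li] : zs[li + 1] + layer_t, r - via_r : r + via_r + 1,
                c - via_r : c + via_r + 1] = 0.9
    return Volume3D(values=np.clip(vol, 0.0, 1.0))


def brain_phantom(shape=(256, 256, 128), seed: int = 0) -> Volume3D:
    """Stained-tissue-like phantom: smooth bright matrix with many small
    dark inclusions.

    The matrix is a Gaussian-correlated random field (correlation length
    ~n/32 voxels, values ~0.55-0.8) inside a soft-edged slab; axon-like
    dark dots (value ~0.2, radius 1-3 voxels) are scattered through it.
    The resulting texture is much smoother than :func:`ic_phantom` (longer
    autocorrelation length) and low contrast, mimicking osmium-stained
    tissue.
    """
    n3, n2, n1 = _shape_zyx(shape)
    rng = np.random.default_rng(seed)
    sigma = max(2.0, n1 / 32.0)
    base = gaussian_filter(rng.standard_normal((n3, n2, n1)), sigma, mode="nearest")
    base = (base - base.min()) / max(np.ptp(base), 1e-12)
    vol = (0.55 + 0.25 * base).astype(np.float32)

    # soft slab support: keeps the object inside the reconstructible region
    z = (np.arange(n3) - n3 / 2 + 0.5) / (0.42 * n3)
    y = (np.arange(n2) - n2 / 2 + 0.5) / (0.42 * n2)
    x = (np.arange(n1) - n1 / 2 + 0.5) / (0.42 * n1)
    r2 = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    support = np.clip(1.6 * (1.0 - r2), 0.0, 1.0).astype(np.float32) ** 2
    vol *= support

    n_dots = max(20, (n1 * n2 * n3) // 2000)
    zz = rng.integers(int(0.2 * n3), int(0.8 * n3), n_dots)
    yy = rng.integers(int(0.2 * n2), int(0.8 * n2), n_dots)
    xx = rng.integers(int(0.2 * n1), int(0.8 * n1), n_dots)
    rr = rng.integers(1, 4, n_dots)
    for zc, yc, xc, r in zip(zz, yy, xx, rr):
        z0, z1 = max(zc - r, 0), min(zc + r + 1, n3)
        y0, y1 = max(yc - r, 0), min(yc + r + 1, n2)
        x0, x1 = max(xc - r, 0), min(xc + r + 1, n1)
        gz, gy, gx = np.meshgrid(
            np.arange(z0, z1) - zc, np.arange(y0, y1) - yc, np.arange(x0, x1) - xc,
            indexing="ij",
        )
        ball = gz**2 + gy**2 + gx**2 <= r**2
        region = vol[z0:z1, y0:y1, x0:x1]
        region[ball] = np.minimum(region[ball], 0.2)
    return Volume3D(values=np.clip(vol, 0.0, 1.0))
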