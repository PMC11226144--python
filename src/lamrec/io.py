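"""File I/O: DXchange-style HDF5 projection files and 32-bit TIFF stacks."""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ProjectionStack

__all__ = [
    "write_dxchange",
    "read_dxchange",
    "write_tiff_stack",
    "read_tiff_stack",
]


def write_dxchange(path, stack: ProjectionStack) -> None:
    """Write projections, dark/flat fields and angles in DXchange layout.

    Datasets: /exchange/data, /exchange/data_dark, /exchange/data_white
    (one frame each here) and /exchange/theta in degrees.
    """
    with h5py.File(path, "w") as f:
        ex = f.create_group("exchange")
        ex.create_dataset("data", data=stack.data)
        ex.create_dataset("data_dark", data=stack.dark[None])
        ex.create_dataset("data_white", data=stack.flat[None])
        ex.create_dataset("theta", data=stack.angles)


def read_dxchange(path) -> ProjectionStack:
    """Read a DXchange-style HDF5 file; dark/flat frames are averaged."""
    with h5py.File(path, "r") as f:
        data = np.asarray(f["exchange/data"], dtype=np.float64)
        dark = np.asarray(f["exchange/data_dark"], dtype=np.float64)
        flat = np.asarray(f["exchange/data_white"], dtype=np.float64)
        theta = np.asarray(f["exchange/theta"], dtype=np.float64)
    if dark.ndim == 3:
        dark = dark.mean(axis=0)
    if flat.ndim == 3:
        flat = flat.mean(axis=0)
    return ProjectionStack(data=data, dark=dark, flat=flat, angles=theta)


def write_tiff_stack(out_dir, images, prefix: str = "recon", names=None) -> list:
    """Write images as 32-bit float TIFFs with zero-padded numeric names.

    ``images`` may be a 3D array (first axis = slice) or a list of 2D
    arrays.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        name = names[i] if names is not None else f"{prefix}_{i:05d}"
        p = out_dir / f"{name}.tiff"
        tifffile.imwrite(p, np.asarray(img, dtype=np.float32))
        paths.append(p)
    return paths


def read_tiff_stack(in_dir, prefix: str = "recon") -> np.ndarray:
    """Read a zero-padded TIFF stack back into a 3D array."""
    in_dir = Path(in_dir)
    files = sorted(in_dir.glob(f"{prefix}_*.tiff"))
    if not files:
        raise FileNotFoundError(f"no '{prefix}_*.tiff' files in {in_dir}")
    return np.stack([tifffile.imread(f) for f in files])
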