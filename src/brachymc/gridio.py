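"""Dose-grid serialization: HDF5 container + plain-text slice export.

The container stores the per-voxel mean, the relative Type A uncertainty
grid, the grid geometry, units, the seed and history count, and a format
version; readers reject future major versions.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import GridGeometry
from .tallies import DoseGrid, finalize_uncertainty

__all__ = ["save_dose_grid", "load_dose_grid", "export_slice_text"]

_FORMAT_VERSION = 1


def save_dose_grid(path, grid: DoseGrid, seed: int,
                   units: str = "eV/g per history",
                   metadata: dict | None = None) -> None:
    mean, rel, note = finalize_uncertainty(grid)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["generator"] = "brachymc"
        f.attrs["units"] = units
        f.attrs["seed"] = int(seed)
        f.attrs["n_histories"] = int(grid.n_histories)
        f.attrs["uncertainty_coverage"] = note
        f.attrs["spacing_cm"] = grid.geometry.spacing
        f.attrs["origin_cm"] = grid.geometry.origin
        f.create_dataset("mean", data=mean, compression="gzip")
        f.create_dataset("relative_uncertainty", data=rel,
                         compression="gzip")
        for k, v in (metadata or {}).items():
            f.attrs[k] = v


def load_dose_grid(path):
    """Returns (mean, relative_uncertainty, GridGeometry, attrs dict)."""
    with h5py.File(path, "r") as f:
        ver = int(f.attrs["format_version"])
        if ver > _FORMAT_VERSION:
            raise ValueError(
                f"{path}: dose-grid format version {ver} is newer than "
                f"this reader supports ({_FORMAT_VERSION})")
        mean = f["mean"][...]
        rel = f["relative_uncertainty"][...]
        geom = GridGeometry(
            shape=tuple(int(n) for n in mean.shape),
            spacing=tuple(float(s) for s in f.attrs["spacing_cm"]),
            origin=tuple(float(o) for o in f.attrs["origin_cm"]))
        attrs = dict(f.attrs)
    return mean, rel, geom, attrs


def export_slice_text(path, array: np.ndarray, axis: int, index: int,
                      header: str = "") -> None:
    """Plain-text export of one grid slice (rows = first remaining axis)."""
    sl = np.take(array, index, axis=axis)
    hdr = (f"# brachymc slice export (axis={axis}, index={index})\n"
           + (f"# {header}\n" if header else ""))
    with open(path, "w") as f:
        f.write(hdr)
        np.savetxt(f, sl, fmt="%.6e")
    Path(path)
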