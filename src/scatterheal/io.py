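"""Reading and writing detector images, masks, provenance maps and reports.

Detector frames and masks come in as single-channel TIFF (via tifffile) or
as a named 2D dataset inside an HDF5 file, addressed ``path.h5::dataset``
(default dataset ``data``). Healed outputs are written as float32 TIFF or
HDF5; provenance masks as 8-bit labeled images.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import tifffile

__all__ = [
    "load_array",
    "save_array",
    "save_provenance",
    "write_report",
    "parse_center",
    "parse_calib",
]

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf", ".nx"}


def _split_h5(path: str) -> Tuple[str, Optional[str]]:
    if "::" in path:
        p, ds = path.split("::", 1)
        return p, ds
    return path, None


def load_array(path: str, dataset: Optional[str] = None) -> np.ndarray:
    """Load a 2D array from TIFF or HDF5 (``file.h5::dataset``)."""
    fname, inline_ds = _split_h5(str(path))
    p = Path(fname)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    if p.suffix.lower() in _H5_SUFFIXES:
        ds = inline_ds or dataset or "data"
        with h5py.File(p, "r") as f:
            if ds not in f:
                raise KeyError(f"dataset {ds!r} not found in {p}")
            arr = np.asarray(f[ds])
    else:
        arr = tifffile.imread(p)
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise ValueError(f"{p}: expected a single-channel 2D image, got shape {arr.shape}")
    return arr


def save_array(path: str, arr: np.ndarray, dataset: str = "data") -> None:
    fname, inline_ds = _split_h5(str(path))
    p = Path(fname)
    if p.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(p, "w") as f:
            f.create_dataset(inline_ds or dataset, data=np.asarray(arr, dtype=np.float32))
    else:
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))


def save_provenance(path: str, prov: np.ndarray) -> None:
    p = Path(str(path))
    if p.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(p, "w") as f:
            f.create_dataset("provenance", data=np.asarray(prov, dtype=np.uint8))
    else:
        tifffile.imwrite(p, np.asarray(prov, dtype=np.uint8))


def write_report(path: str, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def parse_center(text: str) -> Tuple[float, float]:
    """Parse "x,y" beam-center text (0-based pixels, x = column)."""
    parts = text.split(",")
    if len(parts) != 2:
        raise ValueError(f"center must be 'x,y', got {text!r}")
    return float(parts[0]), float(parts[1])


def parse_calib(text: str):
    """Parse "distance_m,pixel_size_m,wavelength_A" into a Calibration."""
    from .geometry import Calibration

    parts = text.split(",")
    if len(parts) != 3:
        raise ValueError(f"calib must be 'DIST,PIX,WAVEL', got {text!r}")
    return Calibration(float(parts[0]), float(parts[1]), float(parts[2]))
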