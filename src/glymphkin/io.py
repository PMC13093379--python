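"""File I/O: NIfTI volumes with JSON sidecars, CSV curves and profiles.

Conventions: times in minutes, T1 in milliseconds, concentrations in mM at
every file boundary; curve CSVs carry a ``time_min`` first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_volume",
    "write_volume",
    "read_curve",
    "write_curve",
    "read_profile_csv",
    "write_profile_csv",
    "read_image",
    "write_image",
]


def read_image(path) -> np.ndarray:
    """Read a (multi-channel) fluorescence image from TIFF."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_image(path, data) -> Path:
    """Write an image array as TIFF (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))
    return Path(path)


def write_volume(path, data, affine=None, voxel_size_mm: float | None = None,
                 sidecar: dict | None = None) -> Path:
    """Write a float volume as NIfTI; optional JSON sidecar for metadata."""
    path = Path(path)
    if affine is None:
        s = voxel_size_mm if voxel_size_mm else 1.0
        affine = np.diag([s, s, s, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, path)
    if sidecar is not None:
        path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path):
    """Read a NIfTI volume; returns ``(data, affine, sidecar_dict_or_None)``."""
    path = Path(path)
    img = nib.load(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
    return np.asarray(img.dataobj, dtype=np.float64), img.affine, sidecar


def write_curve(path, times_min, values, value_name: str = "value") -> Path:
    """Write a curve CSV with columns ``time_min, <value_name>...``.

    ``values`` may be 1-D or a dict of name -> array for multiple columns.
    """
    t = np.asarray(times_min, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    cols = {"time_min": t}
    if isinstance(values, dict):
        cols.update({k: np.asarray(v, float) for k, v in values.items()})
    else:
        cols[value_name] = np.asarray(values, float)
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def read_curve(path):
    """Read a curve CSV; returns ``(times_min, DataFrame of value columns)``."""
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError("curve CSV must have a 'time_min' column")
    t = df["time_min"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time column")
    return t, df.drop(columns=["time_min"])


def write_profile_csv(path, profile) -> Path:
    """Write a line profile as ``position_um, aqp4, cd31, gfap``."""
    cols = {"position_um": profile.positions_um}
    cols.update(profile.channels)
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def read_profile_csv(path):
    from .aqp4 import LineProfile

    df = pd.read_csv(path)
    if "position_um" not in df.columns:
        raise ValueError("profile CSV must have a 'position_um' column")
    channels = {c: df[c].to_numpy(float) for c in df.columns if c != "position_um"}
    return LineProfile(positions_um=df["position_um"].to_numpy(float), channels=channels)
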