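"""NIfTI / JSON / CSV input-output helpers.

Volumes travel as NIfTI with a diagonal affine in millimetres; frame times,
seeds and realized parameters travel in JSON sidecars; stratified profiles
travel as CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .spatial import StratifiedProfile

__all__ = [
    "save_volume", "load_volume", "save_series", "load_series",
    "save_json", "load_json", "profile_to_frame", "profile_from_frame",
]


def _affine(spacing_um) -> np.ndarray:
    spacing_mm = np.asarray(spacing_um, dtype=float) / 1000.0
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(path, arr, spacing_um) -> None:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(spacing_um)), str(path))


def load_volume(path):
    """Load a 3D volume; returns (array, spacing_um)."""
    img = nib.load(str(path))
    spacing_um = np.asarray(img.header.get_zooms()[:3], dtype=float) * 1000.0
    return np.asarray(img.dataobj), spacing_um


def save_series(path, frames, spacing_um) -> None:
    """Save a 4D (x, y, z, t) series."""
    nib.save(nib.Nifti1Image(np.asarray(frames), _affine(spacing_um)), str(path))


def load_series(path):
    img = nib.load(str(path))
    spacing_um = np.asarray(img.header.get_zooms()[:3], dtype=float) * 1000.0
    return np.asarray(img.dataobj), spacing_um


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)!r}")


def profile_to_frame(profile: StratifiedProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "bin_lo_um": profile.bin_lo_um,
        "bin_hi_um": profile.bin_hi_um,
        "mean_vv": profile.mean_vv,
        "mean_ps": profile.mean_ps,
        "voxel_count": profile.voxel_count,
        "valid_count": profile.valid_count,
        "mean_vv_tissue": profile.mean_vv_tissue,
        "mean_ps_tissue": profile.mean_ps_tissue,
        "valid_tissue_count": profile.valid_tissue_count,
    })


def profile_from_frame(df: pd.DataFrame) -> StratifiedProfile:
    edges = np.append(df["bin_lo_um"].to_numpy(float), np.inf)
    # last bin_hi is inf; intermediate edges come from bin_lo
    return StratifiedProfile(
        bin_edges_um=edges,
        mean_vv=df["mean_vv"].to_numpy(float),
        mean_ps=df["mean_ps"].to_numpy(float),
        voxel_count=df["voxel_count"].to_numpy(int),
        valid_count=df["valid_count"].to_numpy(int),
        mean_vv_tissue=df["mean_vv_tissue"].to_numpy(float),
        mean_ps_tissue=df["mean_ps_tissue"].to_numpy(float),
        valid_tissue_count=df["valid_tissue_count"].to_numpy(int),
    )
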