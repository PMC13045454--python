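"""File I/O for the standard formats the pipeline touches.

Volumes, masks and velocity fields travel as NIfTI-1; physiological
traces, hypnograms and summary tables as CSV; sidecars and the run
manifest as JSON.  Velocity fields are serialized as 5D NIfTI with the
5th dimension holding the (x, y, z) vector components in voxel space,
with the affine recorded for world interpretation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .flow import VelocityField
from .spectral import VolumeSeries
from .synthetic import SleepScoreTrack

__all__ = [
    "read_volume_series",
    "write_volume_series",
    "read_velocity_field",
    "write_velocity_field",
    "read_mask",
    "write_mask",
    "read_trace",
    "write_trace",
    "read_hypnogram",
    "write_hypnogram",
    "write_manifest",
]


def write_volume_series(series: VolumeSeries, path: str | Path) -> Path:
    """Write a series as 4D float32 NIfTI-1 (time last, TR in pixdim[4])."""
    path = Path(path)
    affine = series.affine
    if affine is None:
        affine = np.diag([series.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(
        np.moveaxis(series.data, 0, -1).astype(np.float32), affine
    )
    tr = 1.0 / series.sampling_rate_hz
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_volume_series(path: str | Path) -> VolumeSeries:
    """Read a 4D NIfTI-1 series; errors on non-4D input or a zero TR."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {img.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3])
    if tr <= 0:
        raise ValueError(f"{path}: TR (pixdim[4]) is {tr}; refusing to guess a sampling rate")
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    return VolumeSeries(data, 1.0 / tr, float(zooms[0]), img.affine)


def write_velocity_field(
    field: VelocityField, path: str | Path, voxel_size_mm: float = 3.0
) -> Path:
    """Write a velocity field as 5D NIfTI (x, y, z, t, component) plus a
    JSON sidecar recording units and band; the valid mask is stored as a
    companion ``*_valid`` file."""
    path = Path(path)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    arr = np.moveaxis(field.components, 0, 3).astype(np.float32)  # x,y,z,t,3
    nib.save(nib.Nifti1Image(arr, affine), path)
    valid = np.moveaxis(field.valid_mask, 0, -1).astype(np.uint8)
    vpath = path.with_name(path.name.replace(".nii", "_valid.nii"))
    nib.save(nib.Nifti1Image(valid, affine), vpath)
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps({"units": field.units, "band": field.band_name}, indent=2)
    )
    return path


def read_velocity_field(path: str | Path) -> VelocityField:
    path = Path(path)
    img = nib.load(path)
    if img.ndim != 5 or img.shape[-1] != 3:
        raise ValueError(f"{path}: expected 5D (x,y,z,t,3) velocity data")
    comps = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), 3, 0)
    vpath = path.with_name(path.name.replace(".nii", "_valid.nii"))
    if vpath.exists():
        valid = np.moveaxis(np.asarray(nib.load(vpath).dataobj), -1, 0).astype(bool)
    else:
        valid = np.ones(comps.shape[:-1], bool)
    sidecar = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return VelocityField(
        comps, valid, meta.get("units", "voxel/frame"), meta.get("band", "")
    )


def write_mask(mask: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.int16), affine), path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask")
    return np.asarray(img.dataobj).astype(np.int16)


def write_trace(trace: np.ndarray, fs: float, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(trace)) / fs
    pd.DataFrame({"time_s": t, "value": trace}).to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return df["value"].to_numpy(), fs


def write_hypnogram(track: SleepScoreTrack, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "epoch": np.arange(len(track.labels)),
            "onset_s": np.arange(len(track.labels)) * track.epoch_length_s,
            "stage": track.labels,
        }
    ).to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path) -> SleepScoreTrack:
    df = pd.read_csv(path)
    if len(df) < 2:
        epoch = 30.0
    else:
        epoch = float(df["onset_s"].iloc[1] - df["onset_s"].iloc[0])
    return SleepScoreTrack(list(df["stage"]), epoch)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_dir: str | Path, extra: dict | None = None) -> Path:
    """List every artifact under ``output_dir`` with its SHA-256 checksum."""
    output_dir = Path(output_dir)
    # the log carries timestamps, so it is listed without a checksum to
    # keep same-seed reruns manifest-identical
    files = sorted(
        p
        for p in output_dir.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "artifacts": [
            {"path": str(p.relative_to(output_dir)), "sha256": _sha256(p)}
            for p in files
        ],
    }
    manifest.update(extra or {})
    out = output_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out
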