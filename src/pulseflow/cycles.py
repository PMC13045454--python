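"""Cycle-locked velocity analysis.

Each pulsation band is triggered from the region where it is most
conspicuous (an anterior-cerebral-artery-like ROI for cardiac pulses, a
4th-ventricle-like ROI for respiration, a posterior-cingulate-like ROI
for vasomotor waves).  Detected cycles are resampled to a common length
(0.9 s / 6 s / 20 s, i.e. 9 / 60 / 200 frames at 10 Hz) and averaged
voxel-wise, yielding a dynamic velocity map over the canonical cycle.
Direction stability over the cycle is summarized with circular statistics
on the unit-vector field (mean resultant vector and angular deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .flow import VelocityField
from .spectral import BandDefinition

__all__ = [
    "TriggerSet",
    "PulseCycleAverage",
    "DirectionalStats",
    "BAND_CYCLE_SECONDS",
    "detect_triggers",
    "resample_cycles",
    "cycle_speed_profile",
    "directional_stats",
    "roi_segment_summary",
]

#: Canonical cycle durations per band (seconds); at 10 Hz these give the
#: 9 / 60 / 200-frame cycle grids.
BAND_CYCLE_SECONDS = {"cardiac": 0.9, "respiratory": 6.0, "vasomotor": 20.0}


@dataclass
class TriggerSet:
    """Sorted frame indices of detected pulse onsets in a trigger ROI."""

    indices: np.ndarray
    band_name: str = ""
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) and np.any(np.diff(self.indices) <= 0):
            raise ValueError("trigger indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class PulseCycleAverage:
    """Velocity frames on a fixed cycle grid, averaged over cycles."""

    frames: np.ndarray  # (target_frames, nx, ny, nz, 3)
    n_cycles_averaged: int
    band_name: str = ""
    n_cycles_excluded: int = 0
    units: str = "voxel/frame"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.frames, axis=-1)


@dataclass
class DirectionalStats:
    """Per-voxel circular statistics of unit directions over a cycle.

    ``angular_std_rad`` is the chord-based angular deviation
    sqrt(2 * (1 - R)) with R the mean resultant length; it is 0 for
    perfectly aligned directions and sqrt(2) for antipodal ones, and
    decreases monotonically as R grows.
    """

    mean_direction: np.ndarray  # (..., 3), NaN where undefined
    angular_std_rad: np.ndarray
    resultant_length: np.ndarray
    valid_mask: np.ndarray


def detect_triggers(
    roi_signal: np.ndarray,
    band: BandDefinition,
    fs: float,
    prominence_sd: float = 0.5,
) -> TriggerSet:
    """Detect pulse triggers as signal minima (the fast systolic dip).

    Minima must have prominence >= ``prominence_sd`` times the signal SD
    and separation >= 0.5 / f_high seconds.
    """
    x = np.asarray(roi_signal, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant ROI signal: no triggers")
    distance = max(1, int(round(0.5 / band.f_high * fs)))
    peaks, _ = sps.find_peaks(-x, prominence=prominence_sd * sd, distance=distance)
    if len(peaks) == 0:
        raise ValueError(
            f"no minima with prominence >= {prominence_sd} SD in band {band.name!r}"
        )
    return TriggerSet(peaks, band.name)


def resample_cycles(
    fields: VelocityField,
    triggers: TriggerSet,
    target_frames: int,
    length_bounds: tuple[float, float] = (0.4, 2.5),
) -> PulseCycleAverage:
    """Resample trigger-to-trigger cycles to a fixed grid and average.

    Each cycle ``[t_i, t_{i+1})`` is linearly interpolated along time to
    ``target_frames`` samples (closed-open: the next trigger is the
    exclusive endpoint) and the cycles are averaged voxel-wise.  Cycles
    whose length falls outside ``length_bounds`` times the median
    inter-trigger interval are excluded (missed or spurious triggers) and
    counted in ``n_cycles_excluded``.
    """
    if target_frames < 2:
        raise ValueError("target_frames must be >= 2")
    idx = triggers.indices
    idx = idx[idx <= fields.n_frames]
    if len(idx) < 2:
        raise ValueError("need at least two triggers (one complete cycle)")
    lengths = np.diff(idx)
    med = float(np.median(lengths))
    keep = (lengths >= length_bounds[0] * med) & (lengths <= length_bounds[1] * med)
    # a cycle spanning frames [t0, t1) needs flow frames t0 .. t1-1
    keep &= idx[1:] <= fields.n_frames
    n_excl = int((~keep).sum())
    if not keep.any():
        raise ValueError("no usable cycles after length filtering")

    acc = np.zeros((target_frames,) + fields.components.shape[1:], dtype=np.float64)
    n_used = 0
    for t0, t1, ok in zip(idx[:-1], idx[1:], keep):
        if not ok:
            continue
        src_t = np.arange(t0, t1)
        tgt_t = t0 + np.arange(target_frames) * (t1 - t0) / target_frames
        seg = fields.components[t0:t1]
        if len(src_t) == 1:
            acc += seg[0]
        else:
            lo = np.clip(np.searchsorted(src_t, tgt_t, side="right") - 1, 0, len(src_t) - 2)
            w = (tgt_t - src_t[lo]) / (src_t[lo + 1] - src_t[lo])
            acc += seg[lo] * (1 - w)[:, None, None, None, None] + seg[lo + 1] * w[
                :, None, None, None, None
            ]
        n_used += 1
    return PulseCycleAverage(
        (acc / n_used).astype(np.float32),
        n_used,
        fields.band_name,
        n_excl,
        fields.units,
    )


def cycle_speed_profile(
    cycle: PulseCycleAverage, roi: np.ndarray
) -> tuple[np.ndarray, int]:
    """ROI-mean speed per cycle frame, plus the count of its local maxima.

    The curve is treated as circular (the cycle wraps), lightly smoothed
    with a 3-frame moving mean, and maxima are counted as samples strictly
    greater than both circular neighbours.  A pulsatile inflow driven by a
    sinusoidal displacement shows two speed maxima per cycle (peak and
    nadir of the displacement waveform).
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    curve = cycle.speed[:, roi].mean(axis=1)
    sm = (np.roll(curve, 1) + curve + np.roll(curve, -1)) / 3.0
    n_max = int(np.sum((sm > np.roll(sm, 1)) & (sm > np.roll(sm, -1))))
    return curve, n_max


def directional_stats(
    direction_frames: np.ndarray, metric: str = "chord"
) -> DirectionalStats:
    """Circular statistics of per-frame unit directions at each voxel.

    ``direction_frames`` has shape ``(n_frames, ..., 3)`` with NaN where
    a direction was undefined.  Per voxel the mean resultant vector of the
    valid unit directions gives the mean direction and resultant length
    R in [0, 1]; the angular deviation is sqrt(2(1-R)) (``metric="chord"``)
    or sqrt(-2 ln R) (``metric="log"``).  Voxels with no valid frame are
    masked.
    """
    if metric not in ("chord", "log"):
        raise ValueError("metric must be 'chord' or 'log'")
    d = np.asarray(direction_frames, dtype=np.float64)
    finite = np.isfinite(d).all(axis=-1)
    n_valid = finite.sum(axis=0)
    valid = n_valid > 0
    dz = np.where(finite[..., None], d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_vec = dz.sum(axis=0) / n_valid[..., None]
    rbar = np.linalg.norm(mean_vec, axis=-1)
    rbar = np.where(valid, np.clip(rbar, 0.0, 1.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dir = np.where(
            (rbar > 0)[..., None] & valid[..., None],
            mean_vec / np.where(rbar > 0, rbar, 1.0)[..., None],
            np.nan,
        )
        if metric == "chord":
            ang = np.sqrt(2.0 * (1.0 - rbar))
        else:
            ang = np.sqrt(-2.0 * np.log(np.maximum(rbar, 1e-300)))
    return DirectionalStats(mean_dir, ang, rbar, valid)


def roi_segment_summary(
    scalar_map: np.ndarray,
    segmentation: np.ndarray,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-segment mean and SD of a scalar map, plus a whole-mask row.

    ``segmentation`` is an integer-labelled mask (0 = background).  Labels
    named in ``label_names`` but absent from the segmentation are reported
    with NaN statistics rather than raising.
    """
    seg = np.asarray(segmentation)
    labels = sorted(set(np.unique(seg[seg > 0]).tolist()) | set(label_names or {}))
    if not labels:
        raise ValueError("segmentation contains no labels >= 1")
    rows = []
    for lab in labels:
        sel = seg == lab
        name = (label_names or {}).get(lab, f"roi_{lab}")
        if sel.any():
            vals = scalar_map[sel]
            rows.append((name, int(lab), int(sel.sum()), vals.mean(), vals.std()))
        else:
            rows.append((name, int(lab), 0, np.nan, np.nan))
    union = seg > 0
    vals = scalar_map[union]
    rows.append(("whole", 0, int(union.sum()), vals.mean(), vals.std()))
    return pd.DataFrame(rows, columns=["roi", "label", "n_voxels", "mean", "sd"])
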