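"""Spectral analysis of volumetric time series.

Fast fMRI sampled at 10 Hz resolves the three physiological pulsations that
drive intracranial fluid motion -- cardiovascular (~1 Hz), respiratory
(~0.3 Hz) and very-low-frequency vasomotor (< 0.1 Hz) waves -- without
mutual aliasing.  This module provides the voxel-wise periodogram, band
power summation, zero-phase band separation, and the aliasing arithmetic
needed to interpret spectral content above the Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "VolumeSeries",
    "BandDefinition",
    "PowerSpectrumMap",
    "DEFAULT_BANDS",
    "periodogram_map",
    "band_power_map",
    "bandpass_filter",
    "alias_frequency",
    "derive_band_ranges",
    "peak_frequency",
]


@dataclass
class VolumeSeries:
    """A 4D intensity series (time first) with acquisition geometry.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, nx, ny, nz)``.
    sampling_rate_hz
        Volume sampling rate (10 Hz for a 100 ms repetition time).
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    affine
        Optional voxel-to-world affine (4x4), carried through file I/O.
    """

    data: np.ndarray
    sampling_rate_hz: float
    voxel_size_mm: float = 3.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"VolumeSeries requires 4D (t, x, y, z) data, got {self.data.ndim}D"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def nyquist_hz(self) -> float:
        return self.sampling_rate_hz / 2.0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate_hz


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_low, f_high]`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )


#: Group-level band conventions: cardiac low edge from the group-minimum
#: heart rate up to the full 5 Hz range (harmonics preserved); respiratory
#: from group min/max breathing rates; vasomotor fixed below the respiratory
#: range; slow-delta is the EEG sleep-depth band.
DEFAULT_BANDS: Mapping[str, BandDefinition] = {
    "cardiac": BandDefinition("cardiac", 0.51, 5.0),
    "respiratory": BandDefinition("respiratory", 0.08, 0.49),
    "vasomotor": BandDefinition("vasomotor", 0.01, 0.08),
    "slow_delta": BandDefinition("slow_delta", 0.2, 2.0),
}


@dataclass
class PowerSpectrumMap:
    """One-sided voxel-wise power spectrum.

    ``power`` has shape ``(n_bins // 2, *spatial)`` with bins at
    ``k * fs / n_bins`` for ``k = 1 .. n_bins // 2``, covering
    ``(0, Nyquist]``.  DC power is reported separately in ``dc_power``.
    ``normalization`` is ``"parseval"`` (two-sided sum equals the
    time-domain sum of squares) or ``"mean_square"`` (sum equals the
    time-domain mean square).
    """

    power: np.ndarray
    bin_centers_hz: np.ndarray
    dc_power: np.ndarray
    sampling_rate_hz: float
    normalization: str = "parseval"

    @property
    def bin_width_hz(self) -> float:
        return float(self.bin_centers_hz[0])


def periodogram_map(
    series: VolumeSeries, n_bins: int = 4096, normalization: str = "parseval"
) -> PowerSpectrumMap:
    """Voxel-wise FFT power map with ``n_bins`` two-sided frequency bins.

    The series is zero-padded to ``n_bins`` points (4096 bins at 10 Hz
    give 2048 one-sided bins over 0-5 Hz).  ``n_bins`` must be a positive
    even integer no smaller than the series length.
    """
    if not isinstance(n_bins, (int, np.integer)) or n_bins <= 0 or n_bins % 2:
        raise ValueError(f"n_bins must be a positive even integer, got {n_bins}")
    if n_bins < series.n_frames:
        raise ValueError(
            f"n_bins ({n_bins}) < series length ({series.n_frames}); "
            "zero-padding only, no truncation"
        )
    if normalization not in ("parseval", "mean_square"):
        raise ValueError(f"unknown normalization {normalization!r}")

    x = np.asarray(series.data, dtype=np.float64)
    # remove the temporal mean before zero-padding: otherwise the pad
    # step turns the DC level into spurious low-frequency leakage
    xm = x.mean(axis=0)
    spec = np.fft.rfft(x - xm, n=n_bins, axis=0)
    mag2 = np.abs(spec) ** 2

    norm = float(n_bins)
    if normalization == "mean_square":
        norm *= series.n_frames

    dc = series.n_frames * xm**2 / (1.0 if normalization == "parseval" else series.n_frames)
    # interior bins appear twice in the two-sided spectrum; the Nyquist
    # bin (k = n_bins/2) appears once
    power = np.empty_like(mag2[1:])
    power[:-1] = 2.0 * mag2[1:-1] / norm
    power[-1] = mag2[-1] / norm

    fs = series.sampling_rate_hz
    bins = np.arange(1, n_bins // 2 + 1) * (fs / n_bins)
    return PowerSpectrumMap(power, bins, dc, fs, normalization)


def band_power_map(spectrum: PowerSpectrumMap, band: BandDefinition) -> np.ndarray:
    """Per-voxel summed power over bins with ``f_low <= f <= f_high``."""
    sel = (spectrum.bin_centers_hz >= band.f_low) & (
        spectrum.bin_centers_hz <= band.f_high
    )
    if not sel.any():
        raise ValueError(
            f"band {band.name!r} [{band.f_low}, {band.f_high}] Hz contains no "
            f"spectral bins (bin width {spectrum.bin_width_hz:.4g} Hz)"
        )
    return spectrum.power[sel].sum(axis=0)


def _design_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    # tolerance covers float32 round-trip of the sampling rate via file headers
    if band.f_high > nyq * (1 + 1e-6):
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_high} Hz exceeds the "
            f"Nyquist frequency {nyq} Hz"
        )
    if band.f_high >= nyq * (1 - 1e-9):
        # band reaching Nyquist (e.g. cardiac 0.51-5 Hz at fs=10):
        # a high-pass keeps the full upper range including harmonics
        return sps.butter(order, band.f_low, btype="highpass", fs=fs, output="sos")
    return sps.butter(
        order, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_filter(series: VolumeSeries, band: BandDefinition) -> VolumeSeries:
    """Zero-phase 4th-order Butterworth band separation along time.

    Forward-backward filtering (``sosfiltfilt`` with reflective padding)
    removes group delay, which matters because velocity timing within the
    pulse cycle is an endpoint of the analysis.
    """
    sos = _design_sos(band, series.sampling_rate_hz)
    padlen = min(series.n_frames - 1, 3 * int(series.sampling_rate_hz / band.f_low))
    out = sps.sosfiltfilt(sos, series.data, axis=0, padtype="even", padlen=padlen)
    return VolumeSeries(
        out.astype(series.data.dtype, copy=False),
        series.sampling_rate_hz,
        series.voxel_size_mm,
        series.affine,
    )


def bandpass_1d(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band separation of a 1D physiological trace."""
    sos = _design_sos(band, fs)
    padlen = min(len(x) - 1, 3 * int(fs / band.f_low))
    return sps.sosfiltfilt(sos, np.asarray(x, float), padtype="even", padlen=padlen)


def alias_frequency(f: float, fs: float) -> float:
    """Apparent frequency of an ``f`` Hz component sampled at ``fs`` Hz.

    Content above the Nyquist frequency folds back:
    ``alias(5.7, 10) == 4.3``.  Result lies in ``[0, fs/2]``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if np.any(np.asarray(f) < 0):
        raise ValueError("f must be non-negative")
    return float(np.abs(f - fs * np.round(np.asarray(f, float) / fs)))


def peak_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency of the maximum non-DC bin of a 1D signal's power spectrum."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need a 1D signal of length >= 4")
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    if not spec[1:].any():
        raise ValueError("signal has no non-DC spectral content (constant input?)")
    k = int(np.argmax(spec[1:])) + 1
    return k * fs / len(x)


def derive_band_ranges(
    per_subject_peaks: pd.DataFrame,
    cardiac_high_hz: float = 5.0,
    vasomotor_band: tuple[float, float] = (0.01, 0.08),
) -> dict[str, BandDefinition]:
    """Group-level band edges from per-subject peak-frequency tables.

    ``per_subject_peaks`` needs columns ``"cardiac"`` and ``"respiratory"``
    (one row per recording).  The respiratory band spans the group minimum
    to maximum detected rate; the cardiac band runs from the group-minimum
    cardiac peak up to ``cardiac_high_hz`` so that pulse-shape harmonics
    are retained; the vasomotor band is fixed by convention below the
    respiratory range.
    """
    for col in ("cardiac", "respiratory"):
        if col not in per_subject_peaks.columns:
            raise ValueError(f"peak table missing column {col!r}")
    if len(per_subject_peaks) == 0:
        raise ValueError("peak table is empty")
    resp = per_subject_peaks["respiratory"].astype(float)
    card = per_subject_peaks["cardiac"].astype(float)
    bands = {
        "cardiac": BandDefinition("cardiac", float(card.min()), cardiac_high_hz),
        "respiratory": BandDefinition(
            "respiratory", float(resp.min()), float(resp.max())
        ),
        "vasomotor": BandDefinition("vasomotor", *vasomotor_band),
    }
    return bands
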