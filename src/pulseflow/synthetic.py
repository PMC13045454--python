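"""Synthetic phantoms and awake/sleep cohorts with known ground truth.

Two generators make every downstream stage testable without any scanner
data:

* a pulsatile porous-medium phantom -- a streaked "fruit flesh" texture
  with an impermeable rind, advected along a central bore and radially
  outward by a periodic displacement field of known peak amplitude,
  mimicking a pineapple perfused by a peristaltic pump;

* a paired awake/sleep cohort whose volumes carry three band-limited
  travelling pulsation waves (a cardiac dip train with harmonics around
  the subject's heart rate, respiratory and vasomotor sinusoids) that
  propagate through a textured "brain" at known, spatially varying
  speeds.  Sleep scales each band's wave amplitude and propagation speed
  together inside an effect region by known multipliers (cardiac x0.78,
  respiratory x1.29, vasomotor x1.21), and a slow-delta EEG power
  covariate is drawn with a prescribed correlation to the vasomotor (+)
  and cardiac (-) band powers.

All randomness is controlled by the spec seed; regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .spectral import VolumeSeries

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "CohortSpec",
    "SleepScoreTrack",
    "Cohort",
    "CohortSubject",
    "ConditionData",
    "generate_phantom",
    "generate_pump_signal",
    "generate_cohort",
    "phantom_bore_roi",
    "draw_power_covariates",
    "summarize_hypnogram",
]

SLEEP_STAGES = ("W", "N1", "N2", "N3", "ART")

#: Observed stage distribution of selected sleep epochs (percent).
SLEEP_STAGE_PROBS = {"W": 0.10, "N1": 0.43, "N2": 0.43, "N3": 0.01, "ART": 0.02}
AWAKE_STAGE_PROBS = {"W": 0.99, "N1": 0.005, "ART": 0.005}


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of the pulsatile flow phantom.

    The bore (default 7 mm diameter, i.e. 3.5 mm radius) runs along the
    first grid axis through the centre of the fruit; peak_velocity_cm_s is
    the true peak flow speed at the bore exit.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 3.0
    sampling_rate_hz: float = 10.0
    duration_s: float = 60.0
    pulse_freq_hz: float = 2.0
    peak_velocity_cm_s: float = 22.0
    bore_radius_mm: float = 3.5
    streak_contrast: float = 0.3
    noise_sd: float = 0.01
    seed: int = 0
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.pulse_freq_hz <= 0:
            raise ValueError("pulse_freq_hz must be positive")
        if self.peak_velocity_cm_s < 0:
            raise ValueError("peak_velocity_cm_s must be >= 0")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate_hz and duration_s must be positive")
        bore_vox = self.bore_radius_mm / self.voxel_size_mm
        if 2 * bore_vox >= min(self.grid_shape[1:]):
            raise ValueError("bore does not fit inside the grid cross-section")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    @property
    def peak_displacement_vox(self) -> float:
        """Peak true displacement in voxels/frame: v / (voxel_cm * fs)."""
        return self.peak_velocity_cm_s / (
            (self.voxel_size_mm / 10.0) * self.sampling_rate_hz
        )


@dataclass
class PhantomGroundTruth:
    """True displacement field of a generated phantom (the recovery oracle).

    The field is separable: ``displacement_frame(t) = spatial * temporal[t]``
    with ``spatial`` of shape ``(nx, ny, nz, 3)`` (voxels/frame at unit
    drive) and ``temporal`` of length ``n_frames - 1``.  The dense 5D
    array is available through :attr:`displacement_field` but is built on
    demand to keep long phantoms cheap.
    """

    spatial: np.ndarray
    temporal: np.ndarray
    peak_velocity_cm_s: float
    pulse_freq_hz: float
    flow_mask: np.ndarray
    voxel_size_mm: float
    sampling_rate_hz: float

    def displacement_frame(self, t: int) -> np.ndarray:
        """Displacement (voxels/frame) carrying frame ``t`` to ``t + 1``."""
        return self.spatial * self.temporal[t]

    @property
    def n_frames(self) -> int:
        return len(self.temporal)

    @property
    def displacement_field(self) -> np.ndarray:
        return self.spatial[None] * self.temporal[:, None, None, None, None]

    @property
    def peak_displacement_vox(self) -> float:
        spatial_max = np.linalg.norm(self.spatial, axis=-1).max()
        return float(spatial_max * np.abs(self.temporal).max())


def _fruit_geometry(spec: PhantomSpec):
    """Fruit interior taper, flow mask and flow pattern for the phantom."""
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    semi = np.array([0.45 * nx, 0.45 * ny, 0.45 * nz])
    rho = np.sqrt(
        ((x - cx) / semi[0]) ** 2
        + ((y - cy) / semi[1]) ** 2
        + ((z - cz) / semi[2]) ** 2
    )
    fruit = rho <= 1.0
    # impermeable rind: ~2 voxels inside the surface carry no flow, with a
    # smooth taper so the displacement field stays continuous
    rind_frac = 2.0 / semi.min()
    taper = np.clip((1.0 - rind_frac - rho) / rind_frac, 0.0, 1.0)

    r = np.sqrt((y - cy) ** 2 + (z - cz) ** 2)
    sigma_b = spec.bore_radius_mm / spec.voxel_size_mm + 1.5
    axial = np.exp(-0.5 * (r / sigma_b) ** 2)
    radial = 0.5 * (r / sigma_b) * np.exp(-0.5 * (r / sigma_b) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ey = np.where(r > 0, (y - cy) / np.maximum(r, 1e-12), 0.0)
        ez = np.where(r > 0, (z - cz) / np.maximum(r, 1e-12), 0.0)
    pattern = np.stack([axial, radial * ey, radial * ez], axis=-1)
    pattern *= taper[..., None]
    return fruit, taper, pattern


def _phantom_texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Supersampled master texture: radial streaks plus smooth noise."""
    ss = spec.supersample
    shape = tuple(s * ss for s in spec.grid_shape)
    xi = np.arange(shape[0]) / ss
    yi = np.arange(shape[1]) / ss
    zi = np.arange(shape[2]) / ss
    x, y, z = np.meshgrid(xi, yi, zi, indexing="ij")
    cy = (spec.grid_shape[1] - 1) / 2.0
    cz = (spec.grid_shape[2] - 1) / 2.0
    r = np.sqrt((y - cy) ** 2 + (z - cz) ** 2)
    theta = np.arctan2(z - cz, y - cy)
    c = spec.streak_contrast
    tex = (
        1.0
        + c * 0.40 * np.cos(2 * np.pi * r / 2.5 + 3 * theta)
        + c * 0.30 * np.cos(8 * theta)
        # axial fruitlet striation across three octaves: axial bulk motion
        # is only visible to optical flow if intensity varies along the
        # bore axis, and the coarse pyramid levels only keep wavelengths
        # that survive repeated halving
        + c * 0.35 * np.cos(2 * np.pi * x / 5.0)
        + c * 0.25 * np.cos(2 * np.pi * x / 11.0 + 1.0)
        + c * 0.30 * np.cos(2 * np.pi * x / 17.0 + 2.0)
    )
    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=1.5 * ss, mode="wrap")
    noise /= max(noise.std(), 1e-12)
    return tex + c * 0.10 * noise


def _advect_frame(
    master: np.ndarray, supersample: int, offset: np.ndarray
) -> np.ndarray:
    """Sample the supersampled master at base-grid positions minus offset."""
    grid_shape = tuple(s // supersample for s in master.shape)
    idx = np.indices(grid_shape, dtype=np.float64)
    coords = (idx - np.moveaxis(offset, -1, 0)) * supersample
    return ndimage.map_coordinates(master, coords, order=1, mode="reflect")


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeSeries, PhantomGroundTruth]:
    """Generate a pulsatile-flow phantom series and its ground truth.

    The texture is advected semi-Lagrangially: frame t samples a x4
    supersampled master texture at positions displaced by the cumulative
    displacement, which keeps total intensity conserved up to
    interpolation error.  The ground-truth per-frame displacement is
    normalized so that its peak, converted to cm/s, equals
    ``peak_velocity_cm_s`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    fruit, taper, pattern = _fruit_geometry(spec)
    master = _phantom_texture(spec, rng)
    # background outside the fruit is dimmer and unstructured
    base_idx = np.indices(spec.grid_shape)

    n = spec.n_frames
    t_mid = (np.arange(n - 1) + 0.5) / spec.sampling_rate_hz
    temporal = np.sin(2 * np.pi * spec.pulse_freq_hz * t_mid)

    pattern_max = np.linalg.norm(pattern, axis=-1).max()
    temporal_max = np.abs(temporal).max()
    if spec.peak_displacement_vox > 0 and pattern_max * temporal_max > 0:
        spatial = pattern * (spec.peak_displacement_vox / (pattern_max * temporal_max))
    else:
        spatial = np.zeros_like(pattern)
        temporal = np.zeros_like(temporal)

    data = np.empty((n,) + spec.grid_shape, dtype=np.float32)
    offset = np.zeros(spec.grid_shape + (3,), dtype=np.float64)
    outside = ~fruit
    for t in range(n):
        frame = _advect_frame(master, spec.supersample, offset)
        frame[outside] = 0.2
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        data[t] = frame
        if t < n - 1:
            offset += spatial * temporal[t]

    series = VolumeSeries(data, spec.sampling_rate_hz, spec.voxel_size_mm)
    flow_mask = np.linalg.norm(spatial, axis=-1) > 0
    truth = PhantomGroundTruth(
        spatial,
        temporal,
        spec.peak_velocity_cm_s,
        spec.pulse_freq_hz,
        flow_mask,
        spec.voxel_size_mm,
        spec.sampling_rate_hz,
    )
    return series, truth


def phantom_bore_roi(
    spec: PhantomSpec, slab_halfwidth: int = 2, radius_pad_vox: float = 1.0
) -> np.ndarray:
    """Cross-sectional ROI just inside the flow entry point.

    A slab of ``2 * slab_halfwidth + 1`` slices around the grid centre,
    restricted to voxels within the bore radius (plus a pad) of the bore
    axis -- the region where peak flow speed is measured, both on the
    true displacement field and on optical-flow output.
    """
    nx, ny, nz = spec.grid_shape
    y, z = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    r = np.hypot(y - (ny - 1) / 2.0, z - (nz - 1) / 2.0)
    cross = r < (spec.bore_radius_mm / spec.voxel_size_mm + radius_pad_vox)
    roi = np.zeros(spec.grid_shape, dtype=bool)
    roi[nx // 2 - slab_halfwidth : nx // 2 + slab_halfwidth + 1] = cross
    return roi


def generate_pump_signal(
    rotation_fraction: float,
    max_pulse_rate_hz: float = 20.1,
    duration_s: float = 60.0,
    fs: float = 10.0,
    duty: float = 0.5,
) -> np.ndarray:
    """Sampled waveform of a three-head peristaltic pump.

    The pulsation rate is ``rotation_fraction * max_pulse_rate_hz`` (the
    three rotor heads each deliver one pulse per revolution, so the pulse
    rate scales with rotation speed).  The waveform is a raised-cosine
    pulse train (duty cycle 0.5) so that realistic harmonics exist;
    sampling at ``fs`` aliases pulse rates above ``fs / 2`` exactly as a
    scanner would.
    """
    if not 0 < rotation_fraction <= 1:
        raise ValueError("rotation_fraction must be in (0, 1]")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    f_pulse = rotation_fraction * max_pulse_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = np.mod(f_pulse * t, 1.0)
    x = np.where(phase < duty, 0.5 * (1 - np.cos(2 * np.pi * phase / duty)), 0.0)
    return x


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


@dataclass
class SleepScoreTrack:
    """Epoch-wise sleep-stage labels (30 s epochs by default)."""

    labels: list[str]
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("labels must be non-empty")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        bad = set(self.labels) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")


def summarize_hypnogram(track: SleepScoreTrack) -> dict[str, float]:
    """Stage percentages plus the NREM total (N1 + N2 + N3)."""
    n = len(track.labels)
    out = {s: 100.0 * track.labels.count(s) / n for s in SLEEP_STAGES}
    out["NREM"] = out["N1"] + out["N2"] + out["N3"]
    return out


@dataclass
class CohortSpec:
    """Study conditions for the paired awake/sleep synthetic cohort.

    Heart/respiratory rates are (mean, sd) in Hz; sleep multipliers scale
    each band's pulsation amplitude and wave speed inside ``effect_roi``
    (cardiac slows in sleep, respiratory and vasomotor speed up).
    ``mean_speed_cm_s`` calibrates the awake whole-brain mean
    ground-truth speed per band; ``delta_coupling`` gives the target
    correlation of log slow-delta EEG power with log band power
    (positive for vasomotor, negative for cardiac).
    """

    n_subjects: int = 22
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    sampling_rate_hz: float = 10.0
    duration_s: float = 60.0
    heart_rate_hz: tuple[float, float] = (1.02, 0.15)
    resp_rate_hz: tuple[float, float] = (0.27, 0.05)
    vaso_freq_hz: float = 0.05
    cardiac_sleep_multiplier: float = 0.78
    resp_sleep_multiplier: float = 1.29
    vaso_sleep_multiplier: float = 1.21
    mean_speed_cm_s: dict = dc_field(
        default_factory=lambda: {
            "cardiac": 3.27,
            "respiratory": 0.26,
            "vasomotor": 0.058,
        }
    )
    delta_coupling: dict = dc_field(
        default_factory=lambda: {"vasomotor": 0.5, "cardiac": -0.5}
    )
    effect_roi: np.ndarray | None = None
    texture_contrast: float = 0.3
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name, m in self.sleep_multipliers.items():
            if m <= 0:
                raise ValueError(f"{name} sleep multiplier must be > 0, got {m}")
        nyq = self.sampling_rate_hz / 2.0
        for name, rate in (
            ("heart_rate_hz", self.heart_rate_hz[0]),
            ("resp_rate_hz", self.resp_rate_hz[0]),
            ("vaso_freq_hz", self.vaso_freq_hz),
        ):
            if not 0 < rate < nyq:
                raise ValueError(f"{name} mean must lie in (0, Nyquist)")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 for any paired analysis")

    @property
    def sleep_multipliers(self) -> dict[str, float]:
        return {
            "cardiac": self.cardiac_sleep_multiplier,
            "respiratory": self.resp_sleep_multiplier,
            "vasomotor": self.vaso_sleep_multiplier,
        }

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class ConditionData:
    """One scanning condition (awake or sleep) of one subject."""

    series: VolumeSeries
    cardiac_trace: np.ndarray
    resp_trace: np.ndarray
    hypnogram: SleepScoreTrack
    slow_delta_log_power: float


@dataclass
class CohortSubject:
    subject_id: int
    heart_rate_hz: float
    resp_rate_hz: float
    awake: ConditionData
    sleep: ConditionData
    log_band_power: dict[str, float]
    #: per band: ground-truth mean speed (cm/s) over brain mask and over
    #: the effect ROI, for each condition
    truth: dict[str, dict[str, float]]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[CohortSubject]
    brain_mask: np.ndarray
    effect_roi: np.ndarray
    trigger_rois: dict[str, np.ndarray]

    def __len__(self) -> int:
        return len(self.subjects)


def draw_power_covariates(
    n: int, coupling: dict[str, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Subject-level log-power covariates with prescribed delta coupling.

    Draws a latent slow-delta factor z ~ N(0, 1) and, for each band with a
    target correlation r, a log band-power score r*z + sqrt(1-r^2)*eps.
    Returns ``{"log_delta": ..., "<band>": ...}`` arrays of length n.
    """
    z = rng.standard_normal(n)
    out = {"log_delta": z}
    for band, r in coupling.items():
        if not -1 <= r <= 1:
            raise ValueError(f"coupling for {band!r} must lie in [-1, 1]")
        eps = rng.standard_normal(n)
        out[band] = r * z + np.sqrt(1 - r**2) * eps
    return out




def _gaussian_bump(
    shape: tuple[int, int, int], center: np.ndarray, sigma: float
) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return np.exp(-0.5 * d2 / sigma**2)


def _sphere_mask(
    shape: tuple[int, int, int], center: np.ndarray, radius: float
) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def _cardiac_shape_coeffs(duty: float = 0.3, n_max: int = 12) -> np.ndarray:
    """Fourier coefficients of a periodic systolic dip (sharp raised-cosine
    drop followed by a flat recovery), used to synthesize a band-limited
    cardiac waveform with realistic harmonics."""
    phi = np.linspace(0, 1, 2048, endpoint=False)
    dip = np.where(phi < duty, -0.5 * (1 - np.cos(2 * np.pi * phi / duty)), 0.0)
    dip -= dip.mean()
    return np.fft.rfft(dip)[: n_max + 1] / len(phi)


def _eval_harmonics(theta: np.ndarray, coeffs: np.ndarray, n_harm: int) -> np.ndarray:
    """Evaluate sum_k 2 Re[c_k exp(2 pi i k theta)] for k = 1..n_harm."""
    out = np.zeros_like(theta, dtype=np.float64)
    for k in range(1, n_harm + 1):
        out += 2.0 * (
            coeffs[k].real * np.cos(2 * np.pi * k * theta)
            - coeffs[k].imag * np.sin(2 * np.pi * k * theta)
        )
    return out


#: propagation axis per band (voxel axis index) and relative intensity
#: amplitude of the wave at the envelope peak
_BAND_AXES = {"cardiac": 1, "respiratory": 2, "vasomotor": 0}
_BAND_BASE_AMP = {"cardiac": 0.30, "respiratory": 0.22, "vasomotor": 0.18}


def _cohort_geometry(spec: CohortSpec):
    shape = spec.grid_shape
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=np.float64)
    semi = 0.45 * np.array(shape)
    rho = np.sqrt(sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3)))
    brain = rho <= 1.0
    taper = np.clip((1.0 - rho) / 0.15, 0.0, 1.0)
    # band source foci: anterior-artery-like, 4th-ventricle-like and
    # posterior-cingulate-like locations, offset along distinct axes
    centers = {
        "cardiac": center + np.array([0.0, -0.20 * shape[1], 0.0]),
        "respiratory": center + np.array([0.12 * shape[0], 0.0, -0.18 * shape[2]]),
        "vasomotor": center + np.array([0.0, 0.20 * shape[1], 0.0]),
    }
    bumps = {b: _gaussian_bump(shape, c, sigma=min(shape) / 3.5) for b, c in centers.items()}
    # intensity-amplitude envelope: broad floor plus band-specific focus
    envelopes = {b: (0.35 + 0.65 * bumps[b]) * taper for b in bumps}
    trigger_rois = {b: _sphere_mask(shape, c, 2.0) & brain for b, c in centers.items()}
    effect_roi = (
        np.asarray(spec.effect_roi, bool)
        if spec.effect_roi is not None
        else _sphere_mask(shape, center, 0.35 * min(shape)) & brain
    )
    return brain, taper, bumps, envelopes, trigger_rois, effect_roi


def _wave_phase(
    speed_vox_per_frame: np.ndarray,
    f_hz: float,
    fs: float,
    axis: int,
    eta: np.ndarray,
) -> np.ndarray:
    """Spatial phase (in cycles) of a wave travelling along ``axis``.

    The local phase gradient along the axis is f / (fs * c) cycles/voxel
    (wavelength c * fs / f voxels); ``eta`` adds a smooth multiplicative
    ripple to the slowness so that the wavefronts are not perfectly
    planar and the flow problem is well conditioned in 3D.
    """
    slowness = (f_hz / fs) / speed_vox_per_frame * (1.0 + eta)
    return np.cumsum(slowness, axis=axis)


def _stage_track(
    spec: CohortSpec, rng: np.random.Generator, sleep: bool
) -> SleepScoreTrack:
    n_epochs = max(1, int(np.ceil(spec.duration_s / 30.0)))
    probs = SLEEP_STAGE_PROBS if sleep else AWAKE_STAGE_PROBS
    stages = list(probs)
    p = np.array([probs[s] for s in stages])
    labels = list(rng.choice(stages, size=n_epochs, p=p / p.sum()))
    return SleepScoreTrack(labels)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the paired awake/sleep cohort with known ground truth.

    Each subject's series is a static textured background plus three
    band-limited travelling pulsation waves (cardiac dip train with
    harmonics, respiratory and vasomotor sinusoids), each propagating
    through the brain at a known, spatially varying speed, plus white
    noise.  Awake and sleep share texture, wavefront geometry and phases;
    sleep rescales each band's wave amplitude *and* propagation speed by
    its multiplier inside the effect ROI -- amplitude and velocity rise
    and fall together, as for nonlinear pressure waves in a porous
    medium.  Ground-truth amplitude ratios sleep/awake in the effect ROI
    therefore equal the multipliers exactly, and the ground-truth speed
    maps are what dense optical flow should recover.
    """
    rng = np.random.default_rng(spec.seed)
    brain, taper, bumps, envelopes, trigger_rois, effect_roi = _cohort_geometry(spec)
    conv = (spec.voxel_size_mm / 10.0) * spec.sampling_rate_hz  # vox/frame -> cm/s
    fs = spec.sampling_rate_hz
    n = spec.n_frames
    shape = spec.grid_shape
    coeffs = _cardiac_shape_coeffs()
    roi_sm = ndimage.gaussian_filter(effect_roi.astype(np.float64), 1.0)

    cov = draw_power_covariates(spec.n_subjects, spec.delta_coupling, rng)

    subjects = []
    for sid in range(spec.n_subjects):
        f_heart = float(np.clip(rng.normal(*spec.heart_rate_hz), 0.6, 1.6))
        f_resp = float(np.clip(rng.normal(*spec.resp_rate_hz), 0.08, 0.49))
        freqs = {"cardiac": f_heart, "respiratory": f_resp,
                 "vasomotor": spec.vaso_freq_hz}
        n_harm = {"cardiac": max(2, int(np.floor(5.0 / f_heart))),
                  "respiratory": 1, "vasomotor": 1}
        texture = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5, mode="wrap")
        texture = 1.0 + spec.texture_contrast * texture / max(texture.std(), 1e-12)
        phases0 = {b: rng.uniform(0, 1) for b in freqs}
        eta = {}
        for b in freqs:
            e = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0, mode="wrap")
            eta[b] = np.clip(e * (0.06 / max(e.std(), 1e-12)), -0.2, 0.2)
        relief = {b: 0.9 + 0.2 * bumps[b] for b in freqs}
        amp_factor = {b: float(np.exp(0.15 * cov[b][sid])) for b in spec.delta_coupling}

        truth: dict[str, dict[str, float]] = {b: {} for b in freqs}
        cond_fields = {}
        for cond, sleeping in (("awake", False), ("sleep", True)):
            per_band = {}
            for band, f in freqs.items():
                m = spec.sleep_multipliers[band] if sleeping else 1.0
                # wave speed field (arbitrary units before calibration):
                # sleep rescales it inside the (smoothed) effect ROI
                c_raw = relief[band] * (1.0 + (m - 1.0) * roi_sm)
                phase = _wave_phase(c_raw, f, fs, _BAND_AXES[band], eta[band])
                grad = np.stack(np.gradient(phase), axis=-1)
                gnorm = np.linalg.norm(grad, axis=-1)
                speed_raw = (f / fs) / np.maximum(gnorm, 1e-12)  # vox/frame
                per_band[band] = {
                    "phase": phase, "grad": grad, "gnorm": gnorm,
                    "speed_raw": speed_raw, "m": m,
                }
            cond_fields[cond] = per_band

        # calibrate each band on the awake state so the awake whole-brain
        # mean ground-truth speed equals the configured target; the same
        # factor applies to sleep, preserving the multiplier ratios
        alpha = {}
        for band in freqs:
            awake_speed = cond_fields["awake"][band]["speed_raw"]
            target_vox = spec.mean_speed_cm_s[band] / conv
            alpha[band] = awake_speed[brain].mean() / target_vox

        cond_data = {}
        for cond, sleeping in (("awake", False), ("sleep", True)):
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, sid, int(sleeping), 7])
            )
            waves = np.zeros((n,) + shape, dtype=np.float64)
            t_frames = np.arange(n) / fs
            for band, f in freqs.items():
                pb = cond_fields[cond][band]
                phase = pb["phase"] * alpha[band]
                speed_vox = pb["speed_raw"] / alpha[band]
                direction = pb["grad"] / np.maximum(pb["gnorm"], 1e-12)[..., None]
                amp = (
                    _BAND_BASE_AMP[band]
                    * envelopes[band]
                    * amp_factor.get(band, 1.0)
                )
                if sleeping:
                    mb = spec.sleep_multipliers[band]
                    amp = amp * (1.0 + (mb - 1.0) * effect_roi)
                # precompute complex carriers so each frame is a scalar
                # phasor multiply: wave = sum_k 2 Re[C_k(x) e^{-2 pi i k f t}]
                for k in range(1, n_harm[band] + 1):
                    ck = coeffs[k] if band == "cardiac" else (
                        -0.5j if k == 1 else 0.0
                    )
                    if ck == 0.0:
                        continue
                    carrier = amp * np.exp(
                        2j * np.pi * k * (phase + phases0[band])
                    ) * ck
                    phasor = np.exp(-2j * np.pi * k * f * t_frames)
                    waves += 2.0 * (
                        carrier[None].real * phasor[:, None, None, None].real
                        - carrier[None].imag * phasor[:, None, None, None].imag
                    )
                speed_cm = speed_vox * conv
                truth[band][f"{cond}_mean_speed_cm_s"] = float(speed_cm[brain].mean())
                truth[band][f"{cond}_roi_mean_speed_cm_s"] = float(
                    speed_cm[effect_roi].mean()
                )
                truth[band][f"{cond}_mean_amplitude"] = float(amp[brain].mean())
                truth[band][f"{cond}_roi_mean_amplitude"] = float(
                    amp[effect_roi].mean()
                )
                if band == "cardiac":
                    roi = trigger_rois[band]
                    theta0 = float((phase + phases0[band])[roi].mean())
                    trace_card = _eval_harmonics(
                        theta0 - f * t_frames, coeffs, n_harm[band]
                    )
                    trace_card /= max(np.abs(trace_card).max(), 1e-12)
                if band == "respiratory":
                    roi = trigger_rois[band]
                    theta0 = float((phase + phases0[band])[roi].mean())
                    trace_resp = np.sin(2 * np.pi * (theta0 - f * t_frames))

            data = texture[None] + waves
            data[:, ~brain] = 0.2
            if spec.noise_sd > 0:
                data = data + noise_rng.normal(0, spec.noise_sd, data.shape)
            series = VolumeSeries(
                data.astype(np.float32), fs, spec.voxel_size_mm
            )
            delta = float(cov["log_delta"][sid]) * 0.5 + (0.5 if sleeping else 0.0)
            cond_data[cond] = ConditionData(
                series,
                trace_card + noise_rng.normal(0, 0.02, n),
                trace_resp + noise_rng.normal(0, 0.02, n),
                _stage_track(spec, noise_rng, sleeping),
                delta,
            )

        subjects.append(
            CohortSubject(
                sid,
                f_heart,
                f_resp,
                cond_data["awake"],
                cond_data["sleep"],
                {b: float(cov[b][sid]) for b in spec.delta_coupling},
                truth,
            )
        )
    return Cohort(spec, subjects, brain, effect_roi, trigger_rois)
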