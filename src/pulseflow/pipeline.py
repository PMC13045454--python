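"""Stage-wise analysis pipeline: band separation -> optical flow ->
cycle-locked averaging -> group statistics.

Each stage reads its inputs from, and writes its outputs to, the run's
output directory, so the stages compose through the filesystem and the
CLI subcommands (simulate, power, flow, cycles, stats, all) produce the
same artifacts as :func:`run_pipeline`.  A JSON manifest with SHA-256
checksums lists every artifact; a log records band ranges, trigger
counts, excluded cycles and the permutation seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .cycles import (
    PulseCycleAverage,
    cycle_speed_profile,
    detect_triggers,
    directional_stats,
    resample_cycles,
)
from .flow import (
    FlowParams,
    VelocityField,
    decompose_velocity,
    pyramidal_flow,
    sparse_extremum_flow,
    to_physical_velocity,
)
from .spectral import BandDefinition, VolumeSeries, band_power_map, bandpass_filter, periodogram_map
from .stats import (
    directional_reversal_map,
    paired_permutation_test,
    power_delta_regression,
    spatial_correlation,
)
from .synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

__all__ = ["run_pipeline", "STAGES", "run_stage"]

log = logging.getLogger("pulseflow")


def _band_defs(cfg: RunConfig) -> dict[str, BandDefinition]:
    return {
        name: BandDefinition(name, b.f_low, b.f_high) for name, b in cfg.bands.items()
    }


def _max_depth(grid_shape: tuple[int, ...], requested: int) -> int:
    depth = 0
    size = min(grid_shape)
    while depth < requested and size // 2 >= 8:
        size //= 2
        depth += 1
    return depth


def _series_units(cfg: RunConfig) -> list[tuple[str, Path]]:
    """(label, path) pairs of every series the run analyses."""
    root = Path(cfg.output_dir)
    if cfg.mode == "phantom":
        return [("phantom", root / "sim" / "phantom.nii.gz")]
    pairs = []
    for sdir in sorted((root / "sim").glob("sub-*")):
        for cond in ("awake", "sleep"):
            pairs.append((f"{sdir.name}_{cond}", sdir / f"{cond}.nii.gz"))
    return pairs


def stage_simulate(cfg: RunConfig) -> None:
    root = Path(cfg.output_dir)
    sim = root / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    if cfg.mode == "phantom":
        if cfg.input_series is not None:
            return  # real input provided; nothing to simulate
        s = cfg.simulation
        spec = PhantomSpec(
            grid_shape=tuple(s.grid_shape),
            duration_s=s.duration_s,
            pulse_freq_hz=s.pulse_freq_hz,
            peak_velocity_cm_s=s.peak_velocity_cm_s,
            noise_sd=s.noise_sd,
            seed=cfg.seed,
        )
        series, truth = generate_phantom(spec)
        pio.write_volume_series(series, sim / "phantom.nii.gz")
        pio.write_mask(truth.flow_mask, sim / "flow_mask.nii.gz")
        meta = {
            "peak_velocity_cm_s": truth.peak_velocity_cm_s,
            "pulse_freq_hz": truth.pulse_freq_hz,
            "peak_displacement_vox": truth.peak_displacement_vox,
        }
        (sim / "ground_truth.json").write_text(json.dumps(meta, indent=2))
        log.info("simulated phantom %s", meta)
    else:
        s = cfg.simulation
        spec = CohortSpec(
            n_subjects=s.n_subjects,
            grid_shape=tuple(s.grid_shape),
            duration_s=s.duration_s,
            noise_sd=s.noise_sd,
            seed=cfg.seed,
        )
        cohort = generate_cohort(spec)
        pio.write_mask(cohort.brain_mask, sim / "brain_mask.nii.gz")
        pio.write_mask(cohort.effect_roi, sim / "effect_roi.nii.gz")
        for band, roi in cohort.trigger_rois.items():
            pio.write_mask(roi, sim / f"trigger_{band}.nii.gz")
        rows = []
        for sub in cohort.subjects:
            sdir = sim / f"sub-{sub.subject_id:02d}"
            sdir.mkdir(exist_ok=True)
            for cond in ("awake", "sleep"):
                data = getattr(sub, cond)
                fs = data.series.sampling_rate_hz
                pio.write_volume_series(data.series, sdir / f"{cond}.nii.gz")
                pio.write_trace(data.cardiac_trace, fs, sdir / f"{cond}_cardiac.csv")
                pio.write_trace(data.resp_trace, fs, sdir / f"{cond}_resp.csv")
                pio.write_hypnogram(data.hypnogram, sdir / f"{cond}_hypnogram.csv")
                rows.append(
                    {
                        "subject": sub.subject_id,
                        "condition": cond,
                        "heart_rate_hz": sub.heart_rate_hz,
                        "resp_rate_hz": sub.resp_rate_hz,
                        "slow_delta_log_power": data.slow_delta_log_power,
                        **{
                            f"{b}_truth_mean_speed_cm_s": v[f"{cond}_mean_speed_cm_s"]
                            for b, v in sub.truth.items()
                        },
                    }
                )
        pd.DataFrame(rows).to_csv(sim / "subjects.csv", index=False)
        log.info("simulated cohort of %d subjects", len(cohort))


def stage_power(cfg: RunConfig) -> None:
    root = Path(cfg.output_dir)
    out = root / "power"
    out.mkdir(parents=True, exist_ok=True)
    bands = _band_defs(cfg)
    for label, path in _series_units(cfg):
        series = pio.read_volume_series(path)
        n_bins = max(cfg.n_spectrum_bins, 1 << int(np.ceil(np.log2(series.n_frames))))
        spec = periodogram_map(series, n_bins)
        for name, band in bands.items():
            bp = band_power_map(spec, band)
            pio.write_mask(
                bp.astype(np.float32), out / f"{label}_{name}_power.nii.gz",
                series.voxel_size_mm,
            )
        log.info("power maps for %s (%d bins)", label, n_bins)


def stage_flow(cfg: RunConfig) -> None:
    root = Path(cfg.output_dir)
    out = root / "flow"
    out.mkdir(parents=True, exist_ok=True)
    bands = _band_defs(cfg)
    for label, path in _series_units(cfg):
        series = pio.read_volume_series(path)
        for name, band in bands.items():
            filtered = bandpass_filter(series, band)
            depth = _max_depth(series.grid_shape, cfg.flow.pyramid_depth.get(name, 0))
            if depth != cfg.flow.pyramid_depth.get(name, 0):
                log.info(
                    "%s/%s: pyramid depth clamped to %d for grid %s",
                    label, name, depth, series.grid_shape,
                )
            params = FlowParams(
                window_radius=cfg.flow.window_radius,
                pyramid_depth=depth,
                band_name=name,
                conditioning_threshold=cfg.flow.conditioning_threshold,
                n_iter=cfg.flow.n_iter,
                ridge=cfg.flow.ridge,
            )
            field = to_physical_velocity(
                pyramidal_flow(filtered, params),
                series.voxel_size_mm,
                series.sampling_rate_hz,
            )
            pio.write_velocity_field(
                field, out / f"{label}_{name}_velocity.nii.gz", series.voxel_size_mm
            )
        if cfg.mode == "phantom":
            sparse = sparse_extremum_flow(bandpass_filter(series, bands["cardiac" if "cardiac" in bands else next(iter(bands))]), "min")
            sparse = to_physical_velocity(
                sparse, series.voxel_size_mm, series.sampling_rate_hz
            )
            pio.write_velocity_field(
                sparse, out / f"{label}_sparse_velocity.nii.gz", series.voxel_size_mm
            )
        log.info("flow fields for %s", label)


def stage_cycles(cfg: RunConfig) -> None:
    root = Path(cfg.output_dir)
    out = root / "cycles"
    out.mkdir(parents=True, exist_ok=True)
    bands = _band_defs(cfg)
    sim = root / "sim"
    profiles = []
    for label, path in _series_units(cfg):
        series = pio.read_volume_series(path)
        fs = series.sampling_rate_hz
        for name, band in bands.items():
            field = pio.read_velocity_field(
                root / "flow" / f"{label}_{name}_velocity.nii.gz"
            )
            roi_path = sim / f"trigger_{name}.nii.gz"
            if roi_path.exists():
                roi = pio.read_mask(roi_path).astype(bool)
            else:  # phantom: trigger from the flow-mask region
                roi = pio.read_mask(sim / "flow_mask.nii.gz").astype(bool)
            filtered = bandpass_filter(series, band)
            sig = filtered.data[:, roi].mean(axis=1)
            triggers = detect_triggers(sig, band, fs)
            target = cfg.cycle_frames(name, fs)
            cyc = resample_cycles(field, triggers, target)
            log.info(
                "%s/%s: %d triggers, %d cycles averaged, %d excluded",
                label, name, len(triggers), cyc.n_cycles_averaged,
                cyc.n_cycles_excluded,
            )
            np.save(out / f"{label}_{name}_cycle.npy", cyc.frames)
            curve, n_max = cycle_speed_profile(cyc, roi)
            for i, v in enumerate(curve):
                profiles.append(
                    {"series": label, "band": name, "frame": i,
                     "mean_speed": v, "n_maxima": n_max,
                     "n_cycles": cyc.n_cycles_averaged}
                )
            _, direction = decompose_velocity(
                VelocityField(cyc.frames, np.ones(cyc.frames.shape[:-1], bool),
                              cyc.units, name)
            )
            stats = directional_stats(direction)
            pio.write_mask(
                np.nan_to_num(stats.angular_std_rad).astype(np.float32),
                out / f"{label}_{name}_angular_std.nii.gz",
                series.voxel_size_mm,
            )
            np.save(out / f"{label}_{name}_mean_direction.npy", stats.mean_direction)
    pd.DataFrame(profiles).to_csv(out / "cycle_profiles.csv", index=False)


def stage_stats(cfg: RunConfig) -> None:
    if cfg.mode != "cohort":
        return
    root = Path(cfg.output_dir)
    out = root / "stats"
    out.mkdir(parents=True, exist_ok=True)
    bands = _band_defs(cfg)
    sim = root / "sim"
    brain = pio.read_mask(sim / "brain_mask.nii.gz").astype(bool)
    subjects = sorted({p.name for p in sim.glob("sub-*")})
    df = pd.read_csv(sim / "subjects.csv")
    sc = cfg.stats
    tfce_kwargs = {"h_power": sc.tfce_h, "e_power": sc.tfce_e}
    summary = []
    for name in bands:
        # per-frame paired speed test over the cycle grid
        cycles = {
            cond: np.stack(
                [
                    np.load(root / "cycles" / f"{sub}_{cond}_{name}_cycle.npy")
                    for sub in subjects
                ]
            )
            for cond in ("awake", "sleep")
        }
        speed = {c: np.linalg.norm(v, axis=-1) for c, v in cycles.items()}
        n_frames = speed["awake"].shape[1]
        sig_frames = np.zeros((n_frames,) + brain.shape, dtype=bool)
        for t in range(n_frames):
            res = paired_permutation_test(
                speed["sleep"][:, t], speed["awake"][:, t],
                n_perm=sc.n_perm, alpha=sc.alpha, use_tfce=sc.use_tfce,
                seed=cfg.seed + t, tfce_kwargs=tfce_kwargs,
            )
            sig_frames[t] = res.sig_mask
        np.save(out / f"{name}_sig_frames.npy", sig_frames)
        pio.write_mask(
            sig_frames.any(axis=0), out / f"{name}_sig_any_frame.nii.gz"
        )

        # directional reversal on whole-cycle mean directions
        dirs = {
            cond: np.stack(
                [
                    np.load(root / "cycles" / f"{sub}_{cond}_{name}_mean_direction.npy")
                    for sub in subjects
                ]
            )
            for cond in ("awake", "sleep")
        }
        rev = directional_reversal_map(
            dirs["awake"], dirs["sleep"], n_perm=sc.n_perm, alpha=sc.alpha,
            use_tfce=sc.use_tfce, seed=cfg.seed, tfce_kwargs=tfce_kwargs,
        )
        pio.write_mask(rev.reversal, out / f"{name}_reversal.nii.gz")

        # power change vs velocity change spatial correlation
        power = {
            cond: np.stack(
                [
                    np.asarray(
                        pio.read_mask(
                            root / "power" / f"{sub}_{cond}_{name}_power.nii.gz"
                        ),
                        dtype=np.float64,
                    )
                    for sub in subjects
                ]
            )
            for cond in ("awake", "sleep")
        }
        dpower = np.log(np.maximum(power["sleep"], 1e-30)).mean(axis=0) - np.log(
            np.maximum(power["awake"], 1e-30)
        ).mean(axis=0)
        dspeed = speed["sleep"].mean(axis=(0, 1)) - speed["awake"].mean(axis=(0, 1))
        r_pv = spatial_correlation(dpower, dspeed, brain)

        # subject log band power vs slow-delta EEG power (sleep state)
        band_power = np.stack(
            [power["sleep"][i][brain].sum() for i in range(len(subjects))]
        )
        delta = df[df.condition == "sleep"].sort_values("subject")[
            "slow_delta_log_power"
        ].to_numpy()
        try:
            r_delta, slope, excluded = power_delta_regression(
                np.log(band_power), delta, sc.sigma_threshold
            )
        except ValueError:
            r_delta, slope, excluded = np.nan, np.nan, []
        summary.append(
            {
                "band": name,
                "n_sig_voxels_any_frame": int(sig_frames.any(axis=0).sum()),
                "n_reversal_voxels": int(rev.reversal.sum()),
                "power_velocity_r": r_pv,
                "delta_power_r": r_delta,
                "delta_power_slope": slope,
                "n_delta_outliers": len(excluded),
            }
        )
        log.info("stats for band %s: %s", name, summary[-1])
    pd.DataFrame(summary).to_csv(out / "group_summary.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "power": stage_power,
    "flow": stage_flow,
    "cycles": stage_cycles,
    "stats": stage_stats,
}


def run_stage(cfg: RunConfig, stage: str) -> None:
    try:
        STAGES[stage](cfg)
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; choose from {list(STAGES)}")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order and write the artifact manifest."""
    root = Path(cfg.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(root / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    try:
        log.info(
            "run: mode=%s seed=%d bands=%s",
            cfg.mode, cfg.seed,
            {k: (v.f_low, v.f_high) for k, v in cfg.bands.items()},
        )
        for stage in STAGES:
            run_stage(cfg, stage)
    finally:
        log.removeHandler(handler)
        handler.close()
    return pio.write_manifest(root, {"seed": cfg.seed, "mode": cfg.mode})
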