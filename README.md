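# pulseflow

Velocity mapping of physiological brain pulsations from ultrafast (10 Hz)
volumetric MRI, with a fully synthetic validation bench.

Three rhythms drive cerebrospinal/interstitial fluid motion in the human
brain: cardiovascular pulsations (~1 Hz), respiratory pulsations
(~0.3 Hz) and very-low-frequency vasomotor waves (< 0.1 Hz).  Sampled at
10 Hz (TR = 100 ms, 3 mm cubic voxels), whole-brain T2\*-weighted series
resolve all three without aliasing.  `pulseflow` quantifies, per band,
the 3D velocity of the travelling signal pattern

```
V = vs_x i + vs_y j + vs_z k = v_s * v_hat ,
```

where `v_s = |V|` is the speed and `v_hat = V/|V|` the unit direction,
using dense 3D Lucas–Kanade optical flow with coarse-to-fine pyramids
(depth 3 for cardiac, 1 for respiratory, 0 for vasomotor).  Around that
core it implements the full study workflow:

* **spectral** — voxel-wise periodograms (4096-bin convention: 2048
  one-sided bins over 0–5 Hz), summed band power maps, zero-phase
  Butterworth band separation (cardiac 0.51–5 Hz, respiratory
  0.08–0.49 Hz, vasomotor 0.01–0.08 Hz), aliasing arithmetic, and
  group band-edge derivation from physiological traces;
* **flow** — dense pyramidal and sparse feature-tracking 3D optical
  flow, unit conversion (1 voxel/frame = 3 cm/s at 3 mm / 10 Hz), and
  speed/direction decomposition;
* **cycles** — trigger detection from ROI signals (systolic-dip minima),
  resampling of every pulse cycle to a fixed grid (0.9 s / 6 s / 20 s =
  9 / 60 / 200 frames), cycle-averaged velocity maps, speed profiles and
  circular direction statistics;
* **stats** — paired sign-flip permutation tests with TFCE and
  max-statistic FWER control (defaults n = 5000, p < 0.05), directional
  reversal maps from component-wise positive/negative contrasts,
  power-velocity spatial correlation, and log band power vs log
  slow-delta EEG power regression with a 4-sigma Chebyshev outlier rule;
* **synthetic** — a pulsatile porous-medium phantom (streaked fruit
  texture, impermeable rind, peristaltic pump inflow with known peak
  velocity) and a paired awake/sleep cohort with known per-band effect
  sizes (cardiac ×0.78, respiratory ×1.29, vasomotor ×1.21 during sleep)
  and a slow-delta power covariate with prescribed coupling signs.

Everything runs end to end on the synthetic data; no scanner data is
required anywhere in the test suite.

## Worked example

Generate the pulsatile phantom, run dense and sparse optical flow, and
compare recovered peak speeds against the known ground truth:

```python
import numpy as np
from pulseflow import (
    PhantomSpec, generate_phantom, phantom_bore_roi,
    FlowParams, pyramidal_flow, sparse_extremum_flow, to_physical_velocity,
)

spec = PhantomSpec(seed=1)          # 32^3 voxels, 60 s at 10 Hz, 22 cm/s peak
series, truth = generate_phantom(spec)
roi = phantom_bore_roi(spec)        # cross-section just inside the inflow bore

field = pyramidal_flow(series, FlowParams(window_radius=2, pyramid_depth=2,
                                          n_iter=3, ridge=0.01))
dense = to_physical_velocity(field, spec.voxel_size_mm, spec.sampling_rate_hz)
print("dense peak speed:", round(float(dense.speed.max(axis=0)[roi].mean()), 2))

sparse = sparse_extremum_flow(series, "min", roi=roi, prominence_sd=1.0)
sp = to_physical_velocity(sparse, spec.voxel_size_mm, spec.sampling_rate_hz)
per_frame = sp.speed.max(axis=(1, 2, 3))
print("sparse peak speed:", round(float(per_frame[:595].reshape(-1, 5).max(axis=1).mean()), 2))
```

prints

```
dense peak speed: 24.29
sparse peak speed: 12.84
```

against the true 22 cm/s: the dense estimate lands within 15% (slightly
high, because a per-voxel temporal maximum is an upward-biased peak
estimator), while the sparse tracker follows a single signal nadir and
underestimates the peak by roughly a factor of two — the same accuracy
ordering seen when both are compared against Doppler ultrasound in a
physical phantom.

The same pipeline runs from the shell; stage subcommands compose to the
identical result as one `all` run:

```bash
pulseflow all --config examples/phantom.yaml --seed 3 --output-dir out/phantom
```

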