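# Methods

This note documents the models, estimators and numerical choices behind
`pulseflow`, and what the synthetic validation bench does and does not
establish about real data.

## Signal model and band separation

The input is a 4D series sampled at 10 Hz with 3 mm cubic voxels.  At
this rate the three physiological pulsation bands are resolved without
mutual aliasing; content above the 5 Hz Nyquist frequency folds back as
`alias(f, fs) = |f - fs*round(f/fs)|` (e.g. a 5.7 Hz pump pulsation
appears at 4.3 Hz).  Band separation uses a 4th-order Butterworth filter
applied forward and backward (`sosfiltfilt`, reflective padding), chosen
for sharp band edges at 10 Hz sampling with exactly zero group delay —
phase matters because velocity timing within the pulse cycle is an
endpoint.  The cardiac band (0.51–5 Hz) reaches Nyquist and is realised
as a high-pass, which keeps the harmonics that give the cardiac
waveform its sharp systolic dip.  Filtering twice changes in-band
amplitude by well under 5% (passband ripple of the squared Butterworth
response).

Voxel-wise spectra are plain zero-padded periodograms.  The per-voxel
temporal mean is removed before padding — otherwise the pad step turns
the DC level into spurious 1/f²-like leakage across the lowest bins —
and is reported separately as DC power.  One-sided bins sit at
`k*fs/n_bins`, `k = 1..n_bins/2`, so the default 4096 bins give 2048
bins covering 0–5 Hz.  Two normalizations are exposed: `"parseval"`
(two-sided sum equals the time-domain sum of squares; the default) and
`"mean_square"` (sum equals the signal variance for zero-mean input).
Band power is the sum over bins inside the closed band interval.

## Dense 3D Lucas–Kanade flow

Per voxel, the brightness-constancy constraint `Ix u + Iy v + Iz w =
-It` is solved by weighted least squares over a (2r+1)³ window (default
r = 2) with Gaussian weights (σ = r/1.5).  Spatial gradients are central
differences of the two-frame average; the temporal gradient is the
forward difference; volumes are reflect-padded so output matches input
shape.  A voxel is flagged invalid when the smallest structure-tensor
eigenvalue falls below 1e-4 of its trace (aperture problem) or when the
local gradient energy is below 1e-9 of the volume maximum (numerically
flat signal); invalid voxels carry zero velocity.  An optional Tikhonov
ridge (`ridge * trace` added to the tensor diagonal; 0.01 in the
pipeline defaults) shrinks the unconstrained component at
aperture-limited voxels instead of amplifying it.

Large displacements use a coarse-to-fine pyramid: Gaussian anti-aliased
halving per level, flow estimated at the coarsest level, upsampled with
values doubled, used to warp the next level, and refined; `n_iter`
warp-and-refine iterations run per level with each residual clamped to
the window radius (the linearization is meaningless beyond it).  With
depth 0 and `n_iter = 1` this reduces exactly to the single-level solve.
Band defaults follow the acquisition logic — depth 3 for cardiac (up to
several voxels/frame), 1 for respiratory, 0 for vasomotor — and every
pyramid level must keep at least 8 voxels per axis, so a 32³ grid admits
at most depth 2.

Sparse flow tracks a single intensity extremum (e.g. the pulse signal
nadir): per frame the extremum is located (search confined to a few
voxels around the previous position for feature continuity), refined to
sub-voxel precision by per-axis parabolic interpolation (offset clipped
to ±0.5 voxel), and differenced.  Velocities exist only along the track.

Unit conversion: `v[cm/s] = v[voxel/frame] * (voxel_mm/10) * fs`, so one
voxel/frame is 3 cm/s at 3 mm / 10 Hz.  Decomposition returns
`v_s = |V| >= 0` and `v_hat = V/|V|`, with the direction undefined (NaN)
where the speed is below 1e-12 or the solve was invalid.

## Cycle-locked analysis

Triggers are minima of the band-passed mean signal of a band-specific
ROI (anterior-cerebral-artery-like for cardiac, 4th-ventricle-like for
respiratory, posterior-cingulate-like for vasomotor), with prominence at
least 0.5 signal SD and separation at least 0.5/f_high seconds.  Minima
are used for all bands (the cardiac trigger is the fast systolic dip);
zero-crossing triggering can be substituted by pre-processing the
signal.  Each trigger-to-trigger cycle (closed-open) is linearly
interpolated to the band's fixed grid — 0.9 s / 6 s / 20 s, i.e. 9 / 60 /
200 frames at 10 Hz — and averaged voxel-wise.  Cycles shorter than 0.4×
or longer than 2.5× the median inter-trigger interval are excluded and
counted (guards against missed or spurious triggers; the bounds are
deliberately loose so physiological variability is retained).

Cycle speed profiles are ROI means per cycle frame; maxima are counted
on the circularly extended curve after a 3-frame moving mean.  Direction
stability is summarized per voxel by the mean resultant vector R of the
unit directions over the cycle: `angular_std = sqrt(2(1-|R|))` (chord
metric; 0 for aligned, sqrt(2) for antipodal), with `sqrt(-2 ln |R|)`
selectable.  The statistics are invariant under global rotations.

## Group statistics

The paired awake/sleep design is tested with a one-sample sign-flip
permutation test on subject difference maps: voxel statistic = paired t,
optionally TFCE-enhanced, with family-wise error control from the
permutation distribution of the map-wide maximum.  All 2^n sign flips
are enumerated when that is no more than the requested permutation
count; otherwise flips are sampled with the (1+k)/(N+1) p-value
estimator.  Two-sided testing runs the positive and negative contrasts
separately against a shared max-null (so the overall FWER stays at
alpha); empirical calibration over 500 null simulations gives FWER
0.044 at alpha 0.05.  TFCE uses the field-standard H = 2, E = 0.5,
dh = max/100, 26-connectivity; negative maps must be split by the caller.

Directional reversals: each Cartesian component of the per-subject mean
direction maps is split into positive and negative parts; a voxel
reverses along a component when the positive part significantly
decreases while the negative part significantly increases between
states (or vice versa); component maps combine by union (intersection
selectable).  Power–velocity coupling is a Pearson correlation over
in-mask voxels.  The slow-delta analysis regresses log band power on
log slow-delta EEG power after excluding subjects more than 4 SD from
the mean in either coordinate (Chebyshev-justified outlier rule).

Per-cycle-frame testing applies no correction across the 9/60/200
frames, matching the per-frame reporting convention of the workflow this
package reimplements; an across-frame max-statistic mode can be obtained
by stacking frames into one map.

## Synthetic phantom

The phantom emulates a porous fruit perfused through a central bore by a
peristaltic pump: a ×4-supersampled master texture (radial streaks,
angular spokes, axial striations across three octaves, plus smooth
noise) inside an ellipsoidal fruit with an impermeable ~2-voxel rind.
The true displacement field is separable — a fixed spatial pattern
(axial Gaussian core of width bore radius + 1.5 voxels plus a radially
outward component, tapered to zero at the rind) times a sinusoid at the
pump frequency — and is rescaled so its peak, converted to cm/s, equals
the requested peak velocity exactly.  Frames are produced
semi-Lagrangially by sampling the master texture at displaced positions,
which conserves total intensity to well under 1% across frames.  The
three-octave axial striation is deliberate: axial bulk motion is only
visible to optical flow if intensity varies along the bore axis, and
coarse pyramid levels only retain wavelengths that survive repeated
halving.

The pump waveform is a raised-cosine pulse train (duty 0.5) at
`rotation_fraction × 20.1 Hz` — three rotor heads give three pulses per
revolution, so the pulse rate scales with rotation speed — sampled at
the scanner rate so supra-Nyquist stages alias exactly as acquired data
would.

Peak-speed estimators mirror a cross-sectional measurement protocol:
dense = mean over a bore-adjacent cross-sectional slab of each voxel's
temporal maximum speed; sparse = mean over pump cycles of the tracked
feature's per-cycle maximum.  On the default phantom (32³, 600 frames,
22 cm/s at 2 Hz) dense recovers ≈ 24 cm/s (+10%, upward-biased because a
temporal maximum of a noisy estimate overshoots) and sparse ≈ 13 cm/s
(−40%, a single tracked nadir misses the fastest voxels) — the same
ordering as dense/sparse flow against Doppler ultrasound.

## Synthetic cohort

Each subject's series is a static textured "brain" (ellipsoid, smooth
random texture) plus three band-limited travelling pulsation waves and
white noise.  Per band, the wave is `A_b(x) * w_b(phase_b(x) - f_b t)`:
a cardiac waveform synthesized from the Fourier harmonics of a periodic
systolic dip (truncated below 5 Hz, so the shape is realistic and
alias-free), and respiratory/vasomotor sinusoids.  The spatial phase
accumulates slowness `f/(fs*c(x))` along a band-specific propagation
axis, with a smooth multiplicative ripple so wavefronts are not planar
and the flow problem is conditioned in 3D; the ground-truth velocity
field is `(f/fs) * grad(phase)/|grad(phase)|²`, i.e. exactly the phase
velocity a perfect flow estimator would read.  A global phase rescale
calibrates the awake whole-brain mean ground-truth speed to the
configured targets (3.27 / 0.26 / 0.058 cm/s), which sit at the scale of
in-vivo group means.

An early design advected a static texture by a separable oscillatory
displacement field.  That model was rejected after direct measurement:
band-passing such data leaves a *standing* intensity pattern whose
apparent Lucas–Kanade velocity is independent of the displacement
amplitude, so no analysis could recover amplitude ratios from it even in
principle.  Travelling waves are also the physically appropriate model:
what optical flow measures in narrowband data is the propagation of the
pulse pattern.  Consistent with the nonlinear porous-medium picture in
which wave amplitude and speed rise and fall together, the sleep
condition scales each band's wave amplitude *and* propagation speed by
its multiplier (cardiac 0.78, respiratory 1.29, vasomotor 1.21) inside a
central effect ROI.  Amplitudes use the binary ROI (ground-truth
amplitude ratios there equal the multipliers exactly); the speed field
uses a 1-voxel-smoothed ROI so the phase stays integrable, making the
ground-truth speed ratio exact in the ROI interior and blended over a
thin edge shell.  Awake and sleep share texture, wavefront geometry and
phases, so paired contrasts isolate the condition effect.

Heart and breathing rates are drawn per subject from 1.02 ± 0.15 Hz and
0.27 ± 0.05 Hz; the vasomotor wave is fixed at 0.05 Hz.  Subject-level
log band power covariates are drawn from a latent slow-delta factor with
target correlations +0.5 (vasomotor) and −0.5 (cardiac) and modulate the
wave amplitudes; the slow-delta scalar itself is elevated in sleep.
Hypnograms are drawn from the stage distribution observed in selected
sleep epochs (W 10%, N1 43%, N2 43%, N3 1%, artifacts 2% — 87% NREM) in
30 s epochs.  Default cohort conditions keep the study's sample size
(n = 22) and physiological parameters; the default grid (24³) and
duration (60 s) are desk-scale choices — large enough that every band
completes multiple cycles (three vasomotor cycles) and small enough
that the full bench runs on one CPU in minutes.

## What the bench does and does not show

Recovery tests on the phantom validate the flow solver against known
bulk advection of a rich, broadband texture — the regime where optical
flow measures material motion.  The cohort tests validate band
separation, power mapping, cycle machinery and the statistics under a
known travelling-wave model.  Two quantitative limits are documented
deliberately:

* At 3 mm / 10 Hz the slow bands' wavelengths (`c*fs/f` ≈ 3 voxels for
  respiratory and vasomotor waves at in-vivo speeds) sit near the
  spatial Nyquist limit, where discrete-gradient flow carries a large
  wavelength-dependent bias; in addition, narrowband flow has an
  amplitude-independent noise floor.  Sleep/awake *speed-ratio*
  estimates from flow are therefore magnitude-unreliable for the slow
  bands, and for the vasomotor band (shortest wavelength, smallest
  effect) even the direction is cancelled by the bias, so the bench
  asserts flow-derived effect directions for the cardiac and
  respiratory bands only.  The *amplitude* multipliers of all three
  bands are recovered quantitatively (within 10%) from summed band
  power, for which `amplitude = sqrt(power)` is exact.
* The synthetic data contain none of the structured confounds of real
  recordings — head motion, scanner drift, partial-volume mixing of
  opposing flows, arousal-state changes in the waveform shape — so
  green tests establish correctness of the computation, not robustness
  to those effects.

## Numerical conventions

Voxel indices are 0-based; time is the leading axis in memory and the
4th NIfTI dimension on disk (TR in pixdim[4]; a zero TR is a hard
error, never a silent default).  Velocity components are ordered
(x, y, z) in voxel space with the affine recorded for world
interpretation; fields serialize as 5D NIfTI with a JSON sidecar for
units and band.  All generators take a single integer seed and
regenerate bit-identically; the pipeline writes a manifest of SHA-256
checksums, and a same-seed rerun is manifest-identical (the run log is
excluded from checksumming because it carries timestamps).
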