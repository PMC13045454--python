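# Pulsatile-flow phantom validation run (desk scale).
mode: phantom
output_dir: out/phantom
seed: 3
simulation:
  kind: phantom
  grid_shape: [32, 32, 32]
  duration_s: 60.0
  pulse_freq_hz: 2.0
  peak_velocity_cm_s: 22.0
bands:
  pump: {f_low: 1.2, f_high: 3.0}
cycle_seconds:
  pump: 0.5
flow:
  pyramid_depth: {pump: 2}
  n_iter: 3
  ridge: 0.01
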