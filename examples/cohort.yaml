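# Paired awake/sleep cohort run, reduced for a laptop.
# The full analysis conventions (n_perm 5000, TFCE, 22 subjects) are the
# defaults; this example scales the simulation and permutations down.
mode: cohort
output_dir: out/cohort
seed: 7
simulation:
  kind: cohort
  n_subjects: 6
  grid_shape: [16, 16, 16]
  duration_s: 60.0
stats:
  n_perm: 500
  use_tfce: false
n_spectrum_bins: 1024
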