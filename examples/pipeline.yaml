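# Full simulated run of the study design: profiling + three contrasts +
# two-marker classifier trained on discovery and scored on validation.
seed: 7
out_dir: results/example_run

simulate:
  n_assays: 377
  group_sizes: {control: 12, OSC: 14, SCCC: 18}
  de_fraction: 0.1
  effect_size_ct: 2.5
  contrasts: [[control, OSC], [control, SCCC], [OSC, SCCC]]

contrasts:
  - [control, SCCC]
  - [control, OSC]
  - [OSC, SCCC]

p_max: 0.05
min_sensitivity: 0.9

marker_discovery: {}                                  # simulate with defaults
marker_validation: {n_per_class: {OSC: 11, SCCC: 12}}
marker_directions: {miR-196b-5p: low, miR-107: high}
positive_class: OSC
negative_class: SCCC
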