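# Minimal end-to-end smoke configuration: 2 groups x 2 cases x 1 stack
# at 16x64x64 voxels -> metrics table with 4 rows.
seed: 1
log_level: WARNING
simulate:
  groups:
    - [AD, 2.0, 1.0]
    - [aged control, 1.0, 1.0]
  n_cases_per_group: 2
  n_stacks_per_case: 1
  case_cv: 0.1
  base:
    shape_zyx: [16, 64, 64]
    glial_volume_fraction: 0.15
    punctum_density: 0.06
    engulfed_fraction: 0.15
segmentation:
  channels: [Syn1, GFAP]
colocalization:
  pairs:
    - [Syn1, GFAP]
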