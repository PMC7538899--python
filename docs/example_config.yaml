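# Example run configuration for the octlayers CLI.
# All blocks are optional; omitted values fall back to the study-condition
# defaults documented in docs/methods.md.

seed: 7
out_dir: run

cohort:
  n_patients_control: 40
  n_patients_stgd: 63
  p_both_eyes: 0.45
  followup_years_range: [1.2, 8.2]
  n_visits: 2
  variance_components:
    sd_patient_intercept: 8.0
    sd_patient_slope: 0.6
    corr_patient: 0.0
    sd_eye_intercept: 3.0
    sd_eye_slope: 0.3
    corr_eye: 0.0
    sd_residual: 2.5
  grader_model:
    sd_grader: 1.5
    sd_uncorrected: 3.0

grid:
  center_radius_mm: 0.5
  inner_radius_mm: 1.5
  outer_radius_mm: 3.0
  min_coverage_fraction: 0.9

bootstrap:
  n_boot: 1999
  comparison: uncorrected
  stratify: scans_per_patient

analysis:
  alpha: 0.05
  include_laterality: false
  average_laterality: false
  source: grader_avg
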