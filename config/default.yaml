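base_seed: 20140508
n_plans: 8
offset_cm: 0.1
bank: A
sim_spacing_cm: 0.05
analysis_spacing_cm: 0.3
half_extent_cm: 13.5
penumbra_sigma_cm: 0.3
weighting: uniform
cos_power: 1.0
low_dose_cutoff_fraction: 0.1
target_match_fraction: 0.95
scan_step_percent: 0.1
scan_max_percent: 50.0
gamma_criteria:
- - 2.0
  - 2.0
- - 3.0
  - 3.0
detector: null
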