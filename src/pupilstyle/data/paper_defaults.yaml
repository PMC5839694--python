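# Default analysis configuration: every threshold and window of the
# published analysis.  Units in the field names.
experiment: main

# sample-level exclusion (strict inequalities; boundary values kept)
pupil_min_mm: 1.0
pupil_max_mm: 7.0

# phase-level exclusion
phase_min_s: 1.0
phase_max_s: 15.0
min_usable_phases: 10
gap_tolerance_s: 0.2

# epoching
analysis_rate_hz: 60.0
baseline_ms: 150.0
switch_window_s: [-1.0, 1.0]
onset_window_s: [0.0, 6.0]
attention_window_s: [1.0, 3.0]
index_mode: pre_post        # or: post

# detection task
detection_window_s: 2.0

# inference
ci_level: 0.95
bf_prior_scale: 1.0
seed: 0
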