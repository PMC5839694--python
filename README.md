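# pupilstyle

Pupillometry of perceptual style in bistable structure-from-motion viewing.

When observers watch a field of leftward-moving white dots superimposed on
rightward-moving black dots, they perceive a 3-D cylinder rotating in
depth — but the depth order is ambiguous, so perception alternates every
few seconds between "black surface in front" and "white surface in front".
Although the stimulus luminance never changes, the pupil is slightly more
dilated while the *black* surface is perceived in front. The size of this
**luminance-dependent pupil modulation** indexes how the observer
distributes attention (narrowly on the front surface vs broadly over the
whole object), and it co-varies with autistic traits measured by the
Autism-Spectrum Quotient (AQ-50).

`pupilstyle` implements the complete analysis chain for this paradigm,
for pupillometry researchers who want to apply or scrutinize it:

- **Preprocessing** — masking of implausible pupil samples (outside
  1–7 mm: blinks, eyelash interference), segmentation of continuous
  percept reports into phases, exclusion of phases < 1 s or > 15 s, and of
  subjects with fewer than 10 usable phases.
- **Epoching and indices** — switch-locked epochs with 150-ms own-side
  baselines; the luminance-dependent modulation (difference of
  black-front vs white-front traces over the [−1, 0] and [0, 1] s
  windows), the general post-switch dilation ([0, 1] s, both percepts
  pooled), onset-locked cued-attention epochs ([1, 3] s window), and
  switch rates.
- **Detection scoring** — hits (presses within 2 s of a speed increment),
  false alarms, and d′ = z(H) − z(F) split by perceived front/rear
  surface; cued counting-task scoring.
- **AQ-50 scoring** — standard binary scoring into the total and five
  10-item subscales, corrected totals, Jarque–Bera normality checks
  (asymptotic and Monte-Carlo p-values).
- **Inference** — Pearson correlations with Fisher-z 95% CIs and t-based
  p-values, the JZS (Zellner–Siow) default Bayes factor for correlations
  by numerical integration, Fisher-Z comparison of independent
  correlations, paired t-tests, subscale correlation matrices, quartile
  summaries.
- **A calibrated synthetic-cohort generator** — AQ scores
  ~ Normal(14.85, 6.73); gamma-renewal percept phases (mean 5.5 s);
  pupil traces with a switch-locked gamma-kernel transient, a
  percept-dependent modulation whose amplitude is linear in AQ
  (0.002 mm per AQ point, residual SD 0.01373 mm, population r = 0.70),
  Ornstein–Uhlenbeck noise, and sub-1-mm blink dropouts — so every stage
  of the pipeline can be validated against ground truth without any data
  download.

## Worked example

Simulate a 20-subject cohort and run the full analysis:

```bash
pupilstyle simulate --n-subjects 20 --seed 7 --out demo/
pupilstyle analyze demo/ --out demo_results/
```

which prints (abridged):

```json
{
 "n_subjects": 20,
 "n_excluded": 0,
 "mean_switch_rate_hz": 0.179,
 "mean_fraction_phases_excluded": 0.226,
 "aq_vs_luminance_modulation": {
  "r": 0.882, "ci_low": 0.721, "ci_high": 0.953,
  "p": 2.7e-07, "bf10": 73712.4
 },
 "aq_vs_general_dilation": {
  "r": 0.054, "ci_low": -0.398, "ci_high": 0.485,
  "p": 0.820, "bf10": 0.175
 }
}
```

Reading this: subjects switch percepts about every 5.5 s (rate ≈ 0.18/s);
roughly a quarter of phases fail the 1–15 s / trial-boundary rules; the
luminance-dependent modulation correlates strongly with AQ (r = 0.88 here,
with BF10 ≫ 3 — decisive evidence), while the general switch-locked
dilation does not (BF10 < 1/3 — evidence for the null), exactly the
dissociation the index is designed to expose. `demo_results/` also
contains per-subject summaries (`subject_summary.csv`), grand-average
traces (`mean_traces.tsv`) and a reproducibility manifest.

The same analysis runs on real data: provide `samples.tsv` (subject,
trial, t_s, pupil_mm, gaze), `percepts.tsv` (key-state stream),
`aq_responses.csv` (items coded 1–4), and optionally `events.tsv` /
`presses.tsv` for the detection task. All thresholds live in a YAML config
(`pupilstyle.config.paper_defaults()`).

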