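# Methods

This note documents the models, conventions and numerical choices behind
`pupilstyle`, in the order data flow through the pipeline.

## Percept reports and phase segmentation

Continuous reports arrive as a key-state stream (which of two keys is held
at each sample). Maximal constant-state runs become perceptual phases;
the switch time is the report-device change time, with no reaction-time
correction. Release gaps shorter than a tolerance (default 0.2 s,
configurable) at a key change are treated as device debounce: the switch
is placed at the new key's onset and the preceding phase extends to it.
Longer gaps censor both flanking phases.

Phases are unusable when shorter than 1 s or longer than 15 s (strict
inequalities: a phase of exactly 1 s or 15 s is kept, mirroring the
"less than / longer than" wording of the exclusion rules), and when
censored by a trial boundary or a long gap — their duration is unknown,
so they can neither be length-filtered nor epoch-labeled safely. Subjects
with fewer than 10 usable phases are excluded. Pupil samples outside
[1, 7] mm (again strict) or non-finite are masked invalid.

## Epoching and baselines

Recordings (60 Hz or 1 kHz) are sampled onto a 60-Hz analysis grid by
linear interpolation; an interpolated point is valid only if both
bracketing source samples are valid. Each genuine switch contributes two
half-epochs: the *pre* side ([−1, 0) s) belongs to — and is labeled by —
the phase ending at the switch, the *post* side ([0, 1) s) by the phase
beginning there. Each side is baseline-corrected by the mean pupil in the
150 ms adjacent to the switch on its own side; a baseline window with
fewer than 50% valid samples drops that half-epoch with a logged reason.
Because usable phases last at least 1 s, a 1-s window never extends beyond
its labeling phase, so windows cannot straddle excluded phases.

Indices (per subject, label means first):

- **Luminance-dependent modulation** (mm): black-front minus white-front
  trace difference, averaged over the pre and post windows (default
  `pre_post` mode; a `post`-only mode averaging [0, 1) s alone is
  provided because the verbal definitions of the window combination admit
  both readings — the two agree exactly on fixtures where pre and post
  differences coincide).
- **General dilation** (mm): pooled post-switch trace (both percepts),
  averaged over [0, 1) s.
- **Attention modulation** (mm): for onset-locked epochs (baseline 150 ms
  *before* onset), black-cued minus white-cued difference over [1, 3] s.
- **Switch rate** (s⁻¹): genuine report changes divided by in-trial
  reporting time.

Per-subject significance of the modulation uses a one-sided Welch t-test
on per-half-epoch window means (black > white, α = 0.05). The published
analysis does not state its per-subject test; Welch is this package's
documented choice.

## Detection scoring

A press within 2 s *after* an increment is a hit; each increment is
credited at most once, and a press eligible for two increments (possible,
minimum separation 2 s = window) goes to the later, closer one
(configurable). A press more than 2 s from every increment in either
direction is a false alarm; surplus presses inside an already-credited
window are neither. The false-alarm denominator is not defined by verbal
task descriptions; we use the number of non-overlapping 2-s bins of
reporting time not containing an increment, making H and F commensurate
proportions. Rates of 0/1 are corrected to 1/(2N) before z-transforming.
The counting task (0–3 increments) is scored as exact-match percent
correct plus a d′ from collapsing counts to per-slot detections
(min(reported, true) hits among true slots, excess reports as false
alarms among empty slots) — a documented convention, not a published one.

## AQ-50 scoring and normality

Items score 1 when the response is in the keyed ASD-characteristic
direction, collapsing "slightly"/"definitely" — scoring is invariant to
that grade by construction. The item→subscale map and keyed directions
ship as versioned JSON following the standard published scoring key.
Missing responses are an error, not imputed. The Jarque–Bera statistic is
JB = n/6·(S² + K²/4); its p-value uses the χ²(2) asymptote by default,
with a Monte-Carlo small-sample mode (simulated Gaussian null at the
observed n) because the asymptote is quite inaccurate at n ≈ 50 — at
JB ≈ 1.42 with n = 50 the asymptote gives p ≈ 0.49 while the
finite-sample null gives ≈ 0.36, the behaviour of table-based
implementations.

## Inference

Pearson correlations are reported with Fisher-z confidence intervals,
tanh(atanh r ± z₀.₉₇₅/√(n−3)), and two-tailed p from
t = r√(n−2)/√(1−r²). Independent correlations are compared with
Fisher's Z. The Bayes factor for a correlation is the JZS (Zellner–Siow)
default:

    BF₁₀ = √(n s²/2)/Γ(½) ∫₀^∞ (1+g)^((n−2)/2) (1+(1−r²)g)^(−(n−1)/2)
                               g^(−3/2) e^(−n s²/(2g)) dg

integrated numerically (log-space integrand; adaptive quadrature), with
prior scale s (default 1). BF₁₀ > 3 / < 1/3 are read as strong evidence
for / against a correlation. The scale-selection procedure: the mapping
s → BF₁₀ has an interior maximum; `stats.anchored_prior_scale` solves
BF₁₀(r, n; s) = BF_anchor on the decreasing branch (s ≥ 1). The shipped
`ANCHORED_PRIOR_SCALE` (≈ 1.1705) is the root for the anchor
BF₁₀ = 62.7 at (r = 0.68, n = 22); the root below 1 (≈ 0.518) is rejected
because it is farther from the unit-information default and inconsistent
with null-side Bayes factors reported alongside the anchor. The
implementation is cross-checked in tests against an independent
brute-force quadrature of the same integrand and against
`pingouin.bayesfactor_pearson(method="wetzels")`.

## Synthetic-cohort generator

The generator's defaults are the study conditions the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| AQ distribution | Normal(14.85, 6.73), integers, redrawn outside [0, 31] | observed sample mean/SD; all observed totals below the clinical threshold 32; redraw (not clip) avoids a point mass at the bound. `aq_max=None` disables redraws entirely — a calibration mode against the pure normal |
| phase durations | gamma renewal, shape 2, mean 5.5 s | mean alternation from report statistics; gamma shape ~2 is the common bistability finding; shape ∞ gives deterministic phases |
| trials | 10 × 59 s per subject | the reported trial structure |
| pupil baseline | 3.5 mm | mid-range of the 1–7 mm plausible band |
| transient kernel | gamma density, peak latency 0.4 s, FWHM 0.8 s, amplitude 0.03 mm | a typical switch-locked dilation time course; all three are parameters |
| modulation link | amp = 0.002 mm/AQ-point · AQ + N(0, 0.01373 mm) | puts the population AQ–amplitude correlation at βσ/√(β²σ²+σε²) = 0.70 with σ = 6.73 |
| noise | Ornstein–Uhlenbeck, SD 0.05 mm, τ = 0.5 s | autocorrelated like real pupillometry, so epoch averages do not shrink as white noise would |
| blinks | Poisson 2/min, 0.2 s, recorded as 0.2 mm | what an infrared tracker records during lid closure; exercises the 1-mm rule |

**Ground-truth amplitude semantics.** The analysis baselines each epoch
side in the 150 ms next to the switch, so a purely sustained
percept-dependent offset is invisible to the index; what survives is the
switch-locked *change* between percept levels. The generator therefore
defines `modulation_amp` on the index scale: the injected per-phase
offset swing is `modulation_amp / gain`. The gain — expected index per
unit swing — has a closed form for an ideal isolated switch
(`modulation_index_gain`, from the kernel CDF alone), and a
renewal-conditional version (`renewal_index_gain`) that accounts for
short phases starting their transition from incomplete levels, estimated
by simulating the noise-free level process with plain array arithmetic
under a fixed internal seed. Neither touches the epoching code, so
full-chain recovery tests remain genuine cross-checks of two independent
implementations (they agree to within a few percent; the residual
difference reflects trial-boundary truncation, which only the pipeline
sees).

**What the generator does not emulate:** gaze dynamics (fixation is
perfect), the pupillary light reflex and arousal drifts, reaction-time
lag between percept and report, asymmetric percept dominance dynamics,
and any nonlinearity in the AQ–amplitude link. Passing recovery tests
therefore demonstrates correctness of the *analysis*, not validity of
the physiological model on real recordings.

## Numerical choices and degenerate inputs

- Analysis grid 60 Hz (the coarser of the two supported trackers);
  1-kHz input is downsampled by the same interpolation path.
- Boundary samples/phases exactly at thresholds are kept (strict-
  inequality reading of the exclusion rules).
- Quartile bins use sample quantiles with ties assigned to the lower bin.
- Perfectly collinear inputs to `pearson_full` return r = ±1 with a
  degenerate CI and BF₁₀ = ∞ rather than failing.
- d′ is undefined without false-alarm opportunities; the bin count is
  floored at 1.
- All generator outputs are bit-identical under a fixed (params, seed):
  per-subject seeds derive from `numpy.random.SeedSequence.spawn`.

## Problem sizes used in validation

The shipped tests validate the chain at the study's native scale —
10 × 59-s trials at 60 Hz per subject — using cohorts of 5 subjects for
end-to-end I/O checks and 50 subjects for the noisy recovery regression;
the simulation calibration uses 200 cohorts of 50 link draws (no pupil
synthesis, which the calibration does not require). These sizes give
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- The empirical excluded-phase percentage, per-subject significance
  counts, and counting-task d′ depend on observer behaviour the generator
  only schematically emulates; the pipeline computes them but no
  observed-cohort value is asserted.
- The reported switch rate (0.21/s) and mean phase duration (5.5 s) of
  the original cohort are mutually consistent only as subject-weighted
  averages; the generator exposes both parameterizations and does not
  force both numbers at once.
- The cylinder's printed centre speed (3.9°/s) differs from the geometric
  R·ω = 4·π/3 ≈ 4.19°/s with R = 4°; the kinematics module computes from
  geometry and documents the discrepancy rather than forcing the printed
  value.
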