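"""Synthetic cohorts for the bistable-cylinder pupillometry analysis.

Generates, from explicit parameters and a seed, everything the pipeline
consumes: AQ questionnaire responses, alternating percept-report streams,
pupil-diameter traces with switch-locked transients, percept-dependent
modulation, autocorrelated noise and blink artifacts, and speed-increment
events with detection responses.  Every draw is reproducible bit-identically
from ``(params, seed)``.

The pupil model is additive::

    pupil(t) = baseline
             + transient_amp * k(t - t_switch)          (every switch)
             + modulation(t)                            (percept-dependent)
             + OU noise + blink dropouts

where ``k`` is a gamma-shaped impulse response (peak-normalized; default
peak latency 0.4 s, FWHM 0.8 s) and the modulation is a per-phase step of
+swing/2 (black front) or -swing/2 (white front) convolved with the
area-normalized kernel, so the pre-switch trace still reflects the previous
percept.  Because the analysis baselines each epoch side in the 150 ms next
to the switch, a purely sustained offset would be invisible; what the index
measures is the switch-locked *change* between percept levels.  The
generator therefore defines its ground truth ``modulation_amp`` on the
index scale and injects a raw swing of ``modulation_amp /
modulation_index_gain(params)``, where the gain is the closed-form expected
index per unit swing (computed from the kernel CDF alone, independent of
the epoching code).

Phase durations follow a gamma renewal process (default shape 2, common in
the bistability literature) with mean 5.5 s; AQ totals are drawn from
Normal(14.85, 6.73), rounded, and redrawn when outside the admissible
range; the AQ -> modulation link is linear with slope 0.002 mm per AQ point
and residual SD 0.01373 mm, which puts the population correlation between
AQ and true amplitude at 0.70.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import BLACK_FRONT, WHITE_FRONT, PupilRecording
from . import aq as aqmod

__all__ = [
    "CohortParams",
    "PerceptDynamicsParams",
    "PupilModelParams",
    "GroundTruth",
    "gamma_kernel_params",
    "modulation_index_gain",
    "gen_aq_scores",
    "gen_aq_responses",
    "gen_link",
    "renewal_index_gain",
    "percept_stream_from_phases",
    "gen_percept_sequence",
    "gen_pupil_trace",
    "gen_detection_responses",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class CohortParams:
    """Cohort-level parameters: AQ distribution and AQ -> modulation link."""

    n_subjects: int = 50
    aq_mean: float = 14.85          # AQ points (observed sample mean)
    aq_sd: float = 6.73             # AQ points (observed sample SD)
    aq_max: int | None = 31         # redraw bound; None = full 0-50 normal
    slope_beta: float = 0.002       # mm of modulation per AQ point
    residual_sd: float = 0.01373    # mm; with slope/SD above -> rho = 0.70
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.aq_sd <= 0:
            raise ValueError("aq_sd must be positive")
        if self.aq_max is not None and not (0 < self.aq_max <= 50):
            raise ValueError("aq_max must be in (0, 50]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class PerceptDynamicsParams:
    """Gamma-renewal model of perceptual alternation."""

    mean_phase_duration: float = 5.5   # s
    phase_shape: float = 2.0           # gamma shape; inf = deterministic
    p_black_front: float = 0.5         # probability the first phase is black
    trial_duration: float = 59.0       # s
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mean_phase_duration <= 0:
            raise ValueError("mean_phase_duration must be positive")
        if not (0 <= self.p_black_front <= 1):
            raise ValueError("p_black_front must be a probability")
        if self.trial_duration <= 0 or self.n_trials < 1:
            raise ValueError("trial_duration and n_trials must be positive")


@dataclass(frozen=True)
class PupilModelParams:
    """Additive pupil-trace model parameters."""

    baseline_mm: float = 3.5
    transient_amp: float = 0.03     # mm, switch-locked dilation
    transient_latency: float = 0.4  # s, kernel peak time
    transient_width: float = 0.8    # s, kernel FWHM
    modulation_amp: float = 0.03    # mm, index-scale percept modulation
    noise_sd: float = 0.05          # mm, stationary OU noise SD
    noise_ac_tau: float = 0.5       # s, OU autocorrelation time
    sample_rate: float = 60.0       # Hz (60 or 1000)
    blink_rate: float = 2.0         # blinks per minute
    blink_duration: float = 0.2     # s

    def __post_init__(self):
        if not (1.0 < self.baseline_mm < 7.0):
            raise ValueError("baseline_mm must lie strictly within (1, 7) mm")
        if self.sample_rate not in (60.0, 1000.0, 60, 1000):
            raise ValueError("sample_rate must be 60 or 1000 Hz")
        for name in ("transient_latency", "transient_width", "noise_ac_tau",
                     "blink_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.blink_rate < 0:
            raise ValueError("noise_sd and blink_rate must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to verify the pipeline against the generator."""

    subjects: pd.DataFrame            # subject, aq_total, true_modulation_amp, raw_swing
    phases: pd.DataFrame              # subject, trial, start_s, end_s, label
    artifacts: pd.DataFrame           # subject, trial, start_s, end_s
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pupil kernel

def gamma_kernel_params(latency: float, width: float) -> tuple[float, float]:
    """Gamma (shape, scale) with mode ``latency`` and FWHM ``width``.

    Solved numerically; the kernel is the gamma density with these
    parameters.
    """
    from scipy.optimize import brentq

    def fwhm_of_shape(k: float) -> float:
        theta = latency / (k - 1.0)
        t_hi = sps.gamma.ppf(0.9999, k, scale=theta)
        t = np.linspace(t_hi * 1e-6, t_hi, 8000)
        pdf = sps.gamma.pdf(t, k, scale=theta)
        above = t[pdf >= 0.5 * pdf.max()]
        return float(above[-1] - above[0])

    k = brentq(lambda k: fwhm_of_shape(k) - width, 1.0 + 1e-6, 500.0)
    return k, latency / (k - 1.0)


def _kernel_arrays(params: PupilModelParams, dt: float):
    """Discrete causal kernel: (peak-normalized, area-normalized) arrays."""
    k, theta = gamma_kernel_params(params.transient_latency,
                                   params.transient_width)
    t_max = sps.gamma.ppf(0.999, k, scale=theta)
    t = np.arange(dt, t_max + dt, dt)
    pdf = sps.gamma.pdf(t, k, scale=theta)
    peak_norm = pdf / pdf.max()
    area_norm = pdf * dt / (pdf * dt).sum()
    return peak_norm, area_norm


def modulation_index_gain(
    params: PupilModelParams,
    analysis_rate: float = 60.0,
    index_window: float = 1.0,
    baseline_s: float = 0.15,
    mode: str = "pre_post",
) -> float:
    """Expected modulation index per unit injected swing (closed form).

    For an ideal isolated switch between steady-state phases, each
    percept's post-side baseline-corrected trace is ``+/- swing * (K(t) -
    mean K over the baseline window)`` with ``K`` the kernel CDF, while the
    pre-side corrected traces vanish (steady state minus its own baseline).
    Averaging the black-minus-white difference over the index windows gives

        gain = 2 * (K1 - K0)    for mode='post'
        gain = (K1 - K0)        for mode='pre_post'  (the pre window adds 0)

    with K1 the CDF mean over [0, 1) and K0 its mean over the baseline
    window, both on the analysis grid.  Only the kernel CDF is involved —
    no epoching code — so full-chain tests remain a genuine cross-check.
    """
    k, theta = gamma_kernel_params(params.transient_latency,
                                   params.transient_width)
    step = 1.0 / analysis_rate
    t = np.arange(0, index_window, step)
    cdf = sps.gamma.cdf(t, k, scale=theta)
    k0 = cdf[t < baseline_s].mean()
    k1 = cdf.mean()
    if mode == "pre_post":
        gain = k1 - k0
    elif mode == "post":
        gain = 2.0 * (k1 - k0)
    else:
        raise ValueError("mode must be 'pre_post' or 'post'")
    return float(gain)


def renewal_index_gain(
    params: PupilModelParams,
    dynamics: PerceptDynamicsParams,
    analysis_rate: float = 60.0,
    index_window: float = 1.0,
    baseline_s: float = 0.15,
    mode: str = "pre_post",
    usable_bounds: tuple[float, float] = (1.0, 15.0),
    n_phases: int = 6000,
    sim_seed: int = 987654321,
) -> float:
    """Expected index per unit swing under the phase-duration distribution.

    The ideal-switch gain of :func:`modulation_index_gain` assumes every
    phase reaches steady state; with gamma-renewal phases a fraction are
    short, so transitions start from incomplete levels and pre-side windows
    are not flat, shrinking the measured index by several percent.  This
    estimates the renewal-conditional gain by simulating a long alternating
    level process (unit swing, no noise) on the analysis grid, convolving
    with the kernel, and averaging baseline-corrected window means over the
    switches whose labeling phase is usable — plain array arithmetic with a
    fixed internal seed, independent of the epoching implementation.
    Cached per parameter set.
    """
    key = (params.transient_latency, params.transient_width,
           dynamics.phase_shape, dynamics.mean_phase_duration,
           analysis_rate, index_window, baseline_s, mode,
           usable_bounds, n_phases, sim_seed)
    if key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    rng = np.random.default_rng(sim_seed)
    step = 1.0 / analysis_rate
    if math.isinf(dynamics.phase_shape):
        durs = np.full(n_phases, dynamics.mean_phase_duration)
    else:
        durs = rng.gamma(dynamics.phase_shape,
                         dynamics.mean_phase_duration / dynamics.phase_shape,
                         n_phases)
    edges = np.concatenate(([0.0], np.cumsum(durs)))
    n = int(edges[-1] * analysis_rate)
    t = np.arange(n) * step
    which = np.searchsorted(edges, t, side="right") - 1
    level = np.where(which % 2 == 0, 0.5, -0.5)  # even phases "black"
    _, area_k = _kernel_arrays(params, step)
    pad = area_k.size
    padded = np.concatenate((np.full(pad, level[0]), level))
    sig = np.convolve(padded, area_k)[:padded.size][pad:]

    nw = int(round(index_window * analysis_rate))
    nb = int(round(baseline_s * analysis_rate))
    post_diff, pre_diff = [], []
    for j in range(1, n_phases - 1):
        i0 = int(round(edges[j] * analysis_rate))
        sgn = 1.0 if j % 2 == 0 else -1.0
        d_post, d_pre = durs[j], durs[j - 1]
        if usable_bounds[0] <= d_post <= usable_bounds[1] and i0 + nw <= n:
            w = sig[i0:i0 + nw]
            post_diff.append(sgn * (w.mean() - w[:nb].mean()) * 2.0)
        if usable_bounds[0] <= d_pre <= usable_bounds[1] and i0 - nw >= 0:
            w = sig[i0 - nw:i0]
            pre_diff.append(-sgn * (w.mean() - w[-nb:].mean()) * 2.0)
    post = float(np.mean(post_diff))
    if mode == "post":
        gain = post
    elif mode == "pre_post":
        gain = (post + float(np.mean(pre_diff))) / 2.0
    else:
        raise ValueError("mode must be 'pre_post' or 'post'")
    _GAIN_CACHE[key] = gain
    return gain


_GAIN_CACHE: dict = {}


# ---------------------------------------------------------------------------
# generators

def gen_aq_scores(params: CohortParams,
                  rng: np.random.Generator | None = None) -> list[int]:
    """Integer AQ totals: Normal(mean, sd) rounded, redrawn outside range.

    Scores outside [0, aq_max] are redrawn (not clipped), so there is no
    point mass at the bounds.  ``aq_max=None`` disables the redraw rule
    entirely — a calibration mode in which the linear AQ→amplitude link is
    exercised against the unconstrained Normal(mean, sd); such scores can
    in principle fall outside the questionnaire's 0–50 range.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if params.aq_max is None:
        return [int(round(x))
                for x in rng.normal(params.aq_mean, params.aq_sd,
                                    params.n_subjects)]
    out: list[int] = []
    while len(out) < params.n_subjects:
        x = int(round(rng.normal(params.aq_mean, params.aq_sd)))
        if 0 <= x <= params.aq_max:
            out.append(x)
    return out


def gen_aq_responses(total: int, key: dict | None = None,
                     rng: np.random.Generator | None = None) -> dict:
    """Item-level responses (codes 1-4) whose standard score equals ``total``."""
    if not (0 <= total <= 50):
        raise ValueError("AQ total must be in [0, 50]")
    key = key or aqmod.load_key()
    rng = rng if rng is not None else np.random.default_rng(0)
    items = sorted(key["items"])
    scored = set(rng.choice(items, size=total, replace=False)) if total else set()
    resp = {}
    for item in items:
        agree_keyed = key["items"][item]["keyed_direction"] == "agree_is_autistic"
        autistic = item in scored
        agree = agree_keyed == autistic
        # strong vs slight is irrelevant to the score; randomize it
        strong = bool(rng.integers(0, 2))
        resp[item] = (1 if strong else 2) if agree else (4 if strong else 3)
    return resp


def gen_link(cohort: CohortParams,
             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-subject AQ scores and true modulation amplitudes.

    ``true_modulation_amp = slope_beta * AQ + Normal(0, residual_sd)``;
    with the defaults (slope 0.002 mm/point, residual SD 0.01373 mm, AQ SD
    6.73) the population correlation between AQ and amplitude is 0.70.
    """
    rng = rng if rng is not None else np.random.default_rng(cohort.seed)
    aq_totals = gen_aq_scores(cohort, rng=rng)
    noise = rng.normal(0.0, cohort.residual_sd, cohort.n_subjects)
    return pd.DataFrame({
        "subject": [f"s{i:03d}" for i in range(cohort.n_subjects)],
        "aq_total": aq_totals,
        "true_modulation_amp": cohort.slope_beta * np.asarray(aq_totals) + noise,
    })


def gen_percept_sequence(
    params: PerceptDynamicsParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Alternating percept phases tiling each trial exactly.

    Durations are a gamma renewal process with mean
    ``mean_phase_duration`` and shape ``phase_shape`` (``inf`` gives
    deterministic durations); labels strictly alternate within a trial; the
    first label of each trial is black-front with ``p_black_front``.
    Returns columns ``trial``, ``start_s``, ``end_s``, ``label``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rows = []
    for trial in range(params.n_trials):
        black = rng.random() < params.p_black_front
        t = 0.0
        while t < params.trial_duration:
            if math.isinf(params.phase_shape):
                d = params.mean_phase_duration
            else:
                d = rng.gamma(params.phase_shape,
                              params.mean_phase_duration / params.phase_shape)
            end = min(t + d, params.trial_duration)
            rows.append({"trial": trial, "start_s": t, "end_s": end,
                         "label": BLACK_FRONT if black else WHITE_FRONT})
            t += d
            black = not black
    return pd.DataFrame(rows)


def gen_pupil_trace(
    phases: pd.DataFrame,
    params: PupilModelParams,
    seed: int | np.random.Generator = 0,
    subject: str = "s00",
    index_gain_mode: str = "pre_post",
    index_gain: float | None = None,
) -> tuple[PupilRecording, dict]:
    """Synthesize the pupil recording implied by a phase table.

    Returns ``(recording, truth)`` where ``truth`` records the injected
    modulation amplitude (index scale and raw swing) and the blink
    intervals.  Blink artifacts overwrite samples with a sub-1-mm value, as
    an infrared tracker records them, so the 1-mm exclusion rule is
    exercised downstream.
    """
    if phases.empty:
        raise ValueError("phase table is empty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dt = 1.0 / params.sample_rate
    peak_k, area_k = _kernel_arrays(params, dt)
    gain = (index_gain if index_gain is not None
            else modulation_index_gain(params, mode=index_gain_mode))
    swing = params.modulation_amp / gain
    pad = area_k.size

    t_all, p_all, tr_all = [], [], []
    artifacts = []
    for trial, ph in phases.groupby("trial", sort=True):
        ph = ph.sort_values("start_s")
        dur = float(ph["end_s"].max())
        n = int(round(dur * params.sample_rate))
        t = np.arange(n) * dt
        # percept-dependent step, left-padded with the first phase's level
        level = np.empty(n)
        for _, row in ph.iterrows():
            sel = (t >= row["start_s"]) & (t < row["end_s"])
            level[sel] = swing / 2.0 if row["label"] == BLACK_FRONT else -swing / 2.0
        first = level[0]
        padded = np.concatenate((np.full(pad, first), level))
        modulation = np.convolve(padded, area_k)[:padded.size][pad:]
        # switch-locked transient at every within-trial switch
        transient = np.zeros(n)
        switch_times = ph["start_s"].to_numpy()[1:]
        for ts in switch_times:
            i0 = int(round(ts * params.sample_rate))
            seg = peak_k[: max(0, n - i0)]
            transient[i0:i0 + seg.size] += params.transient_amp * seg
        # Ornstein-Uhlenbeck noise, stationary SD = noise_sd
        noise = np.zeros(n)
        if params.noise_sd > 0:
            from scipy.signal import lfilter

            a = math.exp(-dt / params.noise_ac_tau)
            innov = rng.standard_normal(n) * params.noise_sd * math.sqrt(1 - a * a)
            x0 = rng.standard_normal() * params.noise_sd
            rest, _ = lfilter([1.0], [1.0, -a], innov[1:], zi=np.array([a * x0]))
            noise = np.concatenate(([x0], rest))
        pupil = params.baseline_mm + modulation + transient + noise
        # blinks: Poisson process, recorded as sub-1-mm dropouts
        if params.blink_rate > 0:
            n_blinks = rng.poisson(params.blink_rate / 60.0 * dur)
            for t0 in np.sort(rng.uniform(0, dur, n_blinks)):
                sel = (t >= t0) & (t < t0 + params.blink_duration)
                pupil[sel] = 0.2
                artifacts.append({"subject": subject, "trial": trial,
                                  "start_s": float(t0),
                                  "end_s": float(min(t0 + params.blink_duration,
                                                     dur))})
        t_all.append(t)
        p_all.append(pupil)
        tr_all.append(np.full(n, trial))

    rec = PupilRecording(
        t_s=np.concatenate(t_all),
        pupil_mm=np.concatenate(p_all),
        trial=np.concatenate(tr_all),
        sample_rate=params.sample_rate,
        subject=subject,
        gaze_x_deg=np.zeros(sum(len(x) for x in t_all)),
        gaze_y_deg=np.zeros(sum(len(x) for x in t_all)),
    )
    truth = {
        "subject": subject,
        "modulation_amp": params.modulation_amp,
        "raw_swing": swing,
        "index_gain": gain,
        "artifacts": pd.DataFrame(
            artifacts, columns=["subject", "trial", "start_s", "end_s"]),
    }
    return rec, truth


def percept_stream_from_phases(phases: pd.DataFrame,
                               rate: float = 60.0) -> pd.DataFrame:
    """Render a phase table as the key-state stream a subject would produce.

    Samples at ``rate`` Hz over each trial; the held key encodes the
    current percept ('black'/'white').  This is the format the percept
    reader and segmentation consume.
    """
    rows = []
    for trial, ph in phases.groupby("trial", sort=True):
        dur = float(ph["end_s"].max())
        t = np.arange(int(round(dur * rate))) / rate
        state = np.empty(t.size, dtype=object)
        for _, row in ph.iterrows():
            sel = (t >= row["start_s"]) & (t < row["end_s"])
            state[sel] = "black" if row["label"] == BLACK_FRONT else "white"
        rows.append(pd.DataFrame({"trial": trial, "t_s": t,
                                  "key_state": state}))
    return pd.concat(rows, ignore_index=True)


def gen_detection_responses(
    events: pd.DataFrame,
    hit_rate: float,
    fa_rate: float,
    latency_mean: float,
    seed: int | np.random.Generator = 0,
    duration: float | None = None,
) -> pd.DataFrame:
    """Simulated observer for the speed-increment detection task.

    Each event is answered independently with probability ``hit_rate`` at
    event time plus a gamma-distributed latency (shape 10, mean
    ``latency_mean`` — tight enough that responses stay inside the scoring
    window); spurious presses arrive as a Poisson process at ``fa_rate``
    per minute over ``duration``.  Returns a sorted press-time table
    (columns ``trial`` if present in events, ``t_s``).
    """
    if not (0 <= hit_rate <= 1):
        raise ValueError("hit_rate must be a probability")
    if latency_mean >= 2.0:
        raise ValueError("latency_mean must be < 2 s (the scoring window)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    times = events["t_s"].to_numpy(dtype=float) if len(events) else np.array([])
    presses = []
    answered = rng.random(times.size) < hit_rate
    lat = rng.gamma(10.0, latency_mean / 10.0, size=times.size)
    presses.extend(times[answered] + lat[answered])
    if fa_rate > 0:
        horizon = duration if duration is not None else (
            float(times.max()) + 2.0 if times.size else 60.0)
        n_fa = rng.poisson(fa_rate / 60.0 * horizon)
        presses.extend(rng.uniform(0, horizon, n_fa))
    return pd.DataFrame({"t_s": np.sort(np.asarray(presses, dtype=float))})


def gen_cohort(
    cohort: CohortParams,
    dynamics: PerceptDynamicsParams | None = None,
    pupil: PupilModelParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, GroundTruth]:
    """Generate a full synthetic cohort, optionally writing it to disk.

    Per subject: an AQ total (and item responses scoring to it), a percept
    phase sequence, and a pupil recording whose true modulation amplitude
    is ``slope_beta * AQ + Normal(0, residual_sd)``.  Returns
    ``(dataset, truth)`` where ``dataset`` maps subject id to
    ``{"recording", "phases", "aq_responses"}``.  With ``out_dir`` the
    pipeline input files (samples/percepts TSV, AQ CSV, manifest JSON) are
    written; regeneration from the manifest's params and seed is
    byte-identical.
    """
    dynamics = dynamics or PerceptDynamicsParams()
    pupil = pupil or PupilModelParams()
    root = np.random.SeedSequence(cohort.seed)
    link = gen_link(cohort, rng=np.random.default_rng(root.spawn(1)[0]))
    aq_totals = link["aq_total"].to_numpy()
    true_amps = link["true_modulation_amp"].to_numpy()
    key = aqmod.load_key()

    gain = renewal_index_gain(pupil, dynamics)
    dataset: dict[str, dict] = {}
    subj_rows, phase_frames, artifact_frames = [], [], []
    subject_seeds = root.spawn(cohort.n_subjects)
    for i, (aq_total, sseed) in enumerate(zip(aq_totals, subject_seeds)):
        sid = f"s{i:03d}"
        rng = np.random.default_rng(sseed)
        true_amp = true_amps[i]
        phases = gen_percept_sequence(dynamics, rng=rng)
        sp = dataclass_replace(pupil, modulation_amp=true_amp)
        rec, truth = gen_pupil_trace(phases, sp, seed=rng, subject=sid,
                                     index_gain=gain)
        responses = gen_aq_responses(aq_total, key=key, rng=rng)
        dataset[sid] = {"recording": rec, "phases": phases,
                        "aq_responses": responses}
        subj_rows.append({"subject": sid, "aq_total": aq_total,
                          "true_modulation_amp": true_amp,
                          "raw_swing": truth["raw_swing"]})
        phase_frames.append(phases.assign(subject=sid))
        artifact_frames.append(truth["artifacts"])

    truth = GroundTruth(
        subjects=pd.DataFrame(subj_rows),
        phases=pd.concat(phase_frames, ignore_index=True),
        artifacts=pd.concat(artifact_frames, ignore_index=True),
        params={"cohort": asdict(cohort), "dynamics": asdict(dynamics),
                "pupil": asdict(pupil)},
    )
    if out_dir is not None:
        _write_cohort(Path(out_dir), dataset, truth)
    return dataset, truth


def dataclass_replace(params: PupilModelParams, **kw) -> PupilModelParams:
    from dataclasses import replace

    return replace(params, **kw)


def _write_cohort(out: Path, dataset: dict, truth: GroundTruth) -> None:
    from . import io as psio

    out.mkdir(parents=True, exist_ok=True)
    samples, percepts, aq_rows = [], [], []
    for sid, d in dataset.items():
        rec: PupilRecording = d["recording"]
        samples.append(pd.DataFrame({
            "subject": sid, "trial": rec.trial, "t_s": rec.t_s,
            "pupil_mm": rec.pupil_mm,
            "gaze_x_deg": rec.gaze_x_deg, "gaze_y_deg": rec.gaze_y_deg,
        }))
        percepts.append(
            percept_stream_from_phases(d["phases"]).assign(subject=sid))
        aq_rows.append({"subject": sid, **d["aq_responses"]})
    psio.write_samples(pd.concat(samples, ignore_index=True), out / "samples.tsv")
    psio.write_percepts(pd.concat(percepts, ignore_index=True),
                        out / "percepts.tsv")
    pd.DataFrame(aq_rows).to_csv(out / "aq_responses.csv", index=False)
    truth.subjects.to_csv(out / "ground_truth_subjects.csv", index=False)
    manifest = {"params": truth.params, "format_version": 1}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
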