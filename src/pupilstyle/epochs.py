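"""Switch-locked epoching and the pupil summary indices.

Pupil traces are parsed into epochs locked to each perceptual switch (time
zero), or to stimulus onset for the cued-attention condition.  A switch
contributes two half-epochs: the *pre* side belongs to the phase that ends
at the switch, the *post* side to the phase that begins there; each side is
labeled by its own phase's percept (black vs white surface in front) and is
baseline-corrected by the mean pupil size in the 150 ms immediately
adjacent to the switch on that side.  Because usable phases last at least
1 s, the 1-s index windows never extend beyond the labeling phase.

Three per-subject summary indices are derived:

* ``luminance_modulation`` — the black-front minus white-front difference
  of the label-mean corrected traces, averaged over the [-1, 0] and [0, 1] s
  windows (or [0, 1] only in "post"-only mode).  Positive = pupil more
  dilated when the black surface is perceived in front.
* ``general_dilation`` — the across-label pooled post-switch trace averaged
  over [0, 1] s: the transient dilation that follows any switch.
* ``attention_modulation`` — for onset-locked epochs, the black-cued minus
  white-cued trace difference averaged over [1, 3] s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import BLACK_FRONT, WHITE_FRONT, PupilRecording

__all__ = [
    "Epoch",
    "extract_switch_epochs",
    "extract_onset_epochs",
    "mean_traces",
    "luminance_modulation",
    "general_dilation",
    "attention_modulation",
    "switch_rate",
    "per_subject_significance",
]

BASELINE_S = 0.15


@dataclass
class Epoch:
    """One baseline-corrected half-epoch (or onset-locked epoch)."""

    t: np.ndarray          # time relative to the switch/onset, s
    trace: np.ndarray      # baseline-corrected pupil, mm; NaN where missing
    label: str             # percept or cue label
    side: str              # 'pre', 'post' or 'onset'
    align_time: float      # absolute switch/onset time, s
    trial: object = None
    subject: str = ""

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.trace)


def _interp_masked(t, y, valid, t_new):
    """Linear interpolation propagating invalid samples as NaN.

    A target point is valid only if both bracketing source samples are
    valid and the point lies inside the sampled range.
    """
    t = np.asarray(t, float)
    t_new = np.asarray(t_new, float)
    vals = np.interp(t_new, t, y)
    vmask = np.interp(t_new, t, np.asarray(valid, float)) >= 1.0 - 1e-9
    inside = (t_new >= t[0]) & (t_new <= t[-1])
    vals = np.where(vmask & inside, vals, np.nan)
    return vals


def _baseline(trace: np.ndarray, in_window: np.ndarray,
              min_frac: float = 0.5) -> float:
    w = trace[in_window]
    n_valid = np.isfinite(w).sum()
    if w.size == 0 or n_valid < min_frac * w.size:
        return math.nan
    return float(np.nanmean(w))


def extract_switch_epochs(
    rec: PupilRecording,
    phases: pd.DataFrame,
    window: tuple[float, float] = (-1.0, 1.0),
    analysis_rate: float = 60.0,
    baseline_s: float = BASELINE_S,
) -> tuple[list[Epoch], list[dict]]:
    """Extract switch-locked half-epochs from a masked recording.

    For every usable phase, its starting switch yields a post-side epoch
    (grid [0, window[1]) at ``analysis_rate``) and its ending switch a
    pre-side epoch (grid [window[0], 0)).  Each side is baseline-corrected
    by its own 150-ms window adjacent to the switch; epochs whose baseline
    window has fewer than 50% valid samples are dropped with a logged
    reason.  Returns ``(epochs, dropped)``.
    """
    if rec.valid is None:
        raise ValueError("recording has no validity mask; run mask_pupil_samples")
    if "usable" not in phases.columns:
        raise ValueError("phases not filtered; run filter_phases")
    step = 1.0 / analysis_rate
    n_pre = int(round(-window[0] * analysis_rate))
    n_post = int(round(window[1] * analysis_rate))
    t_pre = (np.arange(-n_pre, 0) + 0.0) * step          # [-1, 0)
    t_post = np.arange(0, n_post) * step                 # [0, 1)

    epochs: list[Epoch] = []
    dropped: list[dict] = []
    for tr, idx in rec.trials():
        tt, yy, vv = rec.t_s[idx], rec.pupil_mm[idx], rec.valid[idx]
        ph = phases[(phases["trial"] == tr) & phases["usable"]]
        for _, row in ph.iterrows():
            for side, t0, grid, bl_sel in (
                ("post", row["start_s"], t_post, t_post < baseline_s),
                ("pre", row["end_s"], t_pre, t_pre >= -baseline_s),
            ):
                boundary = (
                    row["starts_at_boundary"] if side == "post"
                    else row["ends_at_boundary"]
                )
                if boundary:
                    continue  # not a genuine switch
                trace = _interp_masked(tt, yy, vv, t0 + grid)
                b = _baseline(trace, bl_sel)
                if math.isnan(b):
                    dropped.append(
                        {"trial": tr, "align_time": t0, "side": side,
                         "reason": "baseline_invalid"}
                    )
                    continue
                epochs.append(
                    Epoch(t=grid.copy(), trace=trace - b, label=row["label"],
                          side=side, align_time=float(t0), trial=tr,
                          subject=rec.subject)
                )
    return epochs, dropped


def extract_onset_epochs(
    rec: PupilRecording,
    onsets,
    cue_labels,
    window: tuple[float, float] = (0.0, 6.0),
    analysis_rate: float = 60.0,
    baseline_s: float = BASELINE_S,
    trials=None,
) -> tuple[list[Epoch], list[dict]]:
    """Onset-locked epochs for the cued feature-attention condition.

    The baseline is the mean pupil size in the 150 ms *preceding* the
    stimulus onset; the epoch covers ``window`` after it.  Cue labels are
    carried through 1:1.  When onset times are trial-relative (recordings
    whose clock restarts each trial), pass the matching ``trials`` ids.
    """
    if rec.valid is None:
        raise ValueError("recording has no validity mask; run mask_pupil_samples")
    onsets = np.asarray(onsets, float)
    cue_labels = list(cue_labels)
    if len(cue_labels) != onsets.size:
        raise ValueError("onsets and cue_labels must be aligned")
    if trials is not None and len(trials) != onsets.size:
        raise ValueError("trials must align with onsets")
    step = 1.0 / analysis_rate
    grid = np.arange(window[0], window[1] - 1e-9, step)
    n_bl = int(round(baseline_s * analysis_rate))
    bl_grid = (np.arange(-n_bl, 0)) * step

    trial_idx = {tr: idx for tr, idx in rec.trials()}
    epochs, dropped = [], []
    for i, (t0, lab) in enumerate(zip(onsets, cue_labels)):
        if trials is None:
            tt, yy, vv = rec.t_s, rec.pupil_mm, rec.valid
        else:
            idx = trial_idx.get(trials[i])
            if idx is None:
                dropped.append({"align_time": float(t0), "side": "onset",
                                "reason": "unknown_trial"})
                continue
            tt, yy, vv = rec.t_s[idx], rec.pupil_mm[idx], rec.valid[idx]
        bl_trace = _interp_masked(tt, yy, vv, t0 + bl_grid)
        b = _baseline(bl_trace, np.ones(bl_trace.size, bool))
        if math.isnan(b):
            dropped.append({"align_time": float(t0), "side": "onset",
                            "reason": "baseline_invalid"})
            continue
        trace = _interp_masked(tt, yy, vv, t0 + grid)
        epochs.append(Epoch(t=grid.copy(), trace=trace - b, label=lab,
                            side="onset", align_time=float(t0),
                            trial=None if trials is None else trials[i],
                            subject=rec.subject))
    return epochs, dropped


def _label_mean(epochs: list[Epoch], label: str, side: str) -> np.ndarray:
    sel = [e.trace for e in epochs if e.label == label and e.side == side]
    if not sel:
        raise ValueError(
            f"no epochs with label {label!r} on side {side!r}; present: "
            f"{sorted({(e.label, e.side) for e in epochs})}"
        )
    return np.nanmean(np.vstack(sel), axis=0)


def mean_traces(epochs: list[Epoch]) -> dict:
    """Grand-average traces per (label, side): across-subject mean and sem.

    Within-subject label means are computed first; the across-subject mean
    and s.e.m. are then taken pointwise (missing samples ignored with count
    tracking).  Returns ``{(label, side): {"t", "mean", "sem", "n"}}``.
    """
    if not epochs:
        raise ValueError("no epochs")
    out = {}
    keys = sorted({(e.label, e.side) for e in epochs})
    for label, side in keys:
        sub_means = []
        grid = None
        for subj in sorted({e.subject for e in epochs}):
            sel = [e for e in epochs
                   if e.label == label and e.side == side and e.subject == subj]
            if not sel:
                continue
            grid = sel[0].t
            sub_means.append(np.nanmean(np.vstack([e.trace for e in sel]), axis=0))
        m = np.vstack(sub_means)
        n = np.isfinite(m).sum(axis=0)
        mean = np.nanmean(m, axis=0)
        if m.shape[0] > 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                sd = np.nanstd(m, axis=0, ddof=1)
                sem = np.where(n > 1, sd / np.sqrt(n), np.nan)
        else:
            sem = np.full(m.shape[1], np.nan)  # s.e.m. undefined for one subject
        out[(label, side)] = {"t": grid, "mean": mean, "sem": sem, "n": n}
    return out


def luminance_modulation(epochs: list[Epoch], mode: str = "pre_post") -> float:
    """Luminance-dependent pupil-modulation index for one subject, in mm.

    Difference of the label-mean corrected traces (black front minus white
    front) averaged over the [-1, 0] s pre window and the [0, 1] s post
    window (``mode='pre_post'``, the default) or the post window alone
    (``mode='post'``).  Positive values mean the pupil is more dilated when
    the black surface is seen in front.
    """
    if mode not in ("pre_post", "post"):
        raise ValueError("mode must be 'pre_post' or 'post'")
    diffs = []
    post = _label_mean(epochs, BLACK_FRONT, "post") - _label_mean(
        epochs, WHITE_FRONT, "post")
    diffs.append(float(np.nanmean(post)))
    if mode == "pre_post":
        pre = _label_mean(epochs, BLACK_FRONT, "pre") - _label_mean(
            epochs, WHITE_FRONT, "pre")
        diffs.append(float(np.nanmean(pre)))
    return float(np.mean(diffs))


def general_dilation(epochs: list[Epoch]) -> float:
    """Post-switch dilation pooled across both percepts, mean over [0, 1] s."""
    post = [e.trace for e in epochs if e.side == "post"]
    if not post:
        raise ValueError("no post-side epochs")
    return float(np.nanmean(np.nanmean(np.vstack(post), axis=0)))


def attention_modulation(
    epochs: list[Epoch],
    window: tuple[float, float] = (1.0, 3.0),
    labels: tuple[str, str] = ("black_cued", "white_cued"),
) -> float:
    """Cue-dependent pupil difference over [1, 3] s from stimulus onset."""
    m_black = _label_mean(epochs, labels[0], "onset")
    m_white = _label_mean(epochs, labels[1], "onset")
    grid = next(e.t for e in epochs if e.side == "onset")
    sel = (grid >= window[0]) & (grid <= window[1])
    return float(np.nanmean((m_black - m_white)[sel]))


def switch_rate(phases: pd.DataFrame, total_time_s: float) -> float:
    """Perceptual switches per second of in-trial reporting time.

    A switch is any phase end that is a genuine report change (not a trial
    boundary or gap); counted over all phases, usable or not.
    """
    if total_time_s <= 0:
        raise ValueError("total reporting time must be positive")
    n_switch = int((~phases["ends_at_boundary"]).sum())
    return n_switch / total_time_s


def per_subject_significance(
    epochs: list[Epoch], alpha: float = 0.05
) -> tuple[bool | None, str]:
    """Is this subject's modulation significantly positive?

    Per-epoch window means (each half-epoch averaged over its own window)
    are compared between the two percepts with a one-sided Welch t-test
    (black front > white front) at ``alpha``.  Returns ``(flag, reason)``;
    the flag is None when either percept has fewer than 2 epochs.
    """
    vals = {BLACK_FRONT: [], WHITE_FRONT: []}
    for e in epochs:
        if e.side in ("pre", "post") and e.label in vals:
            m = np.nanmean(e.trace)
            if np.isfinite(m):
                vals[e.label].append(m)
    nb, nw = len(vals[BLACK_FRONT]), len(vals[WHITE_FRONT])
    if nb < 2 or nw < 2:
        return None, f"insufficient epochs (black={nb}, white={nw})"
    t, p = sps.ttest_ind(vals[BLACK_FRONT], vals[WHITE_FRONT],
                         equal_var=False, alternative="greater")
    return bool(p < alpha), "ok"
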