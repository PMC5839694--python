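"""Sample- and phase-level quality control for pupil / percept streams.

Two exclusion rules operate before any epoching:

* samples with pupil diameter below 1 mm (blinks) or above 7 mm (eyelash
  interference) are masked invalid — boundaries are kept, the rule is a
  strict inequality;
* perceptual phases shorter than 1 s (mostly finger errors) or longer than
  15 s (too few alternations to measure bistability) are flagged unusable,
  as are phases censored by a trial boundary; a subject with fewer than 10
  usable phases is excluded outright.

Percept reports arrive as a time-stamped key-state stream (which key is
held down at each sample); maximal constant-state runs become phases, with
brief "none" gaps at key changes absorbed into the preceding phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PupilRecording",
    "QCReport",
    "BLACK_FRONT",
    "WHITE_FRONT",
    "mask_pupil_samples",
    "segment_phases",
    "filter_phases",
    "foreground_time_share",
]

BLACK_FRONT = "black_front"
WHITE_FRONT = "white_front"

#: percept-report key -> phase label (anticlockwise rotation implies the
#: black, rightward-moving dots are seen in front under the default stimulus)
KEY_TO_LABEL = {
    "black": BLACK_FRONT,
    "white": WHITE_FRONT,
    "anticlockwise": BLACK_FRONT,
    "clockwise": WHITE_FRONT,
    BLACK_FRONT: BLACK_FRONT,
    WHITE_FRONT: WHITE_FRONT,
}

PHASE_COLUMNS = ["trial", "start_s", "end_s", "label",
                 "starts_at_boundary", "ends_at_boundary"]


@dataclass
class PupilRecording:
    """Pupil-diameter time series (possibly multi-trial) in millimetres."""

    t_s: np.ndarray
    pupil_mm: np.ndarray
    trial: np.ndarray
    sample_rate: float
    subject: str = ""
    gaze_x_deg: np.ndarray | None = None
    gaze_y_deg: np.ndarray | None = None
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.pupil_mm = np.asarray(self.pupil_mm, dtype=float)
        self.trial = np.asarray(self.trial)
        if not (self.t_s.shape == self.pupil_mm.shape == self.trial.shape):
            raise ValueError("t_s, pupil_mm and trial must be aligned 1-D arrays")
        for tr in np.unique(self.trial):
            tt = self.t_s[self.trial == tr]
            if np.any(np.diff(tt) <= 0):
                raise ValueError(
                    f"timestamps must be strictly increasing within trial {tr}"
                )

    def trials(self):
        for tr in np.unique(self.trial):
            yield tr, np.flatnonzero(self.trial == tr)


@dataclass
class QCReport:
    subject: str
    fraction_samples_excluded: float
    fraction_phases_excluded: float
    usable_phase_count: int
    subject_excluded: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def mask_pupil_samples(
    rec: PupilRecording, min_mm: float = 1.0, max_mm: float = 7.0
) -> np.ndarray:
    """Validity mask: True where 1 mm <= pupil <= 7 mm and finite.

    Exclusion is strict ("smaller than 1 mm … larger than 7 mm"), so samples
    exactly at a bound are kept.  The mask is also stored on ``rec.valid``.
    """
    p = rec.pupil_mm
    mask = np.isfinite(p) & (p >= min_mm) & (p <= max_mm)
    rec.valid = mask
    return mask


def segment_phases(
    report: pd.DataFrame,
    gap_tolerance_s: float = 0.2,
    key_map: dict | None = None,
) -> pd.DataFrame:
    """Segment a key-state stream into labeled perceptual phases.

    Parameters
    ----------
    report : DataFrame with columns ``trial``, ``t_s``, ``key_state``;
        ``key_state`` in {black, white, anticlockwise, clockwise, none}
        (or 'both' → validation error: simultaneous keys).
    gap_tolerance_s : "none" runs shorter than this at a key change are
        absorbed into the preceding phase (report-device debounce); longer
        gaps terminate the phase.

    Returns a phase table with columns ``trial``, ``start_s``, ``end_s``,
    ``label``, ``starts_at_boundary``, ``ends_at_boundary``.  The switch
    time is the report-device change time; no reaction-time correction is
    applied.  Phases touching the start/end of a trial's report stream (or
    a long gap) are marked as boundary-censored.
    """
    key_map = key_map or KEY_TO_LABEL
    required = {"trial", "t_s", "key_state"}
    if not required.issubset(report.columns):
        raise ValueError(f"report stream missing columns {required - set(report.columns)}")
    if (report["key_state"] == "both").any():
        bad = report.index[report["key_state"] == "both"][0]
        raise ValueError(f"overlapping simultaneous keys at row {bad}")

    rows = []
    for tr, grp in report.groupby("trial", sort=True):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(dtype=float)
        state = grp["key_state"].to_numpy()
        if t.size < 2:
            continue
        dt = float(np.median(np.diff(t)))
        trial_end = t[-1] + dt
        # run-length encode the state sequence; run end = next run's onset
        change = np.flatnonzero(state[1:] != state[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [t.size]))
        runs = [
            (state[s], t[s], trial_end if e == t.size else t[e])
            for s, e in zip(starts, ends)
        ]
        n_runs = len(runs)
        phases_tr: list[dict] = []
        for j, (st, t0, t1) in enumerate(runs):
            if st == "none":
                continue
            if st not in key_map:
                raise ValueError(f"unknown key state {st!r} in trial {tr}")
            label = key_map[st]
            # start side: exact only if the phase begins at a key change or
            # after an absorbed (sub-tolerance) release gap
            if j == 0:
                start_cens = True
            elif runs[j - 1][0] != "none":
                start_cens = False
            else:
                gap_len = runs[j - 1][2] - runs[j - 1][1]
                start_cens = not (gap_len < gap_tolerance_s and j >= 2)
            # end side: extend through an absorbed gap to the next key onset
            if j == n_runs - 1:
                end_cens = True
            elif runs[j + 1][0] != "none":
                end_cens = False
            else:
                nxt = runs[j + 1]
                gap_len = nxt[2] - nxt[1]
                if gap_len < gap_tolerance_s and j + 2 < n_runs:
                    t1, end_cens = nxt[2], False
                else:
                    end_cens = True
            prev = phases_tr[-1] if phases_tr else None
            if (
                prev is not None
                and prev["label"] == label
                and not start_cens
                and not prev["ends_at_boundary"]
                and abs(prev["end_s"] - t0) < 1e-9
            ):
                # same key re-pressed within the tolerance: one phase
                prev["end_s"] = t1
                prev["ends_at_boundary"] = bool(end_cens)
            else:
                phases_tr.append(
                    {
                        "trial": tr,
                        "start_s": float(t0),
                        "end_s": float(t1),
                        "label": label,
                        "starts_at_boundary": bool(start_cens),
                        "ends_at_boundary": bool(end_cens),
                    }
                )
        rows.extend(phases_tr)
    return pd.DataFrame(rows, columns=PHASE_COLUMNS)


def filter_phases(
    phases: pd.DataFrame,
    min_s: float = 1.0,
    max_s: float = 15.0,
    min_usable: int = 10,
    subject: str = "",
    fraction_samples_excluded: float = float("nan"),
) -> tuple[pd.DataFrame, QCReport]:
    """Flag phase usability and build the per-subject QC report.

    A phase is usable iff min_s <= duration <= max_s (strict exclusion:
    boundaries kept) and it is not censored by a trial boundary.  A subject
    with fewer than ``min_usable`` usable phases is excluded.
    """
    out = phases.copy()
    dur = out["end_s"] - out["start_s"]
    reason = np.full(len(out), "none", dtype=object)
    reason[(dur < min_s).to_numpy()] = "too_short"
    reason[(dur > max_s).to_numpy()] = "too_long"
    boundary = (out["starts_at_boundary"] | out["ends_at_boundary"]).to_numpy()
    reason[boundary & (reason == "none")] = "trial_boundary"
    out["duration_s"] = dur
    out["exclusion_reason"] = reason
    out["usable"] = reason == "none"
    n = len(out)
    usable = int(out["usable"].sum())
    report = QCReport(
        subject=subject,
        fraction_samples_excluded=fraction_samples_excluded,
        fraction_phases_excluded=(n - usable) / n if n else 1.0,
        usable_phase_count=usable,
        subject_excluded=usable < min_usable,
    )
    return out, report


def foreground_time_share(phases: pd.DataFrame) -> float:
    """Fraction of usable reporting time spent in the black-front percept."""
    if "usable" not in phases.columns:
        raise ValueError("run filter_phases first (no 'usable' column)")
    use = phases[phases["usable"]]
    total = (use["end_s"] - use["start_s"]).sum()
    if total <= 0:
        raise ValueError("no usable reporting time")
    black = use[use["label"] == BLACK_FRONT]
    return float((black["end_s"] - black["start_s"]).sum() / total)
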