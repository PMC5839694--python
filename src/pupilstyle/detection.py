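"""Scoring of the speed-increment detection tasks.

In the double-task condition, observers track the cylinder's perceived
rotation while pressing a bar whenever they detect a brief speed increment
on either dot surface.  A press within 2 s after an increment is a hit
(each increment can be credited at most once); a press more than 2 s away
from every increment is a false alarm.  Sensitivity is summarized as
d' = z(H) - z(F), separately for increments on the perceived front vs rear
surface.  The false-alarm denominator — never fully pinned down by verbal
descriptions of such tasks — is taken as the number of non-overlapping
window-sized bins of reporting time that contain no increment, so hit and
false-alarm rates are commensurate proportions.

The cued counting task (0-3 increments per brief trial, report the count
on the cued surface) is scored as exact-match percent correct, plus a d'
obtained by collapsing counts to per-opportunity detections (a documented
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DPrimeResult",
    "classify_presses",
    "surface_of_event",
    "dprime",
    "score_counting_task",
]


@dataclass(frozen=True)
class DPrimeResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    hits: int
    misses: int
    false_alarms: int
    fa_opportunities: int


def classify_presses(
    event_times,
    press_times,
    window: float = 2.0,
    attribute: str = "closest",
) -> tuple[np.ndarray, np.ndarray]:
    """Classify presses as hits or false alarms.

    A press is a hit for an event at most ``window`` seconds before it;
    when two events are eligible (possible, since events can be as little
    as 2 s apart), the press is attributed to the later — closer — event
    (``attribute='closest'``; ``'earliest'`` gives first-come scoring).
    Each event is credited at most one hit; surplus presses inside a
    credited window are ignored.  A press farther than ``window`` from
    *every* event (in either direction) is a false alarm.

    Returns ``(hit_mask_per_event, fa_mask_per_press)``.
    """
    if attribute not in ("closest", "earliest"):
        raise ValueError("attribute must be 'closest' or 'earliest'")
    ev = np.sort(np.asarray(event_times, dtype=float))
    pr = np.sort(np.asarray(press_times, dtype=float))
    hit = np.zeros(ev.size, dtype=bool)
    fa = np.zeros(pr.size, dtype=bool)
    for i, p in enumerate(pr):
        eligible = np.flatnonzero((p - ev >= 0) & (p - ev <= window) & ~hit)
        if eligible.size:
            j = eligible[-1] if attribute == "closest" else eligible[0]
            hit[j] = True
        else:
            # FA iff beyond the window from every event, credited or not
            if ev.size == 0 or np.min(np.abs(p - ev)) > window:
                fa[i] = True
            # else: surplus press inside an already-credited window; ignored
    return hit, fa


def surface_of_event(
    event_color: str,
    phase_label_at_event: str | None,
) -> str | None:
    """Perceived surface (front/rear) of an increment at its moment.

    An increment on the black dots is on the *front* surface iff the
    observer currently perceives the black surface in front.  Events
    falling in an unusable or unreported phase return ``None`` (excluded
    from scoring).
    """
    if event_color not in ("black", "white"):
        raise ValueError("event color must be 'black' or 'white'")
    if phase_label_at_event is None:
        return None
    front_color = "black" if phase_label_at_event == "black_front" else "white"
    return "front" if event_color == front_color else "rear"


def dprime(
    hits: int, n_events: int, false_alarms: int, n_fa_opportunities: int
) -> DPrimeResult:
    """d' from hit and false-alarm counts with the 1/(2N) edge correction.

    Rates of exactly 0 or 1 are replaced by 1/(2N) and 1 - 1/(2N)
    respectively (N the relevant trial count) before z-transforming.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    if n_fa_opportunities < 1:
        raise ValueError("need at least one false-alarm opportunity")

    def corrected(k: int, n: int) -> float:
        r = k / n
        if r <= 0:
            return 1.0 / (2 * n)
        if r >= 1:
            return 1.0 - 1.0 / (2 * n)
        return r

    h = corrected(hits, n_events)
    f = corrected(false_alarms, n_fa_opportunities)
    d = float(sps.norm.ppf(h) - sps.norm.ppf(f))
    return DPrimeResult(hit_rate=h, fa_rate=f, dprime=d, hits=hits,
                        misses=n_events - hits, false_alarms=false_alarms,
                        fa_opportunities=n_fa_opportunities)


def fa_opportunities(total_time: float, n_events: int, window: float = 2.0) -> int:
    """Number of event-free window-sized bins of reporting time.

    Non-overlapping bins of ``window`` seconds; each event occupies one, so
    opportunities = floor(total_time / window) - n_events, floored at 1.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    return max(1, int(total_time // window) - n_events)


def score_counting_task(
    reported_counts,
    true_counts,
    max_events: int = 3,
) -> tuple[float, float]:
    """Score the cued counting task: (percent correct, collapsed d').

    Percent correct is the exact-match fraction.  For d', each trial's
    ``max_events`` opportunity slots are collapsed to detections:
    min(reported, true) hits out of ``true`` signal slots, and
    max(reported - true, 0) false alarms out of the ``max_events - true``
    empty slots, pooled over trials.
    """
    rep = np.asarray(reported_counts, dtype=int)
    tru = np.asarray(true_counts, dtype=int)
    if rep.shape != tru.shape or rep.ndim != 1:
        raise ValueError("reported and true counts must be aligned 1-D arrays")
    if ((rep < 0) | (rep > max_events) | (tru < 0) | (tru > max_events)).any():
        raise ValueError(f"counts must lie in [0, {max_events}]")
    pc = float((rep == tru).mean() * 100.0)
    hits = int(np.minimum(rep, tru).sum())
    n_sig = int(tru.sum())
    fas = int(np.maximum(rep - tru, 0).sum())
    n_empty = int((max_events - tru).sum())
    if n_sig == 0 or n_empty == 0:
        return pc, math.nan
    return pc, dprime(hits, n_sig, fas, n_empty).dprime


def score_detection_run(
    events: pd.DataFrame,
    presses: pd.DataFrame,
    phases: pd.DataFrame | None = None,
    total_time: float | None = None,
    window: float = 2.0,
) -> dict:
    """Score one detection run, overall and by perceived surface.

    ``events`` needs columns ``t_s`` and ``dot_color``; ``presses`` needs
    ``t_s``.  With a filtered phase table, events are split into front/rear
    by the concurrent percept (events in unusable phases are dropped from
    the by-surface scores but still shield presses from being FAs).
    Returns a dict of :class:`DPrimeResult` under keys ``overall`` and,
    when phases are given, ``front`` and ``rear``, plus ``excluded_events``.
    """
    ev_t = events["t_s"].to_numpy(dtype=float)
    pr_t = presses["t_s"].to_numpy(dtype=float)
    horizon = total_time if total_time is not None else (
        float(max(ev_t.max() if ev_t.size else 0.0,
                  pr_t.max() if pr_t.size else 0.0)) + window)
    order = np.argsort(ev_t)
    hit, fa = classify_presses(ev_t[order], pr_t, window=window)
    n_fa_opp = fa_opportunities(horizon, ev_t.size, window)
    out = {
        "overall": dprime(int(hit.sum()), ev_t.size, int(fa.sum()), n_fa_opp),
        "excluded_events": 0,
    }
    if phases is not None:
        colors = events["dot_color"].to_numpy()[order]
        surf = []
        for t, c in zip(ev_t[order], colors):
            sel = phases[(phases["start_s"] <= t) & (phases["end_s"] > t)
                         & phases["usable"]]
            label = sel.iloc[0]["label"] if len(sel) else None
            surf.append(surface_of_event(c, label))
        surf = np.asarray(surf, dtype=object)
        out["excluded_events"] = int((surf == None).sum())  # noqa: E711
        # split the FA budget evenly: FAs are surface-less by definition
        for which in ("front", "rear"):
            m = surf == which
            if m.sum() == 0:
                continue
            out[which] = dprime(int(hit[m].sum()), int(m.sum()),
                                int(fa.sum()), n_fa_opp)
    return out
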