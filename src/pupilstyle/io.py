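"""Readers and writers for the plain-text pipeline formats.

All time series travel as TSV, questionnaire responses as CSV, reports and
manifests as JSON — diff-able and tracker-agnostic (conversion from
proprietary eye-tracker formats happens upstream).

Schemas
-------
samples.tsv   subject  trial  t_s  pupil_mm  gaze_x_deg  gaze_y_deg
percepts.tsv  subject  trial  t_s  key_state
events.tsv    subject  trial  t_s  dot_color  kind
presses.tsv   subject  trial  t_s
aq_responses.csv  subject  item_01..item_50  (codes 1-4)
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_samples",
    "read_percepts",
    "read_events",
    "read_presses",
    "read_aq",
    "write_samples",
    "write_percepts",
    "write_events",
    "recordings_from_samples",
]

SAMPLES_COLUMNS = ["subject", "trial", "t_s", "pupil_mm",
                   "gaze_x_deg", "gaze_y_deg"]
PERCEPTS_COLUMNS = ["subject", "trial", "t_s", "key_state"]
EVENTS_COLUMNS = ["subject", "trial", "t_s", "dot_color", "kind"]
PRESSES_COLUMNS = ["subject", "trial", "t_s"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _check_monotone(df: pd.DataFrame, path) -> None:
    for (subj, trial), grp in df.groupby(["subject", "trial"], sort=False):
        t = grp["t_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise ValueError(
                f"{path}: non-monotone or duplicated timestamp at row {row} "
                f"(subject {subj}, trial {trial})"
            )


def read_samples(path) -> pd.DataFrame:
    """Read and validate a pupil-samples TSV."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SAMPLES_COLUMNS[:4], path)
    _check_monotone(df, path)
    med = float(df["pupil_mm"].median())
    if med > 10.0:
        warnings.warn(
            f"{path}: median pupil {med:.1f} looks like pixels, not mm",
            stacklevel=2,
        )
    return df


def read_percepts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PERCEPTS_COLUMNS, path)
    _check_monotone(df, path)
    return df


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENTS_COLUMNS[:4], path)
    _check_monotone(df, path)
    return df


def read_presses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PRESSES_COLUMNS, path)
    return df


def read_aq(path) -> pd.DataFrame:
    """Read an AQ response CSV (one row per subject, item_01..item_50)."""
    df = pd.read_csv(path)
    items = [f"item_{i:02d}" for i in range(1, 51)]
    _require_columns(df, ["subject"] + items, path)
    vals = df[items].to_numpy()
    if not np.isin(vals, [1, 2, 3, 4]).all():
        bad = np.argwhere(~np.isin(vals, [1, 2, 3, 4]))[0]
        raise ValueError(
            f"{path}: invalid response code at row {bad[0]}, {items[bad[1]]}"
        )
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_percepts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def recordings_from_samples(df: pd.DataFrame, sample_rate: float | None = None):
    """Split a samples table into per-subject :class:`PupilRecording`s."""
    from .preprocess import PupilRecording

    out = {}
    for subj, grp in df.groupby("subject", sort=True):
        if sample_rate is None:
            dt = float(np.median(np.diff(grp["t_s"].to_numpy()[:1000])))
            rate = round(1.0 / dt)
        else:
            rate = sample_rate
        out[str(subj)] = PupilRecording(
            t_s=grp["t_s"].to_numpy(dtype=float),
            pupil_mm=grp["pupil_mm"].to_numpy(dtype=float),
            trial=grp["trial"].to_numpy(),
            sample_rate=float(rate),
            subject=str(subj),
            gaze_x_deg=grp["gaze_x_deg"].to_numpy(dtype=float)
            if "gaze_x_deg" in grp else None,
            gaze_y_deg=grp["gaze_y_deg"].to_numpy(dtype=float)
            if "gaze_y_deg" in grp else None,
        )
    return out
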