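"""End-to-end orchestration: files in, subject summaries and stats out.

Stage order: preprocessing (sample masking, phase segmentation and
filtering) → epoching → per-subject indices → detection scoring (when the
experiment has one) → cross-subject inference.  Subjects excluded by the
QC rules are reported with their reason, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aq as aqmod
from . import detection as det
from . import epochs as ep
from . import io as psio
from . import preprocess as pre
from . import stats as st
from .config import AnalysisConfig

__all__ = ["run_experiment", "analyze_subject"]


def analyze_subject(rec, percept_stream, config: AnalysisConfig) -> dict:
    """Run preprocessing + epoching + indices for one subject.

    Returns a dict with the QC report, the filtered phase table, the epoch
    list, and the summary indices (NaN where the subject is excluded).
    """
    mask = pre.mask_pupil_samples(rec, config.pupil_min_mm, config.pupil_max_mm)
    phases = pre.segment_phases(percept_stream,
                                gap_tolerance_s=config.gap_tolerance_s)
    phases, qc = pre.filter_phases(
        phases, config.phase_min_s, config.phase_max_s,
        config.min_usable_phases, subject=rec.subject,
        fraction_samples_excluded=float(1.0 - mask.mean()),
    )
    total_time = 0.0
    for _, grp in percept_stream.groupby("trial"):
        t = grp["t_s"].to_numpy(dtype=float)
        if t.size > 1:
            total_time += float(t[-1] - t[0] + np.median(np.diff(t)))
    out = {
        "qc": qc,
        "phases": phases,
        "epochs": [],
        "dropped_epochs": [],
        "luminance_modulation": np.nan,
        "general_dilation": np.nan,
        "switch_rate": ep.switch_rate(phases, total_time) if total_time else np.nan,
        "significant_positive": None,
    }
    if qc.subject_excluded:
        return out
    epochs, dropped = ep.extract_switch_epochs(
        rec, phases, window=tuple(config.switch_window_s),
        analysis_rate=config.analysis_rate_hz, baseline_s=config.baseline_s,
    )
    out["epochs"] = epochs
    out["dropped_epochs"] = dropped
    try:
        out["luminance_modulation"] = ep.luminance_modulation(
            epochs, mode=config.index_mode)
        out["general_dilation"] = ep.general_dilation(epochs)
    except ValueError:
        pass  # a percept never reported: indices stay NaN
    flag, _ = ep.per_subject_significance(epochs)
    out["significant_positive"] = flag
    return out


def run_experiment(
    config: AnalysisConfig,
    data_dir: str | Path,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full analysis over a data directory.

    Expects ``samples.tsv``, ``percepts.tsv`` and ``aq_responses.csv``
    under ``data_dir`` (plus ``events.tsv``/``presses.tsv`` for the
    double-task experiment).  Returns ``(subject_summary, stats_report)``
    and, with ``out_dir``, writes ``subject_summary.csv``,
    ``stats_report.json``, mean-trace TSVs and a run manifest.
    """
    data_dir = Path(data_dir)
    samples = psio.read_samples(data_dir / "samples.tsv")
    percepts = psio.read_percepts(data_dir / "percepts.tsv")
    aq_df = psio.read_aq(data_dir / "aq_responses.csv")
    recs = psio.recordings_from_samples(samples)
    aq_scores = aqmod.score_aq_frame(aq_df).set_index("subject")

    cues = events = presses = None
    if config.experiment == "feature_attention":
        cue_path = data_dir / "cues.tsv"
        if not cue_path.exists():
            raise ValueError(
                "feature_attention requires cues.tsv (subject, trial, t_s, "
                "cue) — this looks like switch-report data")
        cues = pd.read_csv(cue_path, sep="\t")
        missing = {"subject", "trial", "t_s", "cue"} - set(cues.columns)
        if missing:
            raise ValueError(f"cues.tsv: missing column(s) {sorted(missing)}")
    if config.experiment == "double_task":
        events = psio.read_events(data_dir / "events.tsv")
        presses = psio.read_presses(data_dir / "presses.tsv")

    rows = []
    all_epochs = []
    for subj, rec in recs.items():
        stream = percepts[percepts["subject"] == subj]
        try:
            res = analyze_subject(rec, stream, config)
        except Exception as exc:  # stage failure aborts with context
            raise RuntimeError(
                f"analysis failed at subject {subj}: {exc}") from exc
        qc = res["qc"]
        extra: dict = {}
        if cues is not None:
            sc = cues[cues["subject"] == subj]
            onset_eps, _ = ep.extract_onset_epochs(
                rec, sc["t_s"].to_numpy(), sc["cue"].map(
                    {"black": "black_cued", "white": "white_cued"}),
                window=tuple(config.onset_window_s),
                analysis_rate=config.analysis_rate_hz,
                baseline_s=config.baseline_s, trials=sc["trial"].tolist())
            try:
                extra["attention_modulation_mm"] = ep.attention_modulation(
                    onset_eps, window=tuple(config.attention_window_s))
            except (ValueError, StopIteration):
                extra["attention_modulation_mm"] = np.nan
        if events is not None:
            dp = _score_detection_by_trial(
                events[events["subject"] == subj],
                presses[presses["subject"] == subj],
                res["phases"], window=config.detection_window_s)
            extra.update(dp)
        rows.append({
            "subject": subj,
            **extra,
            "aq_total": int(aq_scores.loc[subj, "total"])
            if subj in aq_scores.index else np.nan,
            "luminance_modulation_mm": res["luminance_modulation"],
            "general_dilation_mm": res["general_dilation"],
            "switch_rate_hz": res["switch_rate"],
            "n_usable_phases": qc.usable_phase_count,
            "fraction_samples_excluded": qc.fraction_samples_excluded,
            "fraction_phases_excluded": qc.fraction_phases_excluded,
            "excluded": qc.subject_excluded,
            "significant_positive": res["significant_positive"],
        })
        all_epochs.extend(res["epochs"])
    summary = pd.DataFrame(rows)

    ok = summary[~summary["excluded"]
                 & summary["luminance_modulation_mm"].notna()
                 & summary["aq_total"].notna()]
    report: dict = {
        "experiment": config.experiment,
        "n_subjects": int(len(summary)),
        "n_analyzed": int(len(ok)),
        "n_excluded": int(summary["excluded"].sum()),
        "n_significant_positive": int(
            (summary["significant_positive"] == True).sum()),  # noqa: E712
        "mean_switch_rate_hz": float(summary["switch_rate_hz"].mean()),
        "mean_fraction_phases_excluded": float(
            summary["fraction_phases_excluded"].mean()),
    }
    if len(ok) >= 4:
        lum = st.pearson_full(ok["aq_total"], ok["luminance_modulation_mm"],
                              ci_level=config.ci_level,
                              bf_scale=config.bf_prior_scale)
        gen = st.pearson_full(ok["aq_total"], ok["general_dilation_mm"],
                              ci_level=config.ci_level,
                              bf_scale=config.bf_prior_scale)
        report["aq_vs_luminance_modulation"] = asdict(lum)
        report["aq_vs_general_dilation"] = asdict(gen)
    if "attention_modulation_mm" in summary.columns:
        okf = summary[summary["attention_modulation_mm"].notna()
                      & summary["aq_total"].notna()]
        if len(okf) >= 4:
            report["aq_vs_attention_modulation"] = asdict(st.pearson_full(
                okf["aq_total"], okf["attention_modulation_mm"],
                ci_level=config.ci_level, bf_scale=config.bf_prior_scale))
    if "dprime_front" in summary.columns:
        okd = summary[summary["dprime_front"].notna()
                      & summary["dprime_rear"].notna()]
        if len(okd) >= 2:
            t, df, p = st.paired_t(okd["dprime_front"], okd["dprime_rear"])
            report["front_vs_rear_dprime"] = {"t": t, "df": df, "p": p}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "subject_summary.csv", index=False)
        (out_dir / "stats_report.json").write_text(
            json.dumps(report, indent=1, default=str))
        if all_epochs:
            _write_mean_traces(all_epochs, out_dir / "mean_traces.tsv")
        manifest = {
            "config": config.to_dict(),
            "inputs": {p.name: _sha256(p) for p in sorted(data_dir.glob("*"))
                       if p.is_file()},
            "n_subjects": int(len(summary)),
            "n_epochs": len(all_epochs),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary, report


def _score_detection_by_trial(events, presses, phases, window=2.0) -> dict:
    """Pool hits/FAs over trials and derive overall + by-surface d'."""
    counts = {k: dict(hits=0, events=0, fas=0, opps=0)
              for k in ("overall", "front", "rear")}
    for tr in sorted(set(events["trial"]).union(presses["trial"])):
        ev = events[events["trial"] == tr].sort_values("t_s")
        pr = presses[presses["trial"] == tr].sort_values("t_s")
        ph = phases[phases["trial"] == tr]
        total = float(ph["end_s"].max()) if len(ph) else (
            float(ev["t_s"].max()) + window if len(ev) else 0.0)
        if total <= 0:
            continue
        run = det.score_detection_run(ev, pr, phases=ph, total_time=total,
                                      window=window)
        for k in counts:
            if k in run:
                counts[k]["hits"] += run[k].hits
                counts[k]["events"] += run[k].hits + run[k].misses
                counts[k]["fas"] += run[k].false_alarms
                counts[k]["opps"] += run[k].fa_opportunities
    out = {}
    for k, c in counts.items():
        col = f"dprime_{k}"
        if c["events"] >= 1 and c["opps"] >= 1:
            out[col] = det.dprime(c["hits"], c["events"], c["fas"],
                                  c["opps"]).dprime
        else:
            out[col] = np.nan
    return out


def _write_mean_traces(epochs, path) -> None:
    traces = ep.mean_traces(epochs)
    rows = []
    for (label, side), d in traces.items():
        for t, m, s, n in zip(d["t"], d["mean"], d["sem"], d["n"]):
            rows.append({"label": label, "side": side, "t_s": t,
                         "mean_mm": m, "sem_mm": s, "n": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
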