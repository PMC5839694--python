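"""Analysis configuration: every threshold/window of the pipeline in one
validated object, loadable from YAML.  The shipped ``paper_defaults.yaml``
holds the published analysis constants; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "paper_defaults"]

EXPERIMENTS = ("main", "swapped", "feature_attention", "double_task",
               "instruction")


@dataclass
class AnalysisConfig:
    experiment: str = "main"
    pupil_min_mm: float = 1.0
    pupil_max_mm: float = 7.0
    phase_min_s: float = 1.0
    phase_max_s: float = 15.0
    min_usable_phases: int = 10
    gap_tolerance_s: float = 0.2
    analysis_rate_hz: float = 60.0
    baseline_ms: float = 150.0
    switch_window_s: list = field(default_factory=lambda: [-1.0, 1.0])
    onset_window_s: list = field(default_factory=lambda: [0.0, 6.0])
    attention_window_s: list = field(default_factory=lambda: [1.0, 3.0])
    index_mode: str = "pre_post"
    detection_window_s: float = 2.0
    ci_level: float = 0.95
    bf_prior_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        if not (0 < self.pupil_min_mm < self.pupil_max_mm):
            raise ValueError("require 0 < pupil_min_mm < pupil_max_mm")
        if not (0 < self.phase_min_s < self.phase_max_s):
            raise ValueError("require 0 < phase_min_s < phase_max_s")
        if self.min_usable_phases < 0:
            raise ValueError("min_usable_phases must be >= 0")
        if self.analysis_rate_hz <= 0 or self.baseline_ms <= 0:
            raise ValueError("analysis_rate_hz and baseline_ms must be positive")
        if self.index_mode not in ("pre_post", "post"):
            raise ValueError("index_mode must be 'pre_post' or 'post'")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.bf_prior_scale <= 0:
            raise ValueError("bf_prior_scale must be positive")

    @property
    def baseline_s(self) -> float:
        return self.baseline_ms / 1000.0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(raw, source=str(path))


def _from_dict(raw: dict, source: str = "<dict>") -> AnalysisConfig:
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{source}: unknown config key(s) {sorted(unknown)}")
    return AnalysisConfig(**raw)


def paper_defaults() -> AnalysisConfig:
    """The shipped published-analysis defaults."""
    text = resources.files("pupilstyle.data").joinpath(
        "paper_defaults.yaml").read_text()
    return _from_dict(yaml.safe_load(text), source="paper_defaults.yaml")
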