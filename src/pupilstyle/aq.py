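"""Autism-Spectrum Quotient (AQ-50) scoring.

The AQ is a 50-item self-report questionnaire with five 10-item subscales
(social skills, attention switching, attention to detail, communication,
imagination).  Each item is answered on a 4-level Likert scale and scored
binary: 1 if the response is in the ASD-characteristic direction for that
item (slightly or strongly — the two grades collapse), 0 otherwise.  Totals
range 0–50; a total of 32 or more is the conventional threshold at which a
clinical assessment is recommended.

The item→subscale assignment and keyed directions ship as a versioned data
file (``data/aq_key.json``) following the standard published scoring key.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats as sps

__all__ = [
    "SUBSCALES",
    "CLINICAL_THRESHOLD",
    "load_key",
    "AQResult",
    "score_aq",
    "score_aq_frame",
    "corrected_totals",
    "check_normality",
]

SUBSCALES = (
    "social_skills",
    "attention_switching",
    "attention_to_detail",
    "communication",
    "imagination",
)

CLINICAL_THRESHOLD = 32

_AGREE_CODES = {1, 2}      # strongly_agree, slightly_agree
_DISAGREE_CODES = {3, 4}   # slightly_disagree, strongly_disagree


def load_key() -> dict:
    """Load the shipped AQ-50 scoring key (item -> subscale, keyed direction)."""
    text = resources.files("pupilstyle.data").joinpath("aq_key.json").read_text()
    key = json.loads(text)
    items = key["items"]
    if len(items) != 50:
        raise ValueError("AQ key must define exactly 50 items")
    counts: dict[str, int] = {}
    for spec in items.values():
        counts[spec["subscale"]] = counts.get(spec["subscale"], 0) + 1
    if set(counts) != set(SUBSCALES) or any(c != 10 for c in counts.values()):
        raise ValueError("AQ key must assign 10 items to each of the 5 subscales")
    return key


@dataclass(frozen=True)
class AQResult:
    subject: str
    total: int
    subscales: dict = field(default_factory=dict)

    @property
    def clinical_flag(self) -> bool:
        return self.total >= CLINICAL_THRESHOLD

    def __post_init__(self):
        if sum(self.subscales.values()) != self.total:
            raise ValueError("subscale scores must sum to the total")


def score_aq(responses, key: dict | None = None, subject: str = "") -> AQResult:
    """Score one AQ-50 response set.

    Parameters
    ----------
    responses : mapping ``item_01`` .. ``item_50`` -> integer code 1–4
        (1 strongly agree, 2 slightly agree, 3 slightly disagree,
        4 strongly disagree), or a sequence of 50 such codes in item order.
    key : scoring key as returned by :func:`load_key` (default: shipped key).

    An item scores 1 iff its response direction (agree vs disagree,
    collapsing slight/strong) matches the keyed ASD-characteristic
    direction.  Missing or invalid responses raise, naming the item.
    """
    key = key or load_key()
    if not isinstance(responses, dict):
        seq = list(responses)
        if len(seq) != 50:
            raise ValueError(f"expected 50 responses, got {len(seq)}")
        responses = {f"item_{i + 1:02d}": v for i, v in enumerate(seq)}

    sub_scores = {s: 0 for s in SUBSCALES}
    for item, spec in key["items"].items():
        if item not in responses or responses[item] is None:
            raise ValueError(f"missing response for {item}")
        code = responses[item]
        if isinstance(code, float) and math.isnan(code):
            raise ValueError(f"missing response for {item}")
        code = int(code)
        if code in _AGREE_CODES:
            direction = "agree_is_autistic"
        elif code in _DISAGREE_CODES:
            direction = "disagree_is_autistic"
        else:
            raise ValueError(f"invalid response code {code!r} for {item}")
        if direction == spec["keyed_direction"]:
            sub_scores[spec["subscale"]] += 1
    return AQResult(subject=subject, total=sum(sub_scores.values()),
                    subscales=sub_scores)


def score_aq_frame(df, key: dict | None = None):
    """Score a DataFrame of AQ responses (one row per subject).

    Expects columns ``subject`` and ``item_01``..``item_50``; returns a
    DataFrame with ``subject``, ``total``, one column per subscale, and
    ``clinical_flag``.
    """
    import pandas as pd

    key = key or load_key()
    rows = []
    for _, row in df.iterrows():
        res = score_aq(
            {c: row[c] for c in df.columns if c.startswith("item_")},
            key=key,
            subject=str(row.get("subject", "")),
        )
        rows.append({"subject": res.subject, "total": res.total,
                     **res.subscales, "clinical_flag": res.clinical_flag})
    return pd.DataFrame(rows)


def corrected_totals(subscale_matrix) -> np.ndarray:
    """Per-subscale "sum of the other four subscales".

    Given an (n_subjects, 5) matrix, returns an (n_subjects, 5) matrix whose
    column j is total - subscale_j for each subject.
    """
    m = np.asarray(subscale_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 5:
        raise ValueError("expected an (n_subjects, 5) subscale matrix")
    return m.sum(axis=1, keepdims=True) - m


def check_normality(values, method: str = "asymptotic",
                    n_mc: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Jarque–Bera composite-normality test.

    JB = n/6 * (S^2 + K^2/4) with sample skewness S and excess kurtosis K.
    ``method='asymptotic'`` uses the chi-square(2) reference; for small
    samples the asymptotic p is anticonservative, so ``method='monte_carlo'``
    simulates the null at the observed n (``n_mc`` replicates).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("Jarque-Bera needs n >= 8")

    def jb_stat(a: np.ndarray) -> float:
        m = a.mean()
        d = a - m
        s2 = (d**2).mean()
        S = (d**3).mean() / s2**1.5
        K = (d**4).mean() / s2**2 - 3.0
        return a.shape[-1] / 6.0 * (S * S + K * K / 4.0)

    jb = jb_stat(x)
    if method == "asymptotic":
        p = float(sps.chi2.sf(jb, 2))
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        null = rng.standard_normal((n_mc, n))
        m = null.mean(axis=1, keepdims=True)
        d = null - m
        s2 = (d**2).mean(axis=1)
        S = (d**3).mean(axis=1) / s2**1.5
        K = (d**4).mean(axis=1) / s2**2 - 3.0
        jb_null = n / 6.0 * (S * S + K * K / 4.0)
        p = float((np.sum(jb_null >= jb) + 1) / (n_mc + 1))
    else:
        raise ValueError("method must be 'asymptotic' or 'monte_carlo'")
    return float(jb), p
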