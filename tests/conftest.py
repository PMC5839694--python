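import numpy as np
import pandas as pd
import pytest

from pupilstyle import preprocess as pre
from pupilstyle.synthetic import (
    CohortParams,
    PerceptDynamicsParams,
    PupilModelParams,
    gen_cohort,
)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 5-subject synthetic cohort written to disk (shared, read-only)."""
    d = tmp_path_factory.mktemp("cohort")
    gen_cohort(CohortParams(n_subjects=5, seed=42), out_dir=d)
    return d


@pytest.fixture(scope="session")
def default_dynamics():
    return PerceptDynamicsParams(seed=0)


@pytest.fixture(scope="session")
def default_pupil():
    return PupilModelParams()


def make_recording(pupil_mm, rate=60.0, subject="s", trial=0):
    """Wrap a raw pupil vector as a masked single-trial recording."""
    p = np.asarray(pupil_mm, dtype=float)
    rec = pre.PupilRecording(
        t_s=np.arange(p.size) / rate,
        pupil_mm=p,
        trial=np.full(p.size, trial),
        sample_rate=rate,
        subject=subject,
    )
    pre.mask_pupil_samples(rec)
    return rec


def make_phases(spans, trial=0, usable=None):
    """Phase table from (start, end, label) triples, pre-filtered."""
    df = pd.DataFrame(
        [{"trial": trial, "start_s": s, "end_s": e, "label": lab,
          "starts_at_boundary": False, "ends_at_boundary": False}
         for s, e, lab in spans]
    )
    df["duration_s"] = df["end_s"] - df["start_s"]
    df["exclusion_reason"] = "none"
    df["usable"] = True if usable is None else usable
    return df
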