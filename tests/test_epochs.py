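"""Epoch extraction, baseline rules, and the summary indices."""

import numpy as np
import pytest

from conftest import make_phases, make_recording
from pupilstyle import epochs as ep
from pupilstyle.preprocess import BLACK_FRONT, WHITE_FRONT


def pre_recording_two_trials(n, rate):
    """Two constant-level trials with trial-relative clocks."""
    from pupilstyle.preprocess import PupilRecording, mask_pupil_samples

    t = np.tile(np.arange(n) / rate, 2)
    rec = PupilRecording(
        t_s=t,
        pupil_mm=np.concatenate([np.full(n, 3.0), np.full(n, 4.0)]),
        trial=np.repeat([0, 1], n),
        sample_rate=rate,
        subject="s",
    )
    mask_pupil_samples(rec)
    return rec


def alternating_phases(n=12, dur=5.0):
    spans = []
    t = 0.0
    for i in range(n):
        lab = BLACK_FRONT if i % 2 == 0 else WHITE_FRONT
        spans.append((t, t + dur, lab))
        t += dur
    return make_phases(spans)


class TestSwitchEpochs:
    def test_constant_trace_corrects_to_zero(self):
        rec = make_recording(np.full(3600, 3.2))
        phases = alternating_phases()
        eps, dropped = ep.extract_switch_epochs(rec, phases)
        assert not dropped
        for e in eps:
            np.testing.assert_allclose(e.trace, 0.0, atol=1e-12)

    def test_step_at_switch_absorbed_by_own_side_baselines(self):
        """A 3.0 -> 3.1 step exactly at a switch leaves both corrected
        sides flat at zero: each side's baseline sees its own level."""
        rate = 60.0
        t = np.arange(1200) / rate
        y = np.where(t < 10.0, 3.0, 3.1)
        rec = make_recording(y)
        phases = make_phases([(5.0, 10.0, BLACK_FRONT),
                              (10.0, 15.0, WHITE_FRONT)])
        eps, _ = ep.extract_switch_epochs(rec, phases)
        for e in eps:
            if e.align_time == 10.0:
                np.testing.assert_allclose(e.trace, 0.0, atol=1e-9)

    def test_post_side_labeled_by_destination(self):
        rec = make_recording(np.full(3600, 3.0))
        phases = alternating_phases()
        eps, _ = ep.extract_switch_epochs(rec, phases)
        for e in eps:
            assert e.side in ("pre", "post")
            assert e.label in (BLACK_FRONT, WHITE_FRONT)
        # the switch at t=5 goes black -> white
        post5 = [e for e in eps if e.align_time == 5.0 and e.side == "post"]
        pre5 = [e for e in eps if e.align_time == 5.0 and e.side == "pre"]
        assert post5[0].label == WHITE_FRONT and pre5[0].label == BLACK_FRONT

    def test_invalid_baseline_drops_epoch(self):
        y = np.full(3600, 3.0)
        y[288:306] = 0.5  # blink covering the pre-baseline of the t=5 switch
        rec = make_recording(y)
        phases = alternating_phases()
        eps, dropped = ep.extract_switch_epochs(rec, phases)
        reasons = {(d["align_time"], d["side"]) for d in dropped}
        assert (5.0, "pre") in reasons

    def test_unusable_phase_contributes_no_side(self):
        phases = alternating_phases()
        phases.loc[1, "usable"] = False
        rec = make_recording(np.full(3600, 3.0))
        eps, _ = ep.extract_switch_epochs(rec, phases)
        assert not any(
            e.label == WHITE_FRONT and e.align_time in (5.0, 10.0) for e in eps
            if e.trial == 0 and e.align_time == 5.0
        )
        # phase 1 (white, 5-10 s) is unusable: no post at 5, no pre at 10
        assert not any(e.side == "post" and e.align_time == 5.0 for e in eps)
        assert not any(e.side == "pre" and e.align_time == 10.0 for e in eps)


class TestOnsetEpochs:
    def test_constant_trace_zero(self):
        rec = make_recording(np.full(1200, 4.0))
        eps, _ = ep.extract_onset_epochs(rec, [5.0, 10.0],
                                         ["black_cued", "white_cued"],
                                         window=(0.0, 6.0))
        assert len(eps) == 2
        for e in eps:
            np.testing.assert_allclose(e.trace, 0.0, atol=1e-12)
        assert [e.label for e in eps] == ["black_cued", "white_cued"]

    def test_trial_relative_onsets(self):
        """Onset times that restart with each trial resolve per trial."""
        rate = 60.0
        n = 600  # 10 s per trial
        rec = pre_recording_two_trials(n, rate)
        eps, dropped = ep.extract_onset_epochs(
            rec, [5.0, 5.0, 5.0], ["black_cued", "white_cued", "black_cued"],
            window=(0.0, 3.0), trials=[0, 1, 99])
        assert len(eps) == 2
        assert {e.trial for e in eps} == {0, 1}
        assert dropped[0]["reason"] == "unknown_trial"
        for e in eps:
            np.testing.assert_allclose(e.trace, 0.0, atol=1e-12)

    def test_linear_ramp_recovered(self):
        rate = 60.0
        t = np.arange(1200) / rate
        a = 0.02
        y = 3.0 + a * np.clip(t - 5.0, 0.0, None)
        rec = make_recording(y)
        eps, _ = ep.extract_onset_epochs(rec, [5.0], ["black_cued"],
                                         window=(0.0, 6.0))
        e = eps[0]
        np.testing.assert_allclose(e.trace, a * e.t, atol=1e-9)


class TestIndices:
    def constant_label_epochs(self, black_val, white_val, n=4):
        """Half-epochs with constant separation on both sides."""
        grid_pre = np.arange(-60, 0) / 60.0
        grid_post = np.arange(0, 60) / 60.0
        eps = []
        for i in range(n):
            for side, grid in (("pre", grid_pre), ("post", grid_post)):
                eps.append(ep.Epoch(t=grid, trace=np.full(60, black_val),
                                    label=BLACK_FRONT, side=side,
                                    align_time=float(i), subject="s"))
                eps.append(ep.Epoch(t=grid, trace=np.full(60, white_val),
                                    label=WHITE_FRONT, side=side,
                                    align_time=float(i), subject="s"))
        return eps

    def test_worked_arithmetic(self):
        eps = self.constant_label_epochs(+0.02, -0.01)
        assert ep.luminance_modulation(eps) == pytest.approx(0.03)

    def test_identical_labels_zero(self):
        eps = self.constant_label_epochs(0.015, 0.015)
        assert ep.luminance_modulation(eps) == pytest.approx(0.0)

    def test_label_swap_negates_exactly(self):
        eps = self.constant_label_epochs(0.021, -0.007)
        swapped = [
            ep.Epoch(t=e.t, trace=e.trace,
                     label=WHITE_FRONT if e.label == BLACK_FRONT else BLACK_FRONT,
                     side=e.side, align_time=e.align_time, subject=e.subject)
            for e in eps
        ]
        assert ep.luminance_modulation(swapped) == pytest.approx(
            -ep.luminance_modulation(eps), abs=1e-15)

    def test_post_only_mode_on_antisymmetric_fixture(self):
        """When pre and post diffs are equal, the two modes agree."""
        eps = self.constant_label_epochs(0.01, -0.01)
        assert ep.luminance_modulation(eps, mode="post") == pytest.approx(
            ep.luminance_modulation(eps, mode="pre_post"))

    def test_missing_label_raises(self):
        eps = [e for e in self.constant_label_epochs(0.01, 0.0)
               if e.label == BLACK_FRONT]
        with pytest.raises(ValueError, match="white_front"):
            ep.luminance_modulation(eps)

    def test_general_dilation_pools_labels(self):
        eps = self.constant_label_epochs(0.04, 0.02)
        assert ep.general_dilation(eps) == pytest.approx(0.03)

    def test_modulation_only_general_dilation_cancels(self):
        eps = self.constant_label_epochs(0.025, -0.025)
        assert ep.general_dilation(eps) == pytest.approx(0.0)

    def test_attention_modulation_constant_separation(self):
        grid = np.arange(0, 360) / 60.0
        eps = [
            ep.Epoch(t=grid, trace=np.full(360, 0.05), label="black_cued",
                     side="onset", align_time=0.0, subject="s"),
            ep.Epoch(t=grid, trace=np.full(360, 0.01), label="white_cued",
                     side="onset", align_time=0.0, subject="s"),
        ]
        assert ep.attention_modulation(eps) == pytest.approx(0.04)

    def test_baseline_idempotent(self):
        """Re-applying the baseline rule to a corrected epoch is a no-op."""
        rate = 60.0
        t = np.arange(3600) / rate
        rec = make_recording(3.0 + 0.05 * np.sin(t))
        phases = alternating_phases()
        eps, _ = ep.extract_switch_epochs(rec, phases)
        for e in eps[:6]:
            sel = (e.t < 0.15) if e.side == "post" else (e.t >= -0.15)
            again = e.trace - np.nanmean(e.trace[sel])
            np.testing.assert_allclose(again, e.trace, atol=1e-12)

    def test_constant_offset_invariance(self):
        rate = 60.0
        t = np.arange(3600) / rate
        base = 3.0 + 0.05 * np.sin(0.7 * t)
        phases = alternating_phases()
        i1 = ep.luminance_modulation(
            ep.extract_switch_epochs(make_recording(base), phases)[0])
        i2 = ep.luminance_modulation(
            ep.extract_switch_epochs(make_recording(base + 1.3), phases)[0])
        assert i1 == pytest.approx(i2, abs=1e-12)


class TestSwitchRateAndSignificance:
    def test_deterministic_alternation_rate(self):
        """Deterministic 5-s alternation approaches 0.2 switches/s."""
        n = 121
        phases = alternating_phases(n=n, dur=5.0)
        phases.loc[n - 1, "ends_at_boundary"] = True  # censored by trial end
        rate = ep.switch_rate(phases, n * 5.0)
        assert rate == pytest.approx(0.2, rel=0.01)

    def test_single_phase_zero_switches(self):
        phases = make_phases([(0.0, 59.0, BLACK_FRONT)])
        phases["ends_at_boundary"] = True
        assert ep.switch_rate(phases, 59.0) == 0.0

    def test_separated_distributions_flagged(self):
        rng = np.random.default_rng(0)
        grid = np.arange(0, 60) / 60.0
        eps = []
        for i in range(20):
            eps.append(ep.Epoch(grid, np.full(60, 0.05 + 0.001 * rng.standard_normal()),
                                BLACK_FRONT, "post", float(i), subject="s"))
            eps.append(ep.Epoch(grid, np.full(60, -0.05 + 0.001 * rng.standard_normal()),
                                WHITE_FRONT, "post", float(i), subject="s"))
        flag, reason = ep.per_subject_significance(eps)
        assert flag is True

    def test_null_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        grid = np.arange(0, 60) / 60.0
        flags = []
        for _ in range(400):
            eps = []
            for i in range(15):
                for lab in (BLACK_FRONT, WHITE_FRONT):
                    eps.append(ep.Epoch(grid,
                                        np.full(60, rng.standard_normal()),
                                        lab, "post", float(i), subject="s"))
            flags.append(ep.per_subject_significance(eps)[0])
        rate = np.mean([f for f in flags if f is not None])
        assert rate == pytest.approx(0.05, abs=0.035)

    def test_insufficient_epochs_undefined(self):
        grid = np.arange(0, 60) / 60.0
        eps = [ep.Epoch(grid, np.zeros(60), BLACK_FRONT, "post", 0.0, subject="s")]
        flag, reason = ep.per_subject_significance(eps)
        assert flag is None and "insufficient" in reason


class TestMeanTraces:
    def test_symmetric_pair(self):
        grid = np.arange(0, 60) / 60.0
        c = 0.02
        eps = [
            ep.Epoch(grid, np.full(60, +c), BLACK_FRONT, "post", 0.0, subject="a"),
            ep.Epoch(grid, np.full(60, -c), BLACK_FRONT, "post", 0.0, subject="b"),
        ]
        out = ep.mean_traces(eps)
        d = out[(BLACK_FRONT, "post")]
        np.testing.assert_allclose(d["mean"], 0.0, atol=1e-15)
        # sd of {+c, -c} is c*sqrt(2); sem over 2 subjects is c
        np.testing.assert_allclose(d["sem"], c, atol=1e-12)

    def test_single_subject_sem_missing(self):
        grid = np.arange(0, 60) / 60.0
        eps = [ep.Epoch(grid, np.ones(60), BLACK_FRONT, "post", 0.0, subject="a")]
        out = ep.mean_traces(eps)
        assert np.isnan(out[(BLACK_FRONT, "post")]["sem"]).all()
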