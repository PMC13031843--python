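import math

import numpy as np
import pytest

from corticomm.selectivity import (
    SelectivityLabel,
    _boxcar_smooth,
    classify_epoch_selectivity,
    distractor_modulation,
    selectivity_fraction,
    smoothing_window_frames,
    trial_type_selectivity_profile,
)
from corticomm.synthio import Session, TrialRecord
from corticomm.synthio.session import REGIONS

FR = 10.0  # Hz; trial epochs in frames: stim [0,10), delay [10,50), action [50,90)


def build_session(
    n_neurons,
    trial_specs,
    fill,
    region="ALM",
    seed=0,
):
    """Session with scripted activity. ``trial_specs`` is a list of
    (stimulus_side, outcome, distractor); ``fill(activity, trial, a_on)``
    writes each trial's activity in place (a_on = onset frame)."""
    rng = np.random.default_rng(seed)
    gap = 200
    onsets = [60 + i * gap for i in range(len(trial_specs))]
    n_frames = onsets[-1] + 120
    activity = rng.normal(size=(n_neurons, n_frames))
    trials = []
    for onset, (side, outcome, distractor) in zip(onsets, trial_specs):
        choice = (
            "none"
            if outcome == "no_response"
            else (side if outcome == "correct" else ("left" if side == "right" else "right"))
        )
        tr = TrialRecord(onset, side, choice, outcome, distractor)
        trials.append(tr)
        fill(activity, tr, onset)
    return Session(
        activity=activity,
        region_of=np.array([region] * n_neurons, dtype=object),
        frame_rate_hz=FR,
        trials=trials,
    )


def alternating_specs(n_per_side, outcome="correct", distractor="none"):
    out = []
    for i in range(2 * n_per_side):
        out.append(("left" if i % 2 else "right", outcome, distractor))
    return out


class TestClassifyEpochSelectivity:
    def test_disjoint_distributions_selective(self):
        def fill(act, tr, on):
            if tr.stimulus_side == "right":
                act[0, on + 10 : on + 50] += 3.0  # delay epoch boost

        s = build_session(12, alternating_specs(40), fill)
        labels = classify_epoch_selectivity(s)
        delay = [l for l in labels if l.epoch == "delay" and l.neuron == 0]
        assert len(delay) == 1
        assert delay[0].preferred_side == "right"
        assert delay[0].p_value < 0.01

    def test_small_region_excluded(self):
        def fill(act, tr, on):
            if tr.stimulus_side == "right":
                act[:, on + 10 : on + 50] += 3.0

        s = build_session(9, alternating_specs(40), fill)  # < 10 neurons
        assert classify_epoch_selectivity(s) == []

    def test_type_one_error_calibration(self):
        # null neurons flagged in <= 2% of 1000 tests at P < 0.01
        flags = total = 0
        for seed in range(5):
            s = build_session(
                100, alternating_specs(20), lambda *a: None, seed=seed
            )
            labels = classify_epoch_selectivity(s, epochs=("stimulus", "delay"))
            flags += len(labels)
            total += 200
        assert total == 1000
        assert flags / total <= 0.02

    def test_power_at_effect_size(self):
        # d = 1.5, 40 trials/side -> power >= 0.9
        def fill(act, tr, on):
            if tr.stimulus_side == "right":
                act[:, on + 10 : on + 50] += 1.5 / math.sqrt(40)
        # per-trial epoch mean has SD ~ 1/sqrt(40 frames); shift by 1.5 SD
        s = build_session(50, alternating_specs(40), fill, seed=3)
        labels = classify_epoch_selectivity(s, epochs=("delay",))
        assert len({l.neuron for l in labels}) >= 45

    def test_one_sided_trials_warns(self):
        s = build_session(
            12, [("right", "correct", "none")] * 10, lambda *a: None
        )
        with pytest.warns(UserWarning):
            assert classify_epoch_selectivity(s) == []


class TestSelectivityFraction:
    def test_basic_fraction(self, small_session):
        labels = [
            SelectivityLabel(n, "delay", "right", 0.001)
            for n in small_session.neurons_in("ALM")[:5]
        ]
        f = selectivity_fraction(labels, small_session, "ALM", "delay")
        assert f == pytest.approx(5 / 20)

    def test_zero_and_full(self, small_session):
        assert selectivity_fraction([], small_session, "ALM", "delay") == 0.0
        labels = [
            SelectivityLabel(n, "delay", "left", 0.001)
            for n in small_session.neurons_in("M2")
        ]
        assert selectivity_fraction(labels, small_session, "M2", "delay") == 1.0

    def test_excluded_region_returns_none(self):
        s = build_session(9, alternating_specs(5), lambda *a: None)
        assert selectivity_fraction([], s, "ALM", "delay") is None


class TestSmoothing:
    def test_mean_preserved_exactly(self, rng):
        trace = rng.normal(size=80)
        for w in (3, 5, 9):
            sm = _boxcar_smooth(trace, w)
            assert sm.mean() == pytest.approx(trace.mean(), abs=1e-10)

    def test_window_is_odd(self):
        assert smoothing_window_frames(9.35, 0.5) == 5
        assert smoothing_window_frames(10.0, 0.5) == 5
        assert smoothing_window_frames(12.0, 0.5) % 2 == 1


class TestTrialTypeSelectivityProfile:
    def make_mirror_session(self, d=2.0):
        # neurons 0,1 right-preferring; neuron 2 left-preferring, mirror-symmetric
        def fill(act, tr, on):
            sgn = 1.0 if tr.stimulus_side == "right" else -1.0
            act[0, on + 10 : on + 50] += sgn * d
            act[1, on + 10 : on + 50] += sgn * d
            act[2, on + 10 : on + 50] -= sgn * d

        s = build_session(12, alternating_specs(20), fill, seed=4)
        labels = [
            SelectivityLabel(0, "delay", "right", 1e-4),
            SelectivityLabel(1, "delay", "right", 1e-4),
            SelectivityLabel(2, "delay", "left", 1e-4),
        ]
        return s, labels

    def test_mirror_population_doubles_group_deflection(self):
        # oracle: hand computation — mirrored groups give selectivity
        # = right_trace - left_trace = 2x the single-group deflection
        s, labels = self.make_mirror_session()
        prof = trial_type_selectivity_profile(s, labels)
        mid = (prof.time_axis >= 2.0) & (prof.time_axis < 4.0)
        ratio = prof.selectivity[mid].mean() / prof.right_trace[mid].mean()
        assert ratio == pytest.approx(2.0, abs=0.1)

    def test_unmodulated_neuron_contributes_zero(self):
        def fill(act, tr, on):
            pass

        s = build_session(12, alternating_specs(25), fill, seed=5)
        labels = [SelectivityLabel(0, "delay", "right", 1e-4)]
        prof = trial_type_selectivity_profile(s, labels)
        assert abs(prof.right_trace.mean()) < 0.2

    def test_normalization_extremes(self):
        s, labels = self.make_mirror_session()
        prof = trial_type_selectivity_profile(s, labels)
        for row in prof.normalized_traces:
            assert row.min() == pytest.approx(0.0, abs=1e-12)
            assert row.max() == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry_under_label_swap(self):
        s, labels = self.make_mirror_session()
        prof = trial_type_selectivity_profile(s, labels)
        swapped_trials = [
            TrialRecord(
                t.onset_frame,
                "left" if t.stimulus_side == "right" else "right",
                {"left": "right", "right": "left", "none": "none"}[t.choice_side],
                t.outcome,
                t.distractor,
            )
            for t in s.trials
        ]
        s2 = Session(
            activity=s.activity,
            region_of=s.region_of,
            frame_rate_hz=s.frame_rate_hz,
            trials=swapped_trials,
        )
        prof2 = trial_type_selectivity_profile(s2, labels)
        assert np.allclose(prof2.selectivity, -prof.selectivity, atol=1e-10)

    def test_empty_without_delay_labels(self, small_session):
        prof = trial_type_selectivity_profile(small_session, [])
        assert prof.empty
        assert np.allclose(prof.selectivity, 0.0)


class TestDistractorModulation:
    def scripted(self, window_gain, d=2.0):
        """Right-left difference d everywhere, scaled by window_gain inside
        the late-distractor analysis window [4.2, 5.2) s (offset-anchored)."""

        def fill(act, tr, on):
            sgn = 1.0 if tr.stimulus_side == "right" else -1.0
            gain = window_gain if tr.distractor == "late" else 1.0
            act[0, on - 10 : on + 70] += sgn * d / 2
            act[1, on - 10 : on + 70] -= sgn * d / 2
            if tr.distractor == "late":
                a, b = on + 42, on + 52
                act[0, a:b] += sgn * (gain - 1.0) * d / 2
                act[1, a:b] -= sgn * (gain - 1.0) * d / 2

        specs = alternating_specs(20) + alternating_specs(10, distractor="late")
        s = build_session(12, specs, fill, seed=6)
        labels = [
            SelectivityLabel(0, "delay", "right", 1e-4),
            SelectivityLabel(1, "delay", "left", 1e-4),
        ]
        return s, labels

    def test_identical_trials_zero_modulation(self):
        s, labels = self.scripted(window_gain=1.0)
        mod = distractor_modulation(s, labels, "late", smooth_s=0.0)
        assert mod["ALM"] == pytest.approx(0.0, abs=0.15)

    def test_halved_selectivity_oracle(self):
        # oracle by hand: the mirror pair has window selectivity 2d = 4 on
        # non-distractor trials; halving it inside the window gives
        # modulation = -0.5 * 4 = -2
        s, labels = self.scripted(window_gain=0.5)
        mod = distractor_modulation(s, labels, "late", smooth_s=0.0)
        assert mod["ALM"] == pytest.approx(-0.5 * 4.0, abs=0.2)

    def test_window_anchor(self, small_session):
        from corticomm.synthio.session import distractor_window_for_type

        tr = small_session.trials[0]
        a_on, b_on = distractor_window_for_type(
            small_session, tr, "early", anchor="onset"
        )
        a_off, b_off = distractor_window_for_type(
            small_session, tr, "early", anchor="offset"
        )
        fr = small_session.frame_rate_hz
        assert a_on == math.floor(2.0 * fr) + tr.onset_frame
        assert a_off == math.floor(2.2 * fr) + tr.onset_frame
        assert b_off - a_off == math.floor(3.2 * fr) - math.floor(2.2 * fr)

    def test_missing_distractor_type_raises(self):
        s, labels = self.scripted(window_gain=1.0)
        with pytest.raises(ValueError):
            distractor_modulation(s, labels, "early")
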