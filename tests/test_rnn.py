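import numpy as np
import pytest

from corticomm.rnn import (
    RNNParams,
    TargetSet,
    ablate_and_test,
    build_target_functions,
    choice_axis_projection,
    detect_switch,
    force_train,
    init_network,
    load_model,
    make_synthetic_targets,
    make_trial_inputs,
    save_model,
    simulate,
    switching_proportion,
    synaptic_strength,
)
from corticomm.rnn.analysis import switch_mask
from corticomm.rnn.targets import inverse_sigmoid, sigmoid


class TestTargets:
    def test_inverse_sigmoid_midpoint(self):
        assert inverse_sigmoid(0.5) == pytest.approx(3.0)

    def test_round_trip_identity(self):
        r = np.linspace(0.01, 0.99, 99)
        assert np.allclose(sigmoid(inverse_sigmoid(r)), r, atol=1e-9)

    def test_build_targets_clip_keeps_finite(self, rng):
        params = RNNParams(n=16, seed=0)
        traces = {
            "left": np.full((8, 52), 5.0),  # at the clip ceiling
            "right": np.full((8, 52), 5.0),
        }
        traces["left"][:, :5] = 1.5  # pass the 1-SD gate
        traces["right"][:, :5] = 1.5
        ts = build_target_functions(traces, params, rng=0)
        assert np.all(np.isfinite(ts.f["left"]))
        assert np.all(np.isfinite(ts.f["right"]))

    def test_subthreshold_neurons_excluded(self):
        params = RNNParams(n=8, seed=0)
        traces = {
            "left": np.full((4, 52), 0.5),
            "right": np.full((4, 52), 0.5),
        }
        with pytest.raises(ValueError, match="1-SD"):
            build_target_functions(traces, params, rng=0)

    def test_region_sampling_counts(self, rng):
        params = RNNParams(n=16, seed=0)  # 2 per region
        traces = {
            "left": rng.normal(scale=1.5, size=(40, 52)),
            "right": rng.normal(scale=1.5, size=(40, 52)),
        }
        from corticomm.synthio.session import REGIONS

        region_of = np.array(
            [REGIONS[i % 8] for i in range(40)], dtype=object
        )
        ts = build_target_functions(traces, params, rng=0, region_of=region_of)
        assert ts.n_units == 16
        assert list(ts.region_of[:2]) == ["ALM", "ALM"]

    def test_round_trip_through_pipeline_midrange(self, rng):
        # sigma(f) reproduces normalized clipped activity for interior values
        params = RNNParams(n=4, seed=0)
        base = np.clip(rng.uniform(0.5, 4.5, size=(4, 52)), 0.01, 4.99)
        ts = build_target_functions(
            {"left": base, "right": base}, params, rng=0, sample=False
        )
        # compare at original sample points (before smoothing, tolerate boxcar)
        approx = sigmoid(ts.f["left"])
        assert approx.min() > 0 and approx.max() < 1


class TestInitNetwork:
    def test_j_scale_concentration(self):
        params = RNNParams(n=1024, seed=0)
        m = init_network(params)
        expected = params.g / np.sqrt(params.n)
        assert m.J.std() == pytest.approx(expected, rel=0.02)

    def test_seed_reproducibility(self):
        params = RNNParams(n=64, seed=7)
        a, b = init_network(params), init_network(params)
        assert np.array_equal(a.J, b.J)
        assert np.array_equal(a.w_stimulus, b.w_stimulus)
        assert np.array_equal(a.w_cue, b.w_cue)

    def test_p_literal_reading(self):
        m = init_network(RNNParams(n=32, seed=0))
        assert np.allclose(m.P, 0.005 * np.eye(32))

    def test_p_inverse_reading(self):
        m = init_network(RNNParams(n=32, seed=0, p_init="inverse"))
        assert np.allclose(m.P, np.eye(32) / 0.005)

    def test_w_cue_dispersion_is_sd(self):
        m = init_network(RNNParams(n=4096, seed=0, ))
        assert m.w_cue.std() == pytest.approx(0.1, rel=0.05)


class TestTrialInputs:
    def test_left_stimulus_identically_zero(self):
        inp = make_trial_inputs("left", rng=0)
        assert np.all(inp.i_stimulus == 0.0)
        assert inp.stim_peak == 0.0

    def test_cue_peak_exact(self):
        inp = make_trial_inputs("right", rng=0)
        assert inp.i_cue.max() == pytest.approx(1.0)
        p = RNNParams()
        times = (np.arange(p.n_steps) + 0.5) * p.dt
        on = inp.i_cue > 0
        assert times[on].min() >= p.cue_onset_s
        assert times[on].max() < p.cue_offset_s

    def test_right_peak_distribution(self):
        rng = np.random.default_rng(0)
        peaks = [
            make_trial_inputs("right", rng=rng).stim_peak for _ in range(1000)
        ]
        assert np.mean(peaks) == pytest.approx(1.0, abs=0.01)

    def test_distractor_span(self):
        p = RNNParams()
        inp = make_trial_inputs("left", with_distractor=True, rng=0)
        times = (np.arange(p.n_steps) + 0.5) * p.dt
        on = inp.i_distractor > 0
        assert times[on].min() >= p.distractor_onset_s
        assert times[on].max() < p.distractor_offset_s

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            make_trial_inputs("middle")


class TestSimulate:
    def test_exponential_decay_oracle(self):
        # J=0, no input, no noise: x(t) = x0 * (1 - dt/tau)^t ~ x0 e^{-t/tau}
        params = RNNParams(n=8, seed=0)
        m = init_network(params)
        m.J[:] = 0.0
        m.w_stimulus[:] = 0.0
        m.w_cue[:] = 0.0
        x0 = np.full(8, 2.0)
        inp = make_trial_inputs("left", rng=0)
        inp.i_cue[:] = 0.0
        sim = simulate(m, inp, noise_on=False, x0=x0, record_every=100)
        # z = 0 for all t, so x(t) = x0 (1-dt/tau)^(t+1); compare against the
        # continuous-time solution within the Euler error bound
        t = sim.times
        x_rec = -np.log(1.0 / sim.r[0] - 1.0) + params.theta  # invert sigmoid
        expected = x0[0] * np.exp(-t / params.tau)
        assert np.allclose(x_rec[:, 0], expected, atol=0.12)

    def test_deterministic_repeatability(self, bistable_rnn):
        model, _, _ = bistable_rnn
        inp = make_trial_inputs("right", rng=3)
        a = simulate(model, inp, noise_on=False)
        b = simulate(model, inp, noise_on=False)
        assert np.array_equal(a.r, b.r)

    def test_activity_in_open_unit_interval(self, bistable_rnn):
        model, _, _ = bistable_rnn
        sim = simulate(model, make_trial_inputs("right", rng=1), noise_on=True,
                       rng=0)
        assert sim.r.min() > 0.0
        assert sim.r.max() < 1.0


class TestForceTrain:
    def test_zero_learning_rate_leaves_j(self):
        params = RNNParams(n=16, epochs=2, seed=0, alpha_learn=0.0, noise_sd=0.0)
        m = init_network(params)
        J0 = m.J.copy()
        targets = make_synthetic_targets(params, seed=0)
        force_train(m, targets, rng=0)
        assert np.array_equal(m.J, J0)

    def test_paired_initialization_shares_j(self):
        params = RNNParams(n=32, seed=5)
        ta = make_synthetic_targets(params, seed=1)
        tb = make_synthetic_targets(params, seed=2)
        ma, mb = init_network(params), init_network(params)
        assert np.array_equal(ma.J, mb.J)
        force_train(ma, ta, epochs=1, rng=0)
        force_train(mb, tb, epochs=1, rng=0)
        assert not np.array_equal(ma.J, mb.J)  # targets differ, init shared

    def test_dimension_mismatch(self):
        params = RNNParams(n=16, seed=0)
        m = init_network(params)
        targets = make_synthetic_targets(RNNParams(n=32, seed=0), seed=0)
        with pytest.raises(ValueError):
            force_train(m, targets)

    def test_numpy_and_numba_agree(self):
        params = RNNParams(n=8, epochs=1, seed=0, noise_sd=0.0, alpha_learn=0.3)
        targets = make_synthetic_targets(params, seed=0)
        ma, mb = init_network(params), init_network(params)
        mse_a = force_train(ma, targets, rng=0, use_numba=False)
        mse_b = force_train(mb, targets, rng=0, use_numba=True)
        assert np.allclose(ma.J, mb.J, atol=1e-8)
        assert mse_a[0] == pytest.approx(mse_b[0], abs=1e-8)


class TestConvergenceFixture:
    def test_mse_drops_tenfold(self, convergence_rnn):
        _, _, mse = convergence_rnn
        assert mse[-1] <= 0.1 * mse[0]

    def test_reproduction_correlation(self, convergence_rnn):
        model, targets, _ = convergence_rnn
        p = model.params
        f_grid = targets.resample(p.n_steps)
        idx = np.arange(0, p.n_steps, 10)
        for ttype in ("right", "left"):
            inp = make_trial_inputs(ttype, params=p, rng=np.random.default_rng(1))
            sim = simulate(model, inp, noise_on=False, record_every=10)
            c = np.corrcoef(
                sigmoid(sim.z[0]).ravel(), sigmoid(f_grid[ttype][:, idx].T).ravel()
            )[0, 1]
            assert c >= 0.9

    def test_full_weight_removal_abolishes_reproduction(self, convergence_rnn):
        model, targets, _ = convergence_rnn
        lesioned = model.copy()
        lesioned.J[:] = 0.0
        p = model.params
        f_grid = targets.resample(p.n_steps)
        idx = np.arange(0, p.n_steps, 10)
        inp = make_trial_inputs("right", params=p, rng=np.random.default_rng(1))
        sim = simulate(lesioned, inp, noise_on=False, record_every=10)
        c = np.corrcoef(
            sigmoid(sim.z[0]).ravel(), sigmoid(f_grid["right"][:, idx].T).ravel()
        )[0, 1]
        assert c < 0.2


class TestChoiceAxis:
    def _times(self):
        p = RNNParams()
        return np.array([0.25, 4.75, 5.49]), p

    def test_single_direction_axis(self):
        times, p = self._times()
        rng = np.random.default_rng(0)
        base = rng.random((4, 3, 6))
        e = np.zeros(6)
        e[2] = 1.0
        acts = {"left": base, "right": base + 0.8 * e}
        proj = choice_axis_projection(acts, times, p)
        assert abs(np.dot(proj.axis, e)) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(proj.axis) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_identical_conditions(self):
        times, p = self._times()
        base = np.ones((2, 3, 5))
        proj = choice_axis_projection({"left": base, "right": base.copy()}, times, p)
        assert proj.degenerate

    def test_hand_computed_projection(self):
        # 3 units, explicit arithmetic oracle
        times = np.array([0.25, 5.0])
        p = RNNParams()
        left = np.array([[[1.0, 0.0, 0.0], [1.0, 2.0, 0.0]]])  # (1, 2, 3)
        right = np.array([[[1.0, 0.0, 0.0], [3.0, 2.0, 2.0]]])
        proj = choice_axis_projection({"left": left, "right": right}, times, p)
        # delta = right_pre - left_pre = (2, 0, 2); axis = (1,0,1)/sqrt(2)
        assert np.allclose(proj.axis, np.array([1, 0, 1]) / np.sqrt(2))
        # raw projections: left = [1/s2, 1/s2]; right = [1/s2, 5/s2]
        s2 = np.sqrt(2)
        assert np.allclose(proj.projections["left"][0], [1 / s2, 1 / s2])
        assert np.allclose(proj.projections["right"][0], [1 / s2, 5 / s2])
        # baselines = first time point -> mean traces [0, 0] and [0, 4/s2]
        # normalized by max right activity (4/s2): right trace ends at 1
        assert proj.mean_traces["right"][-1] == pytest.approx(1.0)
        assert proj.mean_traces["left"][-1] == pytest.approx(0.0)

    def test_missing_reference_condition(self):
        times, p = self._times()
        with pytest.raises(ValueError):
            choice_axis_projection({"left": np.ones((1, 3, 4))}, times, p)


class TestDetectSwitch:
    def _proj(self):
        times = np.array([0.25, 5.49])
        p = RNNParams()
        left = np.zeros((2, 2, 4))
        right = np.zeros((2, 2, 4))
        right[:, 1, 0] = 2.0  # right trials end high on unit 0
        acts = {"left": left, "right": right, "left_distractor": left.copy()}
        return choice_axis_projection(acts, times, p)

    def test_end_at_right_reference_switches(self):
        proj = self._proj()
        trace = proj.projections["right"][0]
        assert detect_switch(proj, trace, condition="left_distractor")

    def test_end_at_left_reference_stays(self):
        proj = self._proj()
        trace = proj.projections["left"][0]
        assert not detect_switch(proj, trace, condition="left_distractor")

    def test_exact_midpoint_not_switched(self):
        proj = self._proj()
        mid = 0.5 * (
            proj.projections["right"][0] + proj.projections["left"][0]
        )
        assert not detect_switch(proj, mid, condition="left_distractor")


class TestSynapticStrength:
    def test_unit_weights(self):
        J = np.array([[1.0, -1.0], [-1.0, 1.0]])
        s = synaptic_strength(J)
        assert s == {"overall": 1.0, "excitatory": 1.0, "inhibitory": 1.0}

    def test_zero_matrix_flags_empty(self):
        s = synaptic_strength(np.zeros((3, 3)))
        assert s["overall"] == 0.0
        assert np.isnan(s["excitatory"]) and np.isnan(s["inhibitory"])

    def test_half_normal_mean(self, rng):
        sigma = 0.7
        J = rng.normal(0, sigma, size=(400, 400))
        s = synaptic_strength(J)
        assert s["overall"] == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.02)


class TestBistableNetwork:
    def test_no_distractor_no_switching(self, bistable_rnn):
        model, _, _ = bistable_rnn
        prop = switching_proportion(
            model, n_trials=100, n_reference=20, seed=0, distractor_peak_mean=0.0
        )
        assert prop == 0.0

    def test_switching_monotone_in_amplitude(self, bistable_rnn):
        model, _, _ = bistable_rnn
        means = []
        for amp in (0.0, 1.25, 2.5, 5.0):
            props = [
                switching_proportion(
                    model, n_trials=20, n_reference=10, seed=s,
                    distractor_peak_mean=amp,
                )
                for s in range(5)
            ]
            means.append(np.mean(props))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    def test_ablation_level_zero_matches_baseline(self, bistable_rnn):
        model, _, _ = bistable_rnn
        a = ablate_and_test(model, mode="random", level=0.0, repeats=2,
                            n_trials=10, n_reference=8, seed=4)
        b = ablate_and_test(model, mode="random", level=0.0, repeats=2,
                            n_trials=10, n_reference=8, seed=4)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))

    def test_region_mode_requires_region(self, bistable_rnn):
        model, _, _ = bistable_rnn
        with pytest.raises(ValueError):
            ablate_and_test(model, mode="region", level=0.1, repeats=1,
                            n_trials=5, n_reference=5, seed=0)


def test_checkpoint_round_trip(tmp_path, convergence_rnn):
    model, _, _ = convergence_rnn
    path = save_model(model, tmp_path / "model.h5")
    back = load_model(path)
    assert np.array_equal(back.J, model.J)
    assert np.array_equal(back.P, model.P)
    assert back.params.n == model.params.n
    assert back.params.alpha_learn == model.params.alpha_learn
    assert list(back.region_of) == list(model.region_of)
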