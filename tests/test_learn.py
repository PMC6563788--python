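"""First-error detection, gradient updates, and the training loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fespike as fs
from fespike.core import NeuronParams, PspCache
from fespike.learn import (
    LearnConfig,
    _first_error_online,
    find_first_error,
    tolerance_windows,
    train,
    voltage_time_derivative,
    weight_decrement,
    weight_increment,
)

from conftest import make_pattern


class TestToleranceWindows:
    def test_width_one_degenerate_interval(self):
        win = tolerance_windows(fs.SpikeTrain([100.0]), 1)
        np.testing.assert_array_equal(win, [[100.0, 100.0]])

    def test_width_three_centered(self):
        win = tolerance_windows(fs.SpikeTrain([100.0]), 3)
        np.testing.assert_array_equal(win, [[99.0, 101.0]])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            tolerance_windows(fs.SpikeTrain([50.0, 53.0]), 5)

    @pytest.mark.parametrize("eps", [0, 2, 4, -3])
    def test_even_or_nonpositive_width_rejected(self, eps):
        with pytest.raises(ValueError):
            tolerance_windows(fs.SpikeTrain([50.0]), eps)


def perfect_assignment_exists(actual, windows):
    """Enumerate all (spike, window) bijections; True iff one covers
    every window with exactly one in-window spike and leaves no stray."""
    if len(actual) != len(windows):
        return False
    for perm in itertools.permutations(range(len(actual))):
        if all(
            windows[j][0] <= actual[perm[j]] <= windows[j][1]
            for j in range(len(windows))
        ):
            return True
    return len(windows) == 0


class TestFindFirstError:
    def test_exact_match_no_error(self):
        t = fs.SpikeTrain([100.0, 200.0])
        for eps in (1, 3, 5):
            assert find_first_error(t, t, eps) is None

    def test_all_missed_reports_first_desired(self):
        err = find_first_error(fs.SpikeTrain.empty(), fs.SpikeTrain([100.0, 200.0]), 1)
        assert (err.kind, err.t_err) == ("c", 100.0)

    def test_stray_spike_outside_windows(self):
        err = find_first_error(
            fs.SpikeTrain([100.0, 150.0]), fs.SpikeTrain([100.0, 200.0]), 3
        )
        assert (err.kind, err.t_err) == ("a", 150.0)

    def test_second_spike_in_same_window(self):
        err = find_first_error(fs.SpikeTrain([99.0, 101.0]), fs.SpikeTrain([100.0]), 3)
        assert (err.kind, err.t_err) == ("b", 101.0)

    def test_missed_window_precedes_later_stray(self):
        # window [99,101] closes unmatched before the stray at 120 is seen
        err = find_first_error(fs.SpikeTrain([120.0]), fs.SpikeTrain([100.0]), 3)
        assert (err.kind, err.t_err) == ("c", 100.0)

    @given(
        actual=st.lists(st.integers(0, 60), max_size=6, unique=True),
        desired=st.lists(st.integers(2, 58), max_size=4, unique=True),
        eps=st.sampled_from([1, 3, 5]),
    )
    @settings(max_examples=300, deadline=None)
    def test_no_error_iff_perfect_assignment(self, actual, desired, eps):
        a = fs.SpikeTrain(np.sort(np.asarray(actual, float)))
        d = fs.SpikeTrain(np.sort(np.asarray(desired, float)))
        try:
            win = tolerance_windows(d, eps)
        except ValueError:
            return  # overlapping windows are a precondition violation
        err = find_first_error(a, d, eps)
        assert (err is None) == perfect_assignment_exists(a.times, win)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_online_detector_agrees_with_post_hoc_scan(self, seed):
        """Stop-at-error simulation and full-trace scanning find the same error."""
        rng = np.random.default_rng(seed)
        params = NeuronParams()
        pattern = make_pattern(rng, 8, 80.0, rate=60.0)
        w = rng.normal(0.25, 0.25, 8)
        desired = fs.SpikeTrain(np.unique(rng.integers(4, 78, 3)).astype(float) * 1.0)
        eps = 3
        try:
            tolerance_windows(desired, eps)
        except ValueError:
            return
        cache = PspCache(pattern, params)
        trace = fs.simulate(pattern, w, params, cache=cache)
        expected = find_first_error(trace.output_spikes, desired, eps)
        got, n_matched = _first_error_online(
            cache, w, params, desired.indices(1.0), (eps - 1) // 2
        )
        if expected is None:
            assert got is None
        else:
            assert (got.kind, got.t_err) == (expected.kind, expected.t_err)
            # every earlier window was matched exactly once
            win = tolerance_windows(desired, eps)
            for j in range(n_matched):
                assert np.any(
                    (trace.output_spikes.times >= win[j, 0])
                    & (trace.output_spikes.times <= win[j, 1])
                )


class TestVoltageTimeDerivative:
    def test_no_history_gives_zero(self, params):
        pattern = fs.SpikePattern((fs.SpikeTrain([50.0]),), 100.0)
        d = voltage_time_derivative(20.0, pattern, [1.0], fs.SpikeTrain.empty(), params)
        assert d == 0.0

    def test_single_input_closed_form(self, params):
        s, t, w = 10.0, 18.0, 0.7
        pattern = fs.SpikePattern((fs.SpikeTrain([s]),), 100.0)
        d = voltage_time_derivative(t, pattern, [w], fs.SpikeTrain.empty(), params)
        x = t - s
        expected = (
            params.v_norm
            * w
            * (
                np.exp(-x / params.tau_s) / params.tau_s
                - np.exp(-x / params.tau_m) / params.tau_m
            )
        )
        assert d == pytest.approx(expected, rel=1e-12)

    def test_matches_finite_difference_of_free_potential(self, rng, params):
        checked = 0
        while checked < 5:
            pattern = make_pattern(rng, 6, 80.0, rate=50.0)
            w = np.abs(rng.normal(0.3, 0.2, 6))
            t_spike = 50.0
            if any(t_spike in tr.times for tr in pattern.trains):
                continue  # kernel kink at the query time; derivative one-sided
            d = voltage_time_derivative(
                t_spike, pattern, w, fs.SpikeTrain.empty(), params
            )

            def vfree(t):
                tot = 0.0
                for i, tr in enumerate(pattern.trains):
                    x = t - tr.times[tr.times < t_spike]
                    tot += w[i] * np.sum(fs.psp_kernel(x, params))
                return tot

            h = 1e-6
            fd = (vfree(t_spike + h) - vfree(t_spike - h)) / (2 * h)
            if abs(fd) > 1e-6:
                assert d == pytest.approx(fd, rel=1e-3)
                checked += 1

    def test_reset_recovery_term(self, params):
        pattern = fs.SpikePattern((fs.SpikeTrain.empty(),), 100.0)
        d = voltage_time_derivative(
            40.0, pattern, [0.0], fs.SpikeTrain([30.0]), params
        )
        expected = params.theta / params.tau_m * np.exp(-10.0 / params.tau_m)
        assert d == pytest.approx(expected, rel=1e-12)


class TestWeightUpdates:
    def test_increment_without_prior_targets_is_kernel_column(self, small_pattern, params):
        cfg = LearnConfig(lambda1=0.01, s_r=1.0)
        dw = weight_increment(
            small_pattern, np.zeros(10), fs.SpikeTrain.empty(), 60.0, cfg, params
        )
        col = fs.psp_matrix(small_pattern, params)[:, 60]
        np.testing.assert_allclose(dw, 0.01 * col, rtol=1e-12)

    def test_sr_zero_mirrors_decrement(self, small_pattern, params):
        cfg = LearnConfig(lambda1=0.02, lambda2=0.02, s_r=0.0)
        inc = weight_increment(
            small_pattern, np.zeros(10), fs.SpikeTrain([30.0]), 60.0, cfg, params
        )
        dec = weight_decrement(small_pattern, 60.0, cfg, params)
        np.testing.assert_allclose(inc, -dec, rtol=1e-12)

    def test_decrement_zero_for_silent_afferent(self, params):
        pattern = fs.SpikePattern(
            (fs.SpikeTrain([10.0]), fs.SpikeTrain([80.0])), 100.0
        )
        cfg = LearnConfig()
        dw = weight_decrement(pattern, 50.0, cfg, params)
        assert dw[1] == 0.0  # its only spike comes after t_err
        assert dw[0] == pytest.approx(
            -cfg.lambda2 * fs.psp_kernel(40.0, params), rel=1e-12
        )

    def test_decrement_lowers_potential_at_terr(self, small_pattern, params, rng):
        w = np.abs(rng.normal(0.4, 0.2, 10))
        cfg = LearnConfig(lambda2=0.01)
        t_err = 70.0
        high = fs.NeuronParams(theta=1e9)  # reset-free readout of V(t_err)
        before = fs.simulate(small_pattern, w, high).values[70]
        dw = weight_decrement(small_pattern, t_err, cfg, params)
        after = fs.simulate(small_pattern, w + dw, high).values[70]
        assert after < before

    def test_increment_raises_potential_at_terr(self, small_pattern, params, rng):
        w = rng.normal(0.1, 0.1, 10)
        cfg = LearnConfig(lambda1=0.01, s_r=0.0)
        high = fs.NeuronParams(theta=1e9)
        before = fs.simulate(small_pattern, w, high).values[60]
        dw = weight_increment(
            small_pattern, w, fs.SpikeTrain.empty(), 60.0, cfg, params
        )
        after = fs.simulate(small_pattern, w + dw, high).values[60]
        assert after > before


class TestChainRuleGradient:
    """The S_r chain term against a continuous-time finite-difference oracle.

    An instance is built so that the neuron's reset-free potential crosses
    the threshold exactly at a pinned desired time t_d (weights rescaled);
    the oracle then tracks how the crossing time, and through the reset
    term the potential at a later t_err, responds to a weight perturbation.
    """

    @staticmethod
    def _continuous_free(pattern, params):
        def vfree(t, w):
            tot = 0.0
            for i, tr in enumerate(pattern.trains):
                x = t - tr.times[tr.times < t]
                tot += w[i] * np.sum(
                    params.v_norm
                    * (np.exp(-x / params.tau_m) - np.exp(-x / params.tau_s))
                )
            return tot

        return vfree

    def test_matches_oracle_on_many_instances(self):
        from scipy.optimize import brentq

        params = NeuronParams()
        rng = np.random.default_rng(1234)
        cfg = LearnConfig(epsilon=1, s_r=1.0, lambda1=1.0, lambda2=1.0)
        td, terr = 60.0, 75.0
        checked = 0
        attempts = 0
        while checked < 100 and attempts < 3000:
            attempts += 1
            pattern = fs.poisson_pattern(
                10, 40.0, 120.0, seed=int(rng.integers(2**31))
            )
            if any(td in tr.times for tr in pattern.trains):
                continue  # kernel kink exactly at the crossing
            vfree = self._continuous_free(pattern, params)
            w = np.abs(rng.normal(0.3, 0.1, 10))
            base = vfree(td, w)
            if base < 1e-2:
                continue
            w = w / base  # crossing pinned exactly at td
            if max(vfree(float(g), w) for g in np.arange(1.0, td)) >= 1.0:
                continue
            slope = voltage_time_derivative(
                td, pattern, w, fs.SpikeTrain.empty(), params
            )
            if slope < 0.05:
                continue
            dw = weight_increment(
                pattern, w, fs.SpikeTrain([td]), terr, cfg, params
            )

            for i in rng.choice(10, 2, replace=False):
                def v_at_terr(wi):
                    wv = w.copy()
                    wv[i] = wi
                    flo = vfree(td - 2.0, wv) - 1.0
                    fhi = vfree(td + 2.0, wv) - 1.0
                    if flo * fhi > 0:
                        return None
                    t1 = brentq(
                        lambda t: vfree(t, wv) - 1.0, td - 2.0, td + 2.0, xtol=1e-12
                    )
                    return vfree(terr, wv) - np.exp(-(terr - t1) / params.tau_m)

                h = 1e-5
                up, down = v_at_terr(w[i] + h), v_at_terr(w[i] - h)
                if up is None or down is None:
                    continue
                fd = (up - down) / (2 * h)
                if abs(fd) < 1e-6:
                    continue
                assert dw[i] == pytest.approx(fd, rel=1e-3)
                checked += 1
        assert checked >= 100


class TestTrain:
    def test_already_correct_weights_converge_immediately(self, params):
        # a neuron whose initial weights produce the desired train exactly
        pattern = fs.poisson_pattern(20, 30.0, 100.0, seed=5)
        cfg = LearnConfig(epsilon=1, init_mean=0.25, init_sd=0.0, seed=0)
        w0 = np.full(20, 0.25)
        desired = fs.simulate(pattern, w0, params).output_spikes
        if len(desired) == 0:
            desired = fs.SpikeTrain.empty()
        rec = train(pattern, desired, cfg, params)
        assert rec.converged
        assert rec.epochs_to_converge == 0
        assert rec.best_c == 1.0

    def test_one_update_per_epoch(self, params):
        pattern = fs.poisson_pattern(50, 10.0, 100.0, seed=11)
        cfg = LearnConfig(epsilon=3, max_epochs=200, seed=3, s_r=0.0)
        rec = train(pattern, fs.SpikeTrain([50.0]), cfg, params)
        n_updates = len(rec.error_log)
        if rec.converged:
            assert n_updates == rec.epochs_to_converge
        else:
            assert n_updates == cfg.max_epochs
        assert len(rec.c_history) == n_updates + 1

    def test_small_task_convergence_rate(self, params):
        """50 afferents at 10 Hz, one desired spike: nearly every seed converges."""
        wins = 0
        for seed in range(20):
            pattern = fs.poisson_pattern(50, 10.0, 100.0, seed=1000 + seed)
            cfg = LearnConfig(epsilon=3, max_epochs=500, seed=seed)
            rec = train(pattern, fs.SpikeTrain([50.0]), cfg, params)
            wins += rec.converged
        assert wins >= 18

    def test_epsilon_one_convergence_gives_exact_c(self, params):
        converged_any = False
        for seed in range(5):
            pattern = fs.poisson_pattern(60, 20.0, 100.0, seed=seed)
            cfg = LearnConfig(epsilon=1, max_epochs=3000, seed=seed, s_r=0.0)
            rec = train(pattern, fs.SpikeTrain([40.0, 70.0]), cfg, params)
            if rec.converged:
                converged_any = True
                assert rec.c_history[-1] == 1.0
        assert converged_any

    def test_record_io_round_trip(self, params, tmp_path):
        pattern = fs.poisson_pattern(30, 20.0, 80.0, seed=2)
        cfg = LearnConfig(epsilon=3, max_epochs=100, seed=2)
        rec = train(pattern, fs.SpikeTrain([40.0]), cfg, params)
        fs.save_train_record(rec, tmp_path, prefix="t")
        assert (tmp_path / "t_log.csv").exists()
        assert (tmp_path / "t_result.json").exists()
        assert (tmp_path / "t_weights.csv").exists()


class TestLearnConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(epsilon=2),
            dict(epsilon=0),
            dict(s_r=-0.5),
            dict(lambda1=0.0),
            dict(lambda2=-1.0),
            dict(max_epochs=0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            LearnConfig(**kw)
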