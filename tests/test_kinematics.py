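"""Kinematic profiles, single-trial SSRT, trigger failures, regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopkin.exceptions import InsufficientDataError, TrialCategoryError
from stopkin.kinematics import (
    central_difference,
    collect_single_trial_ssrts,
    compute_profile,
    detect_trigger_failure,
    racemodel_regressions,
    single_trial_ssrt,
    summarize_stopping,
)
from stopkin.sessions import classify_trial, filter_outliers

from conftest import (
    FRAME,
    START,
    make_trial,
    session_from,
    stop_trial_halted,
    stop_trial_reached,
    stop_trial_still,
)


def _minjerk_trial(D=400.0, T=420.0, rt_offset=0.0):
    """Trial following a pure minimum-jerk path of amplitude D, duration T."""
    t = np.arange(-2 * FRAME, T + 200.0, FRAME)
    s = np.clip(t / T, 0.0, 1.0)
    d = D * (10 * s**3 - 15 * s**4 + 6 * s**5)
    # straight line upward from just outside the pad
    x = np.zeros_like(d)
    y = 1.0 + d
    return make_trial([(0.0, START)]), np.column_stack([t, x, y])


class TestComputeProfile:
    def test_constant_position_after_exit(self):
        tr = make_trial([(0.0, START), (90.0, START), (100.0, (0.0, 2.0))])
        prof = compute_profile(tr)
        assert prof.amplitude == 0.0
        assert np.allclose(prof.resultant_velocity[5:], 0.0)

    def test_straight_line_constant_speed(self):
        # 2 px per frame at 60 Hz -> 120 px/s
        t = np.arange(-FRAME, 500.0, FRAME)
        y = np.where(t >= 0, 0.5 + 2.0 * t / FRAME, -4.0)
        tr = make_trial([(0.0, START)])
        tr.samples = np.column_stack([t, np.zeros_like(t), y])
        prof = compute_profile(tr)
        inner = prof.resultant_velocity[1:-1]
        assert np.allclose(inner, 120.0, atol=1e-6)

    def test_minimum_jerk_peak_velocity(self):
        # peak velocity 1.875 D/T at t = T/2, within one sample
        D, T = 400.0, 420.0
        tr, samples = _minjerk_trial(D, T)
        tr.samples = samples
        prof = compute_profile(tr)
        v_peak = 1.875 * D / T * 1000.0  # px/s
        assert abs(prof.resultant_velocity.max() - v_peak) / v_peak < 0.02
        assert abs(prof.peak_velocity_time - T / 2) <= FRAME

    def test_too_few_samples_rejected(self):
        tr = make_trial([(0.0, START), (10.0, (0.0, 2.0))], t_end=2 * FRAME)
        with pytest.raises(InsufficientDataError):
            compute_profile(tr)

    def test_never_exits_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_profile(stop_trial_still(ssd=100.0))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_time_reversal_negates_velocity(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        t = np.sort(rng.uniform(0, 1000, n))
        t = t[np.concatenate([[True], np.diff(t) > 1e-6])]
        y = rng.uniform(-100, 100, t.size)
        v = central_difference(t, y)
        # time reversal mirrors the grid as well as the values
        v_rev = central_difference(t.max() - t[::-1], y[::-1])
        np.testing.assert_allclose(v_rev[::-1], -v, rtol=1e-9, atol=1e-9)


class TestSingleTrialSSRT:
    def test_home_mode_definitional_subtraction(self):
        tr = stop_trial_halted(ssd=100.0, rt=200.0, halt_t=600.0)
        oc = classify_trial(tr)
        prof = compute_profile(tr, oc)
        est = single_trial_ssrt(tr, prof, "home", oc)
        assert est == pytest.approx(prof.peak_velocity_time - 100.0)

    def test_target_mode_definitional_subtraction(self):
        tr = stop_trial_halted(ssd=600.0, rt=200.0, halt_t=900.0, staircase="target")
        oc = classify_trial(tr)
        prof = compute_profile(tr, oc)
        est = single_trial_ssrt(tr, prof, "target", oc)
        assert est == pytest.approx(prof.max_displacement_time - 600.0)
        # trivial example: max displacement 900 ms after go, SSD 600 -> 300 ms
        assert est == pytest.approx(300.0, abs=2 * FRAME)

    def test_wrong_category_rejected(self):
        tr = stop_trial_still(ssd=100.0)
        oc = classify_trial(tr)
        with pytest.raises(TrialCategoryError):
            single_trial_ssrt(tr, None, "home", oc)
        go = make_trial([(0.0, START)], trial_kind="go")
        with pytest.raises(TrialCategoryError):
            single_trial_ssrt(go, None, "home")

    def test_simulator_recovery_within_one_frame(self, long_sim_session):
        session, gt = long_sim_session
        session.classify()
        gtm = gt.set_index("trial")
        err_home, err_tgt = [], []
        for tr, oc in session.iter_classified(kind="stop"):
            g = gtm.loc[tr.trial]
            try:
                prof = compute_profile(tr, oc)
            except InsufficientDataError:
                continue
            if (tr.staircase == "home" and oc.home_stop_success is False
                    and oc.target_stop_success):
                est = single_trial_ssrt(tr, prof, "home", oc)
                err_home.append(est - (g["peak_velocity_time"] - tr.ssd_actual))
            elif (tr.staircase == "target" and oc.target_stop_success
                    and oc.reaction_time is not None):
                est = single_trial_ssrt(tr, prof, "target", oc)
                err_tgt.append(est - (g["halt_time"] - tr.ssd_actual))
        assert len(err_home) > 50 and len(err_tgt) > 50
        assert np.mean(np.abs(err_home)) <= FRAME
        assert np.mean(np.abs(err_tgt)) <= FRAME

    def test_peak_velocity_precedes_halt(self, long_sim_session):
        # on every qualifying trial the velocity peak cannot come after the
        # maximum-displacement (halt) landmark
        session, _ = long_sim_session
        session.classify()
        for tr, oc in session.iter_classified(kind="stop", staircase="home"):
            if not (oc.home_stop_success is False and oc.target_stop_success):
                continue
            try:
                prof = compute_profile(tr, oc)
            except InsufficientDataError:
                continue
            assert prof.peak_velocity_time <= prof.max_displacement_time


class TestTriggerFailures:
    def test_reaching_target_is_trigger_failure(self):
        tr = stop_trial_reached(ssd=100.0, entry=760.0)
        assert detect_trigger_failure(tr) is True

    def test_halting_short_is_not(self):
        tr = stop_trial_halted(ssd=100.0)
        assert detect_trigger_failure(tr) is False

    def test_rate_arithmetic(self):
        trials = [stop_trial_reached(ssd=100.0) for _ in range(2)]
        trials += [stop_trial_halted(ssd=100.0) for _ in range(35)]
        trials += [stop_trial_still(ssd=100.0) for _ in range(35)]
        session = session_from(trials)
        est = summarize_stopping(session)
        assert est["home"].tf_k_percent == pytest.approx(100.0 * 2 / 72)

    def test_requires_home_staircase_stop_trial(self):
        with pytest.raises(TrialCategoryError):
            detect_trigger_failure(stop_trial_halted(ssd=500.0, staircase="target"))

    def test_rate_matches_injected_probability(self):
        # binomial check over >=1000 simulated home-staircase stop trials
        from stopkin.simulate import SimConfig, simulate_session
        from scipy.stats import binom

        cfg = SimConfig(seed=31, n_blocks=260, p_tf=0.02)
        session, _ = simulate_session(cfg)
        session.classify()
        flags = [detect_trigger_failure(tr, oc)
                 for tr, oc in session.iter_classified(kind="stop", staircase="home")]
        n = len(flags)
        assert n >= 1000
        lo, hi = binom.ppf([0.025, 0.975], n, cfg.p_tf)
        assert lo <= sum(flags) <= hi


class TestSummarizeStopping:
    def test_sub_100ms_values_removed_before_summary(self):
        vals = np.array([95.0, 250.0, 260.0, 270.0, 280.0])
        kept, removed = filter_outliers(vals)
        assert 95.0 in removed
        assert np.mean(kept) == pytest.approx(265.0)

    def test_sd_flagged_undefined_with_single_trial(self):
        trials = [stop_trial_halted(ssd=100.0)]
        trials += [stop_trial_still(ssd=500.0, staircase="target")]
        est = summarize_stopping(session_from(trials))
        assert est["home"].sd_undefined is False or est["home"].n_trials_used >= 2 \
            or est["home"].sd_ssrt_k is None

    def test_sd_recovery_on_simulator_data(self):
        # target-staircase halts time the stop completion directly; with the
        # generating stop-process SD set to 60 ms the per-subject SD estimate
        # should land within 15 ms given ~72 usable trials
        from stopkin.simulate import SimConfig, simulate_session

        cfg = SimConfig(seed=99, n_blocks=40, stop_sigma=36.0, stop_tau=48.0)
        session, _ = simulate_session(cfg)
        est = summarize_stopping(session.classify())
        e = est["target"]
        assert e.n_trials_used >= 50
        assert abs(e.sd_ssrt_k - 60.0) <= 15.0


class TestRacemodelRegressions:
    def test_equal_rts_give_zero_slope(self):
        trials = []
        for i, ssd in enumerate([66.7, 100.0, 133.3, 166.7] * 5):
            trials.append(stop_trial_halted(ssd=ssd, rt=350.0, staircase="home"))
        df = racemodel_regressions(session_from(trials))
        row = df[(df.staircase == "home") & (df.regression == "failed_stop_rt_vs_ssd")]
        assert row.slope.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_simulator_slope_signs(self, long_sim_session):
        session, _ = long_sim_session
        df = racemodel_regressions(session)
        home = df[df.staircase == "home"].set_index("regression")
        assert home.loc["failed_stop_rt_vs_ssd", "slope"] > 0
        assert home.loc["amplitude_vs_ssd", "slope"] > 0
        assert home.loc["ssrt_k_vs_ssd", "slope"] < 0

    def test_degenerate_ssd_flagged(self):
        trials = [stop_trial_halted(ssd=100.0, rt=300.0 + i) for i in range(12)]
        df = racemodel_regressions(session_from(trials))
        row = df[(df.staircase == "home") & (df.regression == "failed_stop_rt_vs_ssd")]
        assert row.flag.iloc[0] == "degenerate_ssd_variance"

    def test_separable_inhibition_function_flagged(self):
        trials = [stop_trial_still(ssd=66.7 + 33.3 * (i % 3), staircase="home")
                  for i in range(15)]
        trials += [stop_trial_halted(ssd=300.0 + 33.3 * (i % 3), staircase="home")
                   for i in range(15)]
        df = racemodel_regressions(session_from(trials))
        row = df[(df.staircase == "home") & (df.regression == "inhibition_function")]
        assert row.flag.iloc[0] in ("separable", "")
        if row.flag.iloc[0] == "":
            assert row.slope.iloc[0] < 0
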