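"""Trial classification, session I/O, exclusions, outlier filtering."""

import numpy as np
import pandas as pd
import pytest

from stopkin.exceptions import (
    GeometryError,
    SchemaError,
    SessionValidationError,
)
from stopkin.sessions import (
    Rect,
    apply_exclusions,
    classify_trial,
    filter_outliers,
    read_session,
    write_session,
)

from conftest import (
    FRAME,
    START,
    go_trial,
    make_trial,
    session_from,
    stop_trial_halted,
    stop_trial_reached,
    stop_trial_still,
)


class TestClassifyTrial:
    def test_go_trial_times_and_no_error(self):
        oc = classify_trial(go_trial(rt=300.0, entry=700.0))
        assert oc.go_error == "none"
        # first sample at/after the true crossing, so within one frame
        assert 300.0 <= oc.reaction_time <= 300.0 + FRAME
        # waypoint at 700 ms is the target centre; box entry precedes it
        assert oc.reaction_time < oc.total_response_time <= 700.0 + FRAME

    def test_stop_never_leaves_pad_both_definitions_succeed(self):
        oc = classify_trial(stop_trial_still(ssd=100.0))
        assert oc.home_stop_success is True
        assert oc.target_stop_success is True
        assert oc.reaction_time is None

    def test_stop_halts_short_home_fails_target_succeeds(self):
        oc = classify_trial(stop_trial_halted(ssd=100.0))
        assert oc.home_stop_success is False
        assert oc.target_stop_success is True
        assert oc.total_response_time is None

    def test_go_into_wrong_target_is_choice_error(self):
        # path runs to the right-hand target while the cue was left
        tr = go_trial(side="right")
        tr.target_side = "left"
        oc = classify_trial(tr)
        assert oc.go_error == "choice_error"

    def test_go_never_exits_is_omission(self):
        oc = classify_trial(make_trial([(0.0, START)], trial_kind="go"))
        assert oc.go_error == "omission"
        assert oc.reaction_time is None

    def test_go_halting_short_is_missed_target(self):
        tr = make_trial(
            [(0.0, START), (280.0, START), (300.0, (0.0, 2.0)), (600.0, (150.0, 146.0))],
            trial_kind="go",
        )
        assert classify_trial(tr).go_error == "missed_target"

    def test_cursor_in_target_before_go_is_geometry_error(self):
        tr = make_trial([(0.0, START)], trial_kind="go", go_onset=100.0)
        tr.samples[0, 1:3] = (305.0, 301.0)  # pre-go sample inside a target
        with pytest.raises(GeometryError):
            classify_trial(tr)

    def test_subsampling_by_two_shifts_rt_by_at_most_one_interval(self, sim_session):
        session, _ = sim_session
        checked = 0
        for tr, oc in session.classify().iter_classified():
            if oc.reaction_time is None:
                continue
            sub = make_trial([(0.0, START)])  # container; replace fields
            sub.__dict__.update({k: v for k, v in tr.__dict__.items() if k != "samples"})
            sub.samples = tr.samples[::2]
            oc2 = classify_trial(sub)
            assert oc2.reaction_time is not None
            assert abs(oc2.reaction_time - oc.reaction_time) <= tr.frame_ms + 1e-9
            checked += 1
            if checked >= 50:
                break
        assert checked > 0


class TestSessionIO:
    @pytest.mark.parametrize("dialect", ["csv", "json"])
    def test_round_trip_bit_exact(self, tmp_path, dialect):
        session = session_from([
            go_trial(rt=300.0), stop_trial_halted(ssd=100.0),
        ])
        path = str(tmp_path / ("s.json" if dialect == "json" else "sdir"))
        write_session(session, path, dialect)
        back = read_session(path, dialect)
        assert back.participant_id == session.participant_id
        assert len(back.trials) == 2
        for a, b in zip(session.trials, back.trials):
            assert a.trial_kind == b.trial_kind
            assert a.staircase == b.staircase
            assert (a.ssd_actual == b.ssd_actual) or (
                np.isnan(a.ssd_actual) and np.isnan(b.ssd_actual)
            )
            assert a.home_pad == b.home_pad
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_shuffled_timestamps_rejected(self, tmp_path):
        session = session_from([go_trial()])
        path = str(tmp_path / "s.json")
        write_session(session, path)
        import json

        with open(path) as fh:
            payload = json.load(fh)
        payload["trials"][0]["samples"] = payload["trials"][0]["samples"][::-1]
        with open(path, "w") as fh:
            json.dump(payload, fh)
        with pytest.raises(SessionValidationError):
            read_session(path)

    def test_missing_columns_is_schema_error(self, tmp_path):
        session = session_from([go_trial()])
        path = tmp_path / "sdir"
        write_session(session, str(path), "csv")
        df = pd.read_csv(path / "trials.csv").drop(columns=["ssd_actual"])
        df.to_csv(path / "trials.csv", index=False)
        with pytest.raises(SchemaError):
            read_session(str(path), "csv")

    def test_simulated_session_counts(self, tmp_path, sim_session):
        session, _ = sim_session
        path = str(tmp_path / "sim")
        write_session(session, path, "csv")
        back = read_session(path, "csv")
        assert len(back.trials) == 576
        assert len(back.go_trials()) == 432
        assert len(back.stop_trials()) == 144
        assert len(back.stop_trials("home")) == 72


class TestFilterOutliers:
    def test_floor_rule_removes_sub_100ms(self):
        kept, removed = filter_outliers([95.0, 300.0, 310.0])
        assert list(removed) == [95.0]
        assert sorted(kept) == [300.0, 310.0]

    def test_identical_values_all_kept(self):
        kept, removed = filter_outliers([250.0] * 8)
        assert removed.size == 0 and kept.size == 8

    def test_iqr_rule_hand_computed(self):
        # linear-interpolation quartiles of {300,310,320,330,1000}:
        # Q1=310, Q3=330, fence = [280, 360] -> 1000 removed
        kept, removed = filter_outliers([300.0, 310.0, 320.0, 330.0, 1000.0])
        assert list(removed) == [1000.0]
        assert sorted(kept) == [300.0, 310.0, 320.0, 330.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers([])


def _clean_session(pid, n_go=20, n_stop=8):
    """Session passing all exclusion criteria (pStop 50%, fast failed stops)."""
    trials = [go_trial(rt=400.0, entry=800.0) for _ in range(n_go)]
    for i in range(n_stop // 2):
        trials.append(stop_trial_halted(ssd=100.0, rt=300.0, staircase="home"))
        trials.append(stop_trial_still(ssd=100.0, staircase="home"))
        trials.append(stop_trial_reached(ssd=500.0, rt=300.0, entry=700.0,
                                         staircase="target"))
        trials.append(stop_trial_still(ssd=500.0, staircase="target"))
    return session_from(trials, pid=pid)


def _low_pstop_session(pid):
    """Home pStop = 20% (below the 25% criterion)."""
    trials = [go_trial(rt=400.0, entry=800.0) for _ in range(20)]
    for i in range(10):
        if i < 2:
            trials.append(stop_trial_still(ssd=100.0, staircase="home"))
        else:
            trials.append(stop_trial_halted(ssd=100.0, rt=300.0, staircase="home"))
    for i in range(10):
        if i < 5:
            trials.append(stop_trial_still(ssd=500.0, staircase="target"))
        else:
            trials.append(stop_trial_reached(ssd=500.0, rt=300.0, entry=700.0,
                                             staircase="target"))
    return session_from(trials, pid=pid)


def _slow_failed_stop_session(pid):
    """Failed-stop RTs exceed go RTs (violates the race prediction)."""
    trials = [go_trial(rt=300.0, entry=700.0) for _ in range(20)]
    for i in range(4):
        trials.append(stop_trial_halted(ssd=100.0, rt=500.0, halt_t=800.0,
                                        staircase="home"))
        trials.append(stop_trial_still(ssd=100.0, staircase="home"))
        trials.append(stop_trial_reached(ssd=500.0, rt=500.0, entry=900.0,
                                         staircase="target"))
        trials.append(stop_trial_still(ssd=500.0, staircase="target"))
    return session_from(trials, pid=pid)


def _high_go_error_session(pid):
    """Go error rate 25% (above the 20% criterion)."""
    trials = [go_trial(rt=400.0, entry=800.0) for _ in range(15)]
    trials += [make_trial([(0.0, START)], trial_kind="go") for _ in range(5)]
    for i in range(4):
        trials.append(stop_trial_halted(ssd=100.0, rt=300.0, staircase="home"))
        trials.append(stop_trial_still(ssd=100.0, staircase="home"))
        trials.append(stop_trial_reached(ssd=500.0, rt=300.0, entry=700.0,
                                         staircase="target"))
        trials.append(stop_trial_still(ssd=500.0, staircase="target"))
    return session_from(trials, pid=pid)


class TestApplyExclusions:
    def test_low_pstop_excluded(self):
        retained, report = apply_exclusions([_low_pstop_session("bad")])
        assert retained == []
        checks = report.attrs["per_participant"]["bad"]
        assert not checks["pstop_home"]

    def test_clean_session_retained(self):
        retained, _ = apply_exclusions([_clean_session("ok")])
        assert len(retained) == 1

    def test_cohort_counts_mirror_report(self):
        # 40 sessions, 17 injected violations -> 23 retained
        sessions = [_clean_session(f"c{i}") for i in range(23)]
        sessions += [_low_pstop_session(f"p{i}") for i in range(7)]
        sessions += [_slow_failed_stop_session(f"s{i}") for i in range(6)]
        sessions += [_high_go_error_session(f"g{i}") for i in range(4)]
        retained, report = apply_exclusions(sessions)
        assert len(retained) == 23
        all_row = report[report.criterion == "All criteria met"].iloc[0]
        assert all_row.n_meeting == 23 and all_row.n_total == 40
        err_row = report[report.criterion == "Go errors < 20%"].iloc[0]
        assert err_row.n_meeting == 36

    def test_idempotent(self):
        sessions = [_clean_session("a"), _low_pstop_session("b")]
        retained, _ = apply_exclusions(sessions)
        retained2, _ = apply_exclusions(retained)
        assert [s.participant_id for s in retained2] == [
            s.participant_id for s in retained
        ]


def test_rect_half_open():
    r = Rect(0.0, 0.0, 10.0, 10.0)
    assert r.contains(0.0, 0.0)
    assert not r.contains(10.0, 5.0)
    assert not r.contains(5.0, 10.0)
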