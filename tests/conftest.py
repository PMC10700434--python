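"""Shared fixtures: hand-built trials with known geometry, and simulated
sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from stopkin.sessions import Rect, Session, TrialRecord
from stopkin.simulate import SimConfig, simulate_session

FRAME = 1000.0 / 60.0
HOME = Rect(-4.0, -8.0, 4.0, 0.0)
TARGETS = {
    "left": Rect(-325.0, 281.0, -285.0, 321.0),
    "right": Rect(285.0, 281.0, 325.0, 321.0),
}
START = np.array([0.0, -4.0])


def line_path(times, waypoints):
    """Piecewise-linear (t, x, y) samples through (time, point) waypoints."""
    times = np.asarray(times, dtype=float)
    ts = np.array([w[0] for w in waypoints], dtype=float)
    xs = np.array([w[1][0] for w in waypoints], dtype=float)
    ys = np.array([w[1][1] for w in waypoints], dtype=float)
    x = np.interp(times, ts, xs)
    y = np.interp(times, ts, ys)
    return np.column_stack([times, x, y])


def make_trial(
    waypoints,
    trial_kind="go",
    staircase="none",
    ssd=np.nan,
    target_side="right",
    go_onset=0.0,
    t_end=1400.0,
    trial=0,
    block=0,
):
    """TrialRecord whose cursor follows a piecewise-linear path.

    Waypoints are (time_ms_from_go, (x, y)); the cursor sits at the first
    waypoint before it and the last waypoint after it.  Samples run at 60 Hz
    from two frames before go onset.
    """
    times = np.arange(-2 * FRAME, t_end + FRAME / 2, FRAME)
    samples = line_path(times, waypoints)
    samples[:, 0] += go_onset
    return TrialRecord(
        trial_kind=trial_kind,
        staircase=staircase,
        ssd_intended=ssd,
        ssd_actual=ssd,
        target_side=target_side,
        go_onset=go_onset,
        response_deadline=1400.0,
        home_pad=HOME,
        target_boxes=dict(TARGETS),
        samples=samples,
        refresh_rate=60.0,
        block=block,
        trial=trial,
    )


def go_trial(rt=300.0, entry=700.0, side="right", **kw):
    """Go trial exiting the pad at ``rt`` and entering the cued target."""
    tgt = np.array([305.0, 301.0]) * (np.array([-1, 1]) if side == "left" else 1)
    return make_trial(
        [(0.0, START), (rt - FRAME, START), (rt, (0.0, 1.0)), (entry, tgt)],
        trial_kind="go", target_side=side, **kw,
    )


def stop_trial_halted(ssd, rt=300.0, halt_t=600.0, halt_xy=(150.0, 146.0),
                      staircase="home", side="right", **kw):
    """Stop trial: exits the pad, halts short of the target."""
    return make_trial(
        [(0.0, START), (rt - FRAME, START), (rt, (0.0, 1.0)), (halt_t, halt_xy)],
        trial_kind="stop", staircase=staircase, ssd=ssd, target_side=side, **kw,
    )


def stop_trial_still(ssd, staircase="home", side="right", **kw):
    """Stop trial on which the cursor never leaves the home pad."""
    return make_trial([(0.0, START)], trial_kind="stop", staircase=staircase,
                      ssd=ssd, target_side=side, **kw)


def stop_trial_reached(ssd, rt=300.0, entry=760.0, staircase="home",
                       side="right", **kw):
    """Stop trial on which the cursor runs all the way into the cued target."""
    tgt = np.array([305.0, 301.0]) * (np.array([-1, 1]) if side == "left" else 1)
    return make_trial(
        [(0.0, START), (rt - FRAME, START), (rt, (0.0, 1.0)), (entry, tgt)],
        trial_kind="stop", staircase=staircase, ssd=ssd, target_side=side, **kw,
    )


def session_from(trials, pid="p01"):
    for i, tr in enumerate(trials):
        tr.trial = i
    return Session(participant_id=pid, trials=list(trials), refresh_rate=60.0,
                   window_width=1627.0, window_height=834.0)


@pytest.fixture(scope="session")
def sim_session():
    """One default simulated session with its ground truth (seed fixed)."""
    cfg = SimConfig(seed=20240915)
    return simulate_session(cfg, participant_id="simfix")


@pytest.fixture(scope="session")
def long_sim_session():
    """A long session (40 blocks) for recovery / regression checks."""
    cfg = SimConfig(seed=777, n_blocks=40)
    return simulate_session(cfg, participant_id="simlong")


def race_dataset(seed, n_go=300, n_stop=100,
                 go=(450.0, 60.0, 80.0), stop=(200.0, 30.0, 50.0),
                 p_tf=0.05, start_ssd=150.0):
    """RT-level stop-task dataset drawn from the race, SSDs staircased."""
    from stopkin.beests import StopSignalData
    from stopkin.exgauss import exgauss_rvs

    rng = np.random.default_rng(seed)
    go_rts = exgauss_rvs(*go, n_go, rng)
    ssd, step, floor = start_ssd, 100.0 / 3.0, 100.0 / 3.0
    sr_ssd, sr_rt, inh = [], [], []
    for _ in range(n_stop):
        g = float(exgauss_rvs(*go, None, rng))
        if rng.random() < p_tf:
            finish = np.inf
        else:
            finish = ssd + float(exgauss_rvs(*stop, None, rng))
        if g < finish:
            sr_ssd.append(ssd)
            sr_rt.append(g)
            ssd = max(floor, ssd - step)
        else:
            inh.append(ssd)
            ssd += step
    return StopSignalData(go_rts, np.array(sr_ssd), np.array(sr_rt),
                          np.array(inh))
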