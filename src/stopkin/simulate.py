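"""Ground-truth synthetic sessions of the mouse-tracking stop signal task.

The generator implements the independent ex-Gaussian race with trigger
failures and renders each trial as a cursor trajectory:

* go finishing times (home-pad exit) are ex-Gaussian; total response times
  add the (min-jerk) travel time from pad exit to target entry;
* on stop trials the stop runner is omitted with probability ``p_tf``
  (trigger failure); otherwise its finishing time is ex-Gaussian and the
  stop completes at SSD + stop RT;
* stop success follows the canonical race: the home staircase is won when
  the stop completes before pad exit (the movement is then never launched),
  the target staircase when it completes before target entry;
* trajectories are bell-shaped: uninterrupted movements follow a
  minimum-jerk displacement profile to the cued target; interrupted
  movements rise along the same profile, the resultant velocity peaks at
  the stop-completion time and decays as a raised cosine, reaching zero one
  braking duration later (the halt, which is also the maximum displacement);
* two independent SSD staircases step by ~33.3 ms (rounded to the nearest
  frame, floored at 33.3 ms) after each of their stop trials.

Both kinematic ground truths (the stop-completion time, which the peak
velocity marks, and the halt time) are logged per trial so that every
estimator in the package can be scored against its own landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exgauss import ExGaussRaceParams, exgauss_rvs
from .sessions import Rect, Session, TrialRecord, write_session

__all__ = [
    "SimConfig",
    "StaircaseState",
    "GroundTruth",
    "update_staircase",
    "sample_trial",
    "synthesize_trajectory",
    "simulate_session",
    "simulate_cohort",
    "race_params",
]


def _minjerk(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _minjerk_vel(s: np.ndarray) -> np.ndarray:
    return 30 * s**2 - 60 * s**3 + 30 * s**4


_S_GRID = np.linspace(0.0, 1.0, 4001)
_G_GRID = _minjerk(_S_GRID)


def _minjerk_inv(frac: float) -> float:
    """s such that the min-jerk displacement fraction equals ``frac``."""
    return float(np.interp(frac, _G_GRID, _S_GRID))


@dataclass
class SimConfig:
    """Generative parameters for one synthetic session.

    Defaults reproduce realistic magnitudes for this task: go latencies
    with mean ~425 ms, SSRT ~320 ms with intra-individual SD ~60 ms, ~1%
    trigger failures, 18 blocks of 32 trials with 25% stop trials split
    evenly between the two staircases, 60 Hz sampling, and home-pad/target
    geometry scaled to a 1627x834 px browser window (8 px pad, 40 px targets
    at 431 px eccentricity).
    """

    # ex-Gaussian finishing-time parameters (ms)
    go_mu: float = 355.0
    go_sigma: float = 50.0
    go_tau: float = 70.0
    stop_mu: float = 270.0
    stop_sigma: float = 35.0
    stop_tau: float = 50.0
    p_tf: float = 0.01

    # task structure
    n_blocks: int = 18
    trials_per_block: int = 32
    stop_fraction: float = 0.25
    ssd_step: float = 100.0 / 3.0
    ssd_floor: float = 100.0 / 3.0
    start_ssd_home: float = 100.0
    start_ssd_target: float = 500.0
    response_deadline: float = 1400.0
    refresh_rate: float = 60.0

    # trajectory model
    movement_duration: float = 600.0  # full min-jerk duration, onset -> target centre
    movement_jitter: float = 0.0  # fractional SD of per-trial duration
    braking_duration: float = 100.0
    clip_margin_px: float = 2.0  # halt at least this short of target entry
    lateral_noise_px: float = 0.0

    # geometry (px, relative to home-pad centre / top)
    home_pad_size: float = 8.0
    target_size: float = 40.0
    target_distance: float = 431.0
    window_width: float = 1627.0
    window_height: float = 834.0

    # go-error injection rates (per go trial)
    p_omission: float = 0.002
    p_choice_error: float = 0.002
    p_missed_target: float = 0.04

    seed: int = 0

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.refresh_rate

    def round_to_frame(self, t: float) -> float:
        return round(t / self.frame_ms) * self.frame_ms

    @property
    def step_frames(self) -> float:
        return max(1, round(self.ssd_step / self.frame_ms)) * self.frame_ms

    # -- geometry -----------------------------------------------------------
    @property
    def home_pad(self) -> Rect:
        h = self.home_pad_size
        return Rect(-h / 2, -h, h / 2, 0.0)

    @property
    def start_point(self) -> np.ndarray:
        return np.array([0.0, -self.home_pad_size / 2])

    def target_center(self, side: str) -> np.ndarray:
        sgn = -1.0 if side == "left" else 1.0
        u = np.array([sgn * np.sqrt(0.5), np.sqrt(0.5)])
        return self.start_point + self.target_distance * u

    def target_box(self, side: str) -> Rect:
        cx, cy = self.target_center(side)
        h = self.target_size / 2
        return Rect(cx - h, cy - h, cx + h, cy + h)

    def _path_thresholds(self, aim: np.ndarray, side: str) -> tuple[float, float]:
        """(distance at pad exit, distance at cued-target entry) along a ray."""
        start = self.start_point
        direction = aim - start
        dist = float(np.hypot(*direction))
        u = direction / dist
        d = np.linspace(0.0, dist, 2000)
        pts = start + d[:, None] * u
        pad = self.home_pad
        outside = ~pad.contains_many(pts[:, 0], pts[:, 1])
        d_exit = float(d[np.argmax(outside)])
        box = self.target_box(side)
        inside = box.contains_many(pts[:, 0], pts[:, 1])
        d_entry = float(d[np.argmax(inside)]) if inside.any() else np.inf
        return d_exit, d_entry


@dataclass
class StaircaseState:
    """One SSD tracking staircase."""

    ssd: float
    step: float
    floor: float


def update_staircase(state: StaircaseState, stop_success: bool) -> StaircaseState:
    """SSD goes up one step after a successful stop, down after a failure,
    never below the floor; steps are frame-quantised by construction."""
    if stop_success:
        ssd = state.ssd + state.step
    else:
        ssd = max(state.floor, state.ssd - state.step)
    return replace(state, ssd=ssd)


@dataclass
class GroundTruth:
    """Per-trial generative bookkeeping, never visible to estimators."""

    block: int
    trial: int
    trial_kind: str
    staircase: str
    ssd: float
    tf: bool
    go_rt: float  # pad-exit finishing time (ms from go signal)
    trt_nat: float  # natural target-entry time had the movement completed
    stop_rt: float  # NaN on go / trigger-failure trials
    stop_completion: float  # ssd + stop_rt
    halt_time: float  # halt of an interrupted movement (NaN otherwise)
    peak_velocity_time: float  # velocity-peak landmark of the trajectory
    halt_displacement: float
    home_success: bool | None
    target_success: bool | None
    go_error: str = "none"


def _interrupted_displacement(
    t: np.ndarray, m0: float, T: float, D: float, C: float,
    tau_b: float, d_allow: float,
) -> tuple[np.ndarray, float, float, float]:
    """Displacement profile of a movement braked from the stop completion C.

    Returns (d(t), halt_time, halt_displacement, peak_velocity_time).
    """
    sc = min((C - m0) / T, 1.0)
    d_c = D * _minjerk(np.array(sc)).item()
    v_c = D * _minjerk_vel(np.array(sc)).item() / T  # px per ms
    natural_halt = d_c + v_c * tau_b / 2.0
    if natural_halt <= d_allow or v_c <= 0:
        tau = tau_b
        d_halt = natural_halt
    else:
        tau = max(2.0 * (d_allow - d_c) / v_c, 0.0)
        d_halt = d_c + v_c * tau / 2.0
    rel = np.asarray(t, dtype=float) - m0
    s = np.clip(rel / T, 0.0, 1.0)
    d = D * _minjerk(s)
    brake = rel > (C - m0)
    if tau > 0:
        u = np.clip((np.asarray(t) - C) / tau, 0.0, 1.0)
        d_brake = d_c + v_c * tau * (u + np.sin(np.pi * u) / np.pi) / 2.0
    else:
        d_brake = np.full_like(d, d_halt)
    d = np.where(brake, d_brake, d)
    d = np.where(np.asarray(t) >= C + tau, d_halt, d)
    d[rel < 0] = 0.0
    peak_t = min(C, m0 + T / 2.0)
    return d, C + tau, d_halt, peak_t


def sample_trial(
    config: SimConfig,
    rng: np.random.Generator,
    trial_kind: str,
    staircase: str,
    target_side: str,
    ssd: float,
    block: int = 0,
    trial: int = 0,
) -> tuple[TrialRecord, GroundTruth]:
    """Draw one trial of the race and synthesise its trajectory."""
    frame = config.frame_ms
    go_onset = config.round_to_frame(rng.uniform(1000.0, 1500.0))
    go_rt = float(exgauss_rvs(config.go_mu, config.go_sigma, config.go_tau, None, rng))
    go_rt = max(go_rt, 2 * frame)
    T = config.movement_duration
    if config.movement_jitter > 0:
        T *= max(1.0 + config.movement_jitter * rng.standard_normal(), 0.5)

    go_error = "none"
    aim_side = target_side
    aim = config.target_center(target_side)
    if trial_kind == "go":
        u = rng.random()
        if u < config.p_omission:
            go_error = "omission"
        elif u < config.p_omission + config.p_choice_error:
            go_error = "choice_error"
            aim_side = "left" if target_side == "right" else "right"
            aim = config.target_center(aim_side)
        elif u < config.p_omission + config.p_choice_error + config.p_missed_target:
            go_error = "missed_target"
            # aim just beside the cued target so the path never enters the box
            offset = np.array([0.0, 1.4 * config.target_size])
            aim = config.target_center(target_side) + offset

    d_exit, d_entry = config._path_thresholds(aim, aim_side)
    D = float(np.hypot(*(aim - config.start_point)))
    t_exit_off = T * _minjerk_inv(d_exit / D)
    m0 = max(go_rt - t_exit_off, 0.0)  # pathological fast draws: launch at go
    trt_nat = m0 + T * _minjerk_inv(min(d_entry / D, 1.0)) if np.isfinite(d_entry) else np.inf

    ssd_actual = config.round_to_frame(ssd) if trial_kind == "stop" else np.nan
    tf = False
    stop_rt = np.nan
    stop_completion = np.nan
    if trial_kind == "stop":
        tf = bool(rng.random() < config.p_tf)
        if not tf:
            stop_rt = float(
                exgauss_rvs(config.stop_mu, config.stop_sigma, config.stop_tau, None, rng)
            )
            stop_rt = max(stop_rt, 0.0)
            stop_completion = ssd_actual + stop_rt

    gt = GroundTruth(
        block=block, trial=trial, trial_kind=trial_kind, staircase=staircase,
        ssd=ssd_actual if trial_kind == "stop" else np.nan, tf=tf,
        go_rt=go_rt, trt_nat=trt_nat, stop_rt=stop_rt,
        stop_completion=stop_completion, halt_time=np.nan,
        peak_velocity_time=np.nan, halt_displacement=np.nan,
        home_success=None, target_success=None, go_error=go_error,
    )

    record = TrialRecord(
        trial_kind=trial_kind,
        staircase=staircase,
        ssd_intended=float(ssd) if trial_kind == "stop" else np.nan,
        ssd_actual=float(ssd_actual) if trial_kind == "stop" else np.nan,
        target_side=target_side,
        go_onset=go_onset,
        response_deadline=config.response_deadline,
        home_pad=config.home_pad,
        target_boxes={"left": config.target_box("left"), "right": config.target_box("right")},
        samples=np.empty((0, 3)),
        refresh_rate=config.refresh_rate,
        block=block,
        trial=trial,
    )
    record.samples = synthesize_trajectory(
        gt, config, record, aim=aim, m0=m0, T=T, D=D, d_entry=d_entry, rng=rng
    )
    return record, gt


def synthesize_trajectory(
    gt: GroundTruth,
    config: SimConfig,
    record: TrialRecord,
    aim: np.ndarray,
    m0: float,
    T: float,
    D: float,
    d_entry: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one trial's cursor samples at the frame rate; fills in the
    race outcome and kinematic-landmark ground truths on ``gt``."""
    frame = config.frame_ms
    go_onset = record.go_onset
    n_pre = 2
    t_end = go_onset + config.response_deadline + frame
    t = np.arange(-n_pre * frame, t_end - go_onset + frame / 2, frame)  # rel. to go

    omitted = gt.go_error == "omission"
    interrupted = False
    if gt.trial_kind == "stop" and not gt.tf:
        C = gt.stop_completion
        gt.home_success = bool(C <= gt.go_rt)
        gt.target_success = bool(C <= gt.trt_nat)
        if gt.home_success:
            omitted = True  # stop won before launch: movement never starts
        elif gt.target_success:
            interrupted = True
    elif gt.trial_kind == "stop":  # trigger failure: runs to the target
        gt.home_success = False
        gt.target_success = False

    if omitted:
        d = np.zeros_like(t)
    elif interrupted:
        d, halt_t, d_halt, peak_t = _interrupted_displacement(
            t, m0, T, D, gt.stop_completion, config.braking_duration,
            d_entry - config.clip_margin_px,
        )
        gt.halt_time = halt_t
        gt.halt_displacement = d_halt
        gt.peak_velocity_time = peak_t
    else:
        s = np.clip((t - m0) / T, 0.0, 1.0)
        d = D * _minjerk(s)
        gt.peak_velocity_time = m0 + T / 2.0
        gt.halt_displacement = D

    start = config.start_point
    u = (aim - start) / D
    pts = start + d[:, None] * u
    if config.lateral_noise_px > 0:
        perp = np.array([-u[1], u[0]])
        wiggle = config.lateral_noise_px * rng.standard_normal(len(t))
        wiggle[d <= 0] = 0.0
        pts = pts + wiggle[:, None] * perp
    return np.column_stack([t + go_onset, pts])


def _block_plan(config: SimConfig, rng: np.random.Generator) -> list:
    """Trial plan for one block: (kind, staircase, side) tuples, shuffled."""
    tpb = config.trials_per_block
    n_stop = int(round(config.stop_fraction * tpb))
    n_home = n_stop // 2
    n_target = n_stop - n_home
    plan = []
    for staircase, n in (("home", n_home), ("target", n_target)):
        sides = ["left", "right"] * (n // 2 + 1)
        plan += [("stop", staircase, sides[i]) for i in range(n)]
    n_go = tpb - n_stop
    go_sides = (["left", "right"] * (n_go // 2 + 1))[:n_go]
    plan += [("go", "none", s) for s in go_sides]
    order = rng.permutation(len(plan))
    return [plan[i] for i in order]


def simulate_session(
    config: SimConfig, participant_id: str = "sim01"
) -> tuple[Session, pd.DataFrame]:
    """Simulate one full session plus its ground-truth table."""
    rng = np.random.default_rng(config.seed)
    frame_step = config.step_frames
    floor = config.round_to_frame(config.ssd_floor)
    states = {
        "home": StaircaseState(config.round_to_frame(config.start_ssd_home), frame_step, floor),
        "target": StaircaseState(config.round_to_frame(config.start_ssd_target), frame_step, floor),
    }
    trials, gts = [], []
    idx = 0
    for block in range(config.n_blocks):
        for kind, staircase, side in _block_plan(config, rng):
            ssd = states[staircase].ssd if kind == "stop" else np.nan
            rec, gt = sample_trial(
                config, rng, kind, staircase, side, ssd, block=block, trial=idx
            )
            trials.append(rec)
            gts.append(gt)
            if kind == "stop":
                success = gt.home_success if staircase == "home" else gt.target_success
                states[staircase] = update_staircase(states[staircase], bool(success))
            idx += 1
    session = Session(
        participant_id=participant_id,
        trials=trials,
        refresh_rate=config.refresh_rate,
        window_width=config.window_width,
        window_height=config.window_height,
    )
    gt_df = pd.DataFrame([vars(g) for g in gts])
    gt_df.insert(0, "participant_id", participant_id)
    return session, gt_df


def simulate_cohort(
    configs: list, out_dir: str | None = None, dialect: str = "csv"
) -> tuple[list, pd.DataFrame]:
    """Simulate several subjects; optionally write sessions + ground truth.

    Ground truth is written to a separate table so that estimators under
    test can only ever see the session files.
    """
    import os

    sessions, gt_frames = [], []
    for i, cfg in enumerate(configs):
        pid = f"sim{i + 1:02d}"
        session, gt = simulate_session(cfg, participant_id=pid)
        sessions.append(session)
        gt_frames.append(gt)
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            if dialect == "json":
                write_session(session, os.path.join(out_dir, f"{pid}.json"), "json")
            else:
                write_session(session, os.path.join(out_dir, pid), "csv")
    gt_all = pd.concat(gt_frames, ignore_index=True)
    if out_dir is not None:
        gt_all.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    return sessions, gt_all


def race_params(config: SimConfig) -> ExGaussRaceParams:
    """The generating race parameters as seen by the home staircase.

    The home-staircase go runner is the pad-exit time, whose distribution is
    the configured go ex-Gaussian; the trigger-failure probit is the inverse
    normal CDF of ``p_tf``.
    """
    from scipy.special import ndtri

    tf_probit = float(ndtri(np.clip(config.p_tf, 1e-12, 1 - 1e-12)))
    return ExGaussRaceParams(
        config.go_mu, config.go_sigma, config.go_tau,
        config.stop_mu, config.stop_sigma, config.stop_tau, tf_probit,
    )
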