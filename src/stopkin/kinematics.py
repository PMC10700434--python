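"""Single-trial kinematic decomposition of stopping behaviour.

Each trajectory is reduced to a resultant-displacement profile (Euclidean
distance from the point at which the cursor left the home pad) and its time
derivative, estimated by central differences on the possibly non-uniform
sample grid.  Two kinematic landmarks provide single-trial stop signal
reaction times (SSRT):

* home staircase, failed stops that still halted short of the target —
  the time of peak resultant velocity minus the stop signal time (the peak
  marks the point at which the interrupted movement starts to decelerate);
* target staircase, successful stops with movement initiated — the time of
  maximum resultant displacement (the halt) minus the stop signal time.

Trigger failures are the home-staircase stop trials on which the cursor
reached the cued target within the response deadline: the stop process was
seemingly never engaged despite ample time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InsufficientDataError, TrialCategoryError
from .sessions import Session, TrialOutcome, TrialRecord, classify_trial, filter_outliers

__all__ = [
    "KinematicProfile",
    "StaircaseEstimates",
    "StopEstimates",
    "central_difference",
    "compute_profile",
    "single_trial_ssrt",
    "detect_trigger_failure",
    "collect_single_trial_ssrts",
    "summarize_stopping",
    "racemodel_regressions",
    "kinematics_table",
]


@dataclass
class KinematicProfile:
    """Resultant displacement/velocity time series with landmark times.

    Times are ms relative to the go signal; displacement is px relative to
    the home-pad exit sample; velocity is px/s.
    """

    times: np.ndarray
    resultant_displacement: np.ndarray
    resultant_velocity: np.ndarray
    peak_velocity_time: float
    max_displacement_time: float
    amplitude: float


@dataclass
class StaircaseEstimates:
    """Per-staircase stopping estimates (kinematic + Race-Model)."""

    staircase: str
    ssrt_rm: float | None = None
    ssrt_k_trials: np.ndarray = field(default_factory=lambda: np.empty(0))
    ssrt_k_mean: float | None = None
    sd_ssrt_k: float | None = None
    tf_k_percent: float | None = None
    n_trials_used: int = 0
    n_stop_trials: int = 0
    sd_undefined: bool = False


@dataclass
class StopEstimates:
    """Stopping estimates for one participant, keyed by staircase."""

    participant_id: str
    home: StaircaseEstimates
    target: StaircaseEstimates

    def __getitem__(self, staircase: str) -> StaircaseEstimates:
        return getattr(self, staircase)


def central_difference(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Derivative of y(t) by central differences on a non-uniform grid.

    One-sided differences are used at the two endpoints.  Equivalent to
    ``np.gradient(y, t)``; kept as a named primitive because the derivative
    of the resultant-displacement scalar is the quantity the kinematic
    estimators are defined on.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise InsufficientDataError("central differences need at least 3 samples")
    return np.gradient(y, t)


def compute_profile(
    trial: TrialRecord,
    outcome: TrialOutcome | None = None,
    smooth_window: int | None = None,
) -> KinematicProfile:
    """Kinematic profile of a trial, from the home-pad exit sample onward.

    Displacement is measured relative to the exit-point sample (no
    interpolation before the first recorded exit).  Velocity is the central
    difference of the resultant-displacement scalar — not the norm of the
    component velocities, which differs on curved paths.  Landmark times are
    the argmax sample times; the earliest sample wins on ties.

    ``smooth_window`` optionally applies a centred moving average of that
    many samples to the displacement before differentiation; the default is
    no smoothing.
    """
    if outcome is None:
        outcome = classify_trial(trial)
    if outcome.reaction_time is None:
        raise InsufficientDataError(
            f"block {trial.block} trial {trial.trial}: cursor never left the home pad"
        )
    rel = trial.t - trial.go_onset
    exit_idx = int(np.searchsorted(rel, outcome.reaction_time))
    t = rel[exit_idx:]
    if t.size < 3:
        raise InsufficientDataError(
            f"block {trial.block} trial {trial.trial}: <3 samples after pad exit"
        )
    xy = trial.xy[exit_idx:]
    disp = np.hypot(xy[:, 0] - xy[0, 0], xy[:, 1] - xy[0, 1])
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(int(smooth_window)) / int(smooth_window)
        disp_s = np.convolve(disp, kernel, mode="same")
        # keep the endpoints unsmoothed (partial windows distort them)
        k = int(smooth_window) // 2
        disp_s[:k], disp_s[-k:] = disp[:k], disp[-k:]
        disp = disp_s
    vel = central_difference(t, disp) * 1000.0  # ms -> s
    i_v = int(np.argmax(vel))
    i_d = int(np.argmax(disp))
    return KinematicProfile(
        times=t,
        resultant_displacement=disp,
        resultant_velocity=vel,
        peak_velocity_time=float(t[i_v]),
        max_displacement_time=float(t[i_d]),
        amplitude=float(disp[i_d]),
    )


def single_trial_ssrt(
    trial: TrialRecord,
    profile: KinematicProfile,
    mode: str,
    outcome: TrialOutcome | None = None,
) -> float:
    """Single-trial SSRT from a kinematic landmark, in ms.

    ``mode="home"`` (failed stops that halted short of the target) returns
    peak-velocity time minus the stop signal time; ``mode="target"``
    (successful stops with movement initiated) returns maximum-displacement
    time minus the stop signal time.  Negative values are legal outputs,
    flagged only by the downstream outlier filters.
    """
    if trial.trial_kind != "stop":
        raise TrialCategoryError("single_trial_ssrt requires a stop trial")
    if outcome is None:
        outcome = classify_trial(trial)
    if mode == "home":
        if not (outcome.home_stop_success is False and outcome.target_stop_success is True):
            raise TrialCategoryError(
                "home mode requires a failed home stop that halted short of the target"
            )
        return float(profile.peak_velocity_time - trial.ssd_actual)
    if mode == "target":
        if not (outcome.target_stop_success is True and outcome.reaction_time is not None):
            raise TrialCategoryError(
                "target mode requires a successful target stop with movement initiated"
            )
        return float(profile.max_displacement_time - trial.ssd_actual)
    raise ValueError(f"unknown mode {mode!r}")


def detect_trigger_failure(trial: TrialRecord, outcome: TrialOutcome | None = None) -> bool:
    """True iff the cursor entered the cued target within the deadline.

    Defined for home-staircase stop trials: with the short SSDs tracked by
    the home staircase, a movement that runs all the way to the target had
    ample time to be stopped, so the stop process was presumably never
    triggered.
    """
    if trial.trial_kind != "stop" or trial.staircase != "home":
        raise TrialCategoryError("detect_trigger_failure requires a home-staircase stop trial")
    if outcome is None:
        outcome = classify_trial(trial)
    return (
        outcome.total_response_time is not None
        and outcome.entered_side == trial.target_side
    )


def collect_single_trial_ssrts(session: Session, staircase: str) -> np.ndarray:
    """Raw (unfiltered) single-trial SSRT values for one staircase.

    Home staircase: failed stops that halted short of the target, excluding
    trigger-failure trials (they have no stop process to time).  Target
    staircase: successful stops with movement initiated.  Trials with too few
    post-exit samples are skipped.
    """
    values = []
    for tr, oc in session.iter_classified(kind="stop", staircase=staircase):
        try:
            if staircase == "home":
                if not (oc.home_stop_success is False and oc.target_stop_success is True):
                    continue
                prof = compute_profile(tr, oc)
                values.append(single_trial_ssrt(tr, prof, "home", oc))
            else:
                if not (oc.target_stop_success is True and oc.reaction_time is not None):
                    continue
                prof = compute_profile(tr, oc)
                values.append(single_trial_ssrt(tr, prof, "target", oc))
        except InsufficientDataError:
            continue
    return np.asarray(values, dtype=float)


def summarize_stopping(session: Session) -> StopEstimates:
    """Per-participant kinematic and Race-Model stopping estimates.

    Single-trial SSRT distributions pass through the standard latency
    outlier filter (including the 100 ms floor) before the mean and sample
    standard deviation are taken.  The trigger-failure rate is computed over
    all home-staircase stop trials.
    """
    from .race import integration_ssrt_for_session  # local import avoids cycle

    if session.outcomes is None:
        session.classify()
    out = {}
    for staircase in ("home", "target"):
        est = StaircaseEstimates(staircase=staircase)
        stop_trials = list(session.iter_classified(kind="stop", staircase=staircase))
        est.n_stop_trials = len(stop_trials)
        raw = collect_single_trial_ssrts(session, staircase)
        if raw.size:
            kept, _ = filter_outliers(raw)
        else:
            kept = raw
        est.ssrt_k_trials = kept
        est.n_trials_used = int(kept.size)
        if kept.size:
            est.ssrt_k_mean = float(np.mean(kept))
        if kept.size >= 2:
            est.sd_ssrt_k = float(np.std(kept, ddof=1))
        else:
            est.sd_undefined = True
        if staircase == "home" and stop_trials:
            n_tf = sum(detect_trigger_failure(tr, oc) for tr, oc in stop_trials)
            est.tf_k_percent = 100.0 * n_tf / len(stop_trials)
        try:
            est.ssrt_rm = integration_ssrt_for_session(session, staircase)
        except Exception:
            est.ssrt_rm = None
        out[staircase] = est
    return StopEstimates(
        participant_id=session.participant_id, home=out["home"], target=out["target"]
    )


# ---------------------------------------------------------------------------
# Race-Model consistency regressions
# ---------------------------------------------------------------------------

_MIN_REGRESSION_N = 10


def _ols_slope(x: np.ndarray, y: np.ndarray) -> dict:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = {"slope": np.nan, "n": int(x.size), "flag": ""}
    if x.size < _MIN_REGRESSION_N:
        res["flag"] = "too_few_trials"
        return res
    if np.ptp(x) == 0:
        res["flag"] = "degenerate_ssd_variance"
        return res
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    res["slope"] = float(fit.params[1])
    return res


def _logistic_slope(x: np.ndarray, y: np.ndarray) -> dict:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = {"slope": np.nan, "n": int(x.size), "flag": ""}
    if x.size < _MIN_REGRESSION_N:
        res["flag"] = "too_few_trials"
        return res
    if np.ptp(x) == 0:
        res["flag"] = "degenerate_ssd_variance"
        return res
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
        slope = float(fit.params[1])
        if not np.isfinite(slope) or abs(slope) > 10:
            res["flag"] = "separable"
        else:
            res["slope"] = slope
    except Exception:
        res["flag"] = "separable"
    return res


def racemodel_regressions(session: Session) -> pd.DataFrame:
    """Single-trial regression slopes diagnostic of the independent race.

    Per staircase: (i) OLS slope of failed-stop response time on SSD,
    (ii) OLS slope of movement amplitude on SSD over initiated-but-stopped
    trials, (iii) OLS slope of single-trial SSRT on SSD, and (iv) the
    logistic slope of stop success on SSD (the inhibition function).  Under
    the race, (i) and (ii) are positive and (iii) negative; (iv) is negative
    for the success~SSD coding used here.
    """
    if session.outcomes is None:
        session.classify()
    rows = []
    for staircase in ("home", "target"):
        trials = list(session.iter_classified(kind="stop", staircase=staircase))

        # (i) failed-stop latency vs SSD, using the staircase's own latency
        ssd, lat = [], []
        for tr, oc in trials:
            if staircase == "home" and oc.home_stop_success is False and oc.reaction_time is not None:
                ssd.append(tr.ssd_actual)
                lat.append(oc.reaction_time)
            elif staircase == "target" and oc.target_stop_success is False and oc.total_response_time is not None:
                ssd.append(tr.ssd_actual)
                lat.append(oc.total_response_time)
        rows.append(dict(staircase=staircase, regression="failed_stop_rt_vs_ssd",
                         **_ols_slope(np.array(ssd), np.array(lat))))

        # (ii) amplitude vs SSD over initiated-but-stopped trials
        ssd, amp = [], []
        for tr, oc in trials:
            if oc.reaction_time is not None and oc.target_stop_success is True:
                try:
                    prof = compute_profile(tr, oc)
                except InsufficientDataError:
                    continue
                ssd.append(tr.ssd_actual)
                amp.append(prof.amplitude)
        rows.append(dict(staircase=staircase, regression="amplitude_vs_ssd",
                         **_ols_slope(np.array(ssd), np.array(amp))))

        # (iii) single-trial SSRT vs SSD
        ssd, val = [], []
        for tr, oc in trials:
            try:
                if staircase == "home":
                    if not (oc.home_stop_success is False and oc.target_stop_success is True):
                        continue
                    prof = compute_profile(tr, oc)
                    v = single_trial_ssrt(tr, prof, "home", oc)
                else:
                    if not (oc.target_stop_success is True and oc.reaction_time is not None):
                        continue
                    prof = compute_profile(tr, oc)
                    v = single_trial_ssrt(tr, prof, "target", oc)
            except InsufficientDataError:
                continue
            ssd.append(tr.ssd_actual)
            val.append(v)
        rows.append(dict(staircase=staircase, regression="ssrt_k_vs_ssd",
                         **_ols_slope(np.array(ssd), np.array(val))))

        # (iv) inhibition function: stop success vs SSD (logistic)
        ssd, succ = [], []
        for tr, oc in trials:
            flag = oc.home_stop_success if staircase == "home" else oc.target_stop_success
            ssd.append(tr.ssd_actual)
            succ.append(1.0 if flag else 0.0)
        rows.append(dict(staircase=staircase, regression="inhibition_function",
                         **_logistic_slope(np.array(ssd), np.array(succ))))
    return pd.DataFrame(rows, columns=["staircase", "regression", "slope", "n", "flag"])


def kinematics_table(session: Session) -> pd.DataFrame:
    """Per-trial kinematics table for delimited-text export."""
    if session.outcomes is None:
        session.classify()
    rows = []
    for tr, oc in session.iter_classified(kind="stop"):
        row = dict(
            participant_id=session.participant_id,
            block=tr.block,
            trial=tr.trial,
            staircase=tr.staircase,
            ssd=tr.ssd_actual,
            reaction_time=oc.reaction_time,
            total_response_time=oc.total_response_time,
            peak_velocity_time=np.nan,
            max_displacement_time=np.nan,
            amplitude=np.nan,
            ssrt_k=np.nan,
            tf=detect_trigger_failure(tr, oc) if tr.staircase == "home" else False,
        )
        try:
            prof = compute_profile(tr, oc)
            row.update(
                peak_velocity_time=prof.peak_velocity_time,
                max_displacement_time=prof.max_displacement_time,
                amplitude=prof.amplitude,
            )
            mode = tr.staircase
            row["ssrt_k"] = single_trial_ssrt(tr, prof, mode, oc)
        except (InsufficientDataError, TrialCategoryError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)
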