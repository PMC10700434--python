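"""Trial data model, session I/O, outcome classification and filtering.

A session is one participant's run of the mouse-tracking stop signal task:
ordered trials, each carrying metadata (trial kind, staircase assignment,
stop signal delay, cued target side) and the recorded cursor trajectory
(time in ms, x/y position in px at the monitor refresh rate).

Coordinates follow the task's screen convention: x is measured relative to
the home-pad centre, y relative to the home-pad top, with y increasing
toward the targets.  Rectangles are half-open in pixel coordinates, so
"exiting the home pad" means the first sample strictly outside the pad and
"entering a target" means the first sample inside the box.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    GeometryError,
    SchemaError,
    SessionValidationError,
)

__all__ = [
    "Rect",
    "CursorSample",
    "TrialRecord",
    "TrialOutcome",
    "Session",
    "read_session",
    "write_session",
    "classify_trial",
    "classify_session",
    "apply_exclusions",
    "filter_outliers",
    "GO_ERRORS",
]

GO_ERRORS = ("none", "omission", "choice_error", "missed_target")

#: Performance criteria used to retain a participant, mirroring the
#: standard screening for this task: failed-stop RT faster than go RT (per
#: staircase on its own response-time definition), pStop between 25 and 75%
#: per staircase, and a go error rate below 20%.
PSTOP_LO = 0.25
PSTOP_HI = 0.75
GO_ERROR_MAX = 0.20

#: Response-time outlier rule: values below this floor (ms) are always removed.
RT_FLOOR_MS = 100.0


class Rect(NamedTuple):
    """Axis-aligned rectangle, half-open: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return (self.x0 <= x < self.x1) and (self.y0 <= y < self.y1)

    def contains_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (self.x0 <= x) & (x < self.x1) & (self.y0 <= y) & (y < self.y1)

    @property
    def degenerate(self) -> bool:
        return not (self.x1 > self.x0 and self.y1 > self.y0)

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


class CursorSample(NamedTuple):
    """One cursor sample: time since trial onset (ms) and position (px)."""

    t: float
    x: float
    y: float


@dataclass
class TrialRecord:
    """One task trial: metadata plus the recorded cursor trajectory.

    ``samples`` is an (n, 3) float array with columns (t, x, y); times are ms
    since trial onset and must be strictly increasing.  ``ssd_actual`` is the
    frame-quantised stop signal delay actually realised on screen; it is NaN
    on go trials.
    """

    trial_kind: str  # "go" | "stop"
    staircase: str  # "home" | "target" | "none"
    ssd_intended: float
    ssd_actual: float
    target_side: str  # "left" | "right"
    go_onset: float
    response_deadline: float
    home_pad: Rect
    target_boxes: dict  # {"left": Rect, "right": Rect}
    samples: np.ndarray
    refresh_rate: float
    block: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)

    @property
    def t(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.refresh_rate

    def cursor_samples(self) -> list:
        return [CursorSample(*row) for row in self.samples]

    def validate(self) -> None:
        """Raise SessionValidationError / GeometryError on invariant violations."""
        label = f"block {self.block} trial {self.trial}"
        if self.trial_kind not in ("go", "stop"):
            raise SessionValidationError(f"{label}: unknown trial_kind {self.trial_kind!r}")
        if self.trial_kind == "stop":
            if self.staircase not in ("home", "target"):
                raise SessionValidationError(
                    f"{label}: stop trial must carry a home/target staircase"
                )
            if not (self.ssd_actual >= 0):
                raise SessionValidationError(f"{label}: stop trial needs ssd_actual >= 0")
        else:
            if not (math.isnan(self.ssd_actual) and math.isnan(self.ssd_intended)):
                raise SessionValidationError(f"{label}: go trial must not carry an SSD")
        if self.target_side not in ("left", "right"):
            raise SessionValidationError(f"{label}: target_side must be left/right")
        t = self.t
        if len(t) and not np.all(np.diff(t) > 0):
            raise SessionValidationError(f"{label}: sample timestamps not strictly increasing")
        rects = [self.home_pad, self.target_boxes["left"], self.target_boxes["right"]]
        if any(r.degenerate for r in rects):
            raise GeometryError(f"{label}: degenerate rectangle")
        for i in range(3):
            for j in range(i + 1, 3):
                if rects[i].overlaps(rects[j]):
                    raise GeometryError(f"{label}: overlapping rectangles")


@dataclass(frozen=True)
class TrialOutcome:
    """Derived timings and outcome labels for one trial.

    ``reaction_time`` is the first sample time (minus go onset) at which the
    cursor is strictly outside the home pad; ``total_response_time`` the first
    time it is inside a target box within the response deadline.  Go trials
    carry exactly one error label; stop trials carry both stop-success flags
    (one per staircase definition) regardless of the staircase that was
    actually adjusted on that trial.
    """

    reaction_time: float | None
    total_response_time: float | None
    go_error: str | None  # one of GO_ERRORS for go trials, None for stop trials
    home_stop_success: bool | None
    target_stop_success: bool | None
    entered_side: str | None = None  # which target box was entered first, if any


@dataclass
class Session:
    """One participant's ordered trials plus monitor metadata."""

    participant_id: str
    trials: list
    refresh_rate: float
    window_width: float
    window_height: float
    outcomes: list | None = field(default=None, repr=False)

    def validate(self) -> None:
        for tr in self.trials:
            tr.validate()

    def stop_trials(self, staircase: str | None = None) -> list:
        out = [t for t in self.trials if t.trial_kind == "stop"]
        if staircase is not None:
            out = [t for t in out if t.staircase == staircase]
        return out

    def go_trials(self) -> list:
        return [t for t in self.trials if t.trial_kind == "go"]

    def classify(self) -> "Session":
        """Classify every trial, caching outcomes on the session."""
        self.outcomes = [classify_trial(t) for t in self.trials]
        return self

    def iter_classified(self, kind: str | None = None, staircase: str | None = None):
        if self.outcomes is None:
            self.classify()
        for tr, oc in zip(self.trials, self.outcomes):
            if kind is not None and tr.trial_kind != kind:
                continue
            if staircase is not None and tr.staircase != staircase:
                continue
            yield tr, oc


# ---------------------------------------------------------------------------
# Trial classification
# ---------------------------------------------------------------------------

def classify_trial(trial: TrialRecord) -> TrialOutcome:
    """Derive timings and outcome labels from the cursor trajectory.

    Reaction time is defined by the cursor exiting the home pad and total
    response time by it entering a target box; stopping on the home staircase
    is successful when the cursor never leaves the pad, and on the target
    staircase when it never enters a target within the deadline.
    """
    t = trial.t
    x = trial.samples[:, 1]
    y = trial.samples[:, 2]
    rel = t - trial.go_onset

    pre_go = rel < 0
    for side, box in trial.target_boxes.items():
        if np.any(box.contains_many(x[pre_go], y[pre_go])):
            raise GeometryError(
                f"block {trial.block} trial {trial.trial}: cursor inside "
                f"{side} target before go onset"
            )

    post = rel >= 0
    in_window = post & (rel <= trial.response_deadline)

    outside_pad = ~trial.home_pad.contains_many(x, y)
    exit_idx = np.flatnonzero(outside_pad & in_window)
    reaction_time = float(rel[exit_idx[0]]) if exit_idx.size else None

    entered_side = None
    total_response_time = None
    for side, box in trial.target_boxes.items():
        idx = np.flatnonzero(box.contains_many(x, y) & in_window)
        if idx.size:
            rt_entry = float(rel[idx[0]])
            if total_response_time is None or rt_entry < total_response_time:
                total_response_time = rt_entry
                entered_side = side

    if trial.trial_kind == "go":
        if reaction_time is None:
            go_error = "omission"
        elif entered_side is not None and entered_side != trial.target_side:
            go_error = "choice_error"
        elif entered_side is None:
            go_error = "missed_target"
        else:
            go_error = "none"
        return TrialOutcome(
            reaction_time=reaction_time,
            total_response_time=total_response_time,
            go_error=go_error,
            home_stop_success=None,
            target_stop_success=None,
            entered_side=entered_side,
        )

    home_success = reaction_time is None
    target_success = total_response_time is None
    return TrialOutcome(
        reaction_time=reaction_time,
        total_response_time=total_response_time,
        go_error=None,
        home_stop_success=home_success,
        target_stop_success=target_success,
        entered_side=entered_side,
    )


def classify_session(session: Session) -> Session:
    return session.classify()


# ---------------------------------------------------------------------------
# Participant exclusions
# ---------------------------------------------------------------------------

def _go_error_rate(session: Session) -> float:
    gos = list(session.iter_classified(kind="go"))
    if not gos:
        return float("nan")
    n_err = sum(1 for _, oc in gos if oc.go_error != "none")
    return n_err / len(gos)


def _pstop(session: Session, staircase: str) -> float:
    trials = list(session.iter_classified(kind="stop", staircase=staircase))
    if not trials:
        return float("nan")
    if staircase == "home":
        n_succ = sum(1 for _, oc in trials if oc.home_stop_success)
    else:
        n_succ = sum(1 for _, oc in trials if oc.target_stop_success)
    return n_succ / len(trials)


def _failed_stop_vs_go(session: Session, staircase: str) -> bool | None:
    """True if mean failed-stop latency < mean go latency (Race Model check).

    The home staircase compares reaction times, the target staircase total
    response times, matching each staircase's own response definition.
    """
    if staircase == "home":
        fs = [
            oc.reaction_time
            for _, oc in session.iter_classified(kind="stop", staircase="home")
            if oc.home_stop_success is False and oc.reaction_time is not None
        ]
        go = [
            oc.reaction_time
            for _, oc in session.iter_classified(kind="go")
            if oc.reaction_time is not None
        ]
    else:
        fs = [
            oc.total_response_time
            for _, oc in session.iter_classified(kind="stop", staircase="target")
            if oc.target_stop_success is False and oc.total_response_time is not None
        ]
        go = [
            oc.total_response_time
            for _, oc in session.iter_classified(kind="go")
            if oc.total_response_time is not None
        ]
    if not fs or not go:
        return None
    return float(np.mean(fs)) < float(np.mean(go))


def apply_exclusions(sessions: Sequence[Session]) -> tuple[list, pd.DataFrame]:
    """Retain sessions meeting the task performance criteria.

    Returns the retained sessions and a report table with one row per
    criterion (plus the all-criteria row), in the standard exclusion-table
    layout for this task.  Idempotent: re-applying to the retained set removes
    nothing further.
    """
    checks = {}
    for s in sessions:
        if s.outcomes is None:
            s.classify()
        fs_home = _failed_stop_vs_go(s, "home")
        fs_target = _failed_stop_vs_go(s, "target")
        ps_home = _pstop(s, "home")
        ps_target = _pstop(s, "target")
        err = _go_error_rate(s)
        checks[s.participant_id] = {
            "fsrt_lt_gort_home": bool(fs_home) if fs_home is not None else False,
            "fsrt_lt_gort_target": bool(fs_target) if fs_target is not None else False,
            "pstop_home": bool(PSTOP_LO <= ps_home <= PSTOP_HI),
            "pstop_target": bool(PSTOP_LO <= ps_target <= PSTOP_HI),
            "go_errors": bool(err < GO_ERROR_MAX),
        }
        checks[s.participant_id]["all"] = all(checks[s.participant_id].values())

    retained = [s for s in sessions if checks[s.participant_id]["all"]]
    n = len(sessions)
    rows = [
        ("FSRT<GoRT", "home", sum(c["fsrt_lt_gort_home"] for c in checks.values())),
        ("FSRT<GoRT", "target", sum(c["fsrt_lt_gort_target"] for c in checks.values())),
        ("pStop 25-75%", "home", sum(c["pstop_home"] for c in checks.values())),
        ("pStop 25-75%", "target", sum(c["pstop_target"] for c in checks.values())),
        ("Go errors < 20%", "", sum(c["go_errors"] for c in checks.values())),
        ("All criteria met", "", len(retained)),
    ]
    report = pd.DataFrame(rows, columns=["criterion", "staircase", "n_meeting"])
    report["n_total"] = n
    report.attrs["per_participant"] = checks
    report.attrs["empty_retained"] = len(retained) == 0
    return retained, report


# ---------------------------------------------------------------------------
# Outlier filtering
# ---------------------------------------------------------------------------

def filter_outliers(values: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass latency outlier filter.

    Removes values below 100 ms and values beyond 1.5 times the
    inter-quartile range outside the first and third quartiles.  Quartiles
    use linear interpolation between order statistics and are computed once
    on the full input (no re-computation after removal).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("filter_outliers requires a non-empty input")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    bad = (v < RT_FLOOR_MS) | (v < lo) | (v > hi)
    return v[~bad], v[bad]


# ---------------------------------------------------------------------------
# Session file I/O
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "participant_id", "block", "trial", "trial_kind", "staircase",
    "ssd_intended", "ssd_actual", "target_side", "go_onset",
    "response_deadline", "refresh_rate", "window_width", "window_height",
    "home_x0", "home_y0", "home_x1", "home_y1",
    "left_x0", "left_y0", "left_x1", "left_y1",
    "right_x0", "right_y0", "right_x1", "right_y1",
]
_SAMPLE_COLUMNS = ["participant_id", "block", "trial", "t", "x", "y"]


def _trial_to_row(session: Session, tr: TrialRecord) -> dict:
    row = {
        "participant_id": session.participant_id,
        "block": tr.block,
        "trial": tr.trial,
        "trial_kind": tr.trial_kind,
        "staircase": tr.staircase,
        "ssd_intended": tr.ssd_intended,
        "ssd_actual": tr.ssd_actual,
        "target_side": tr.target_side,
        "go_onset": tr.go_onset,
        "response_deadline": tr.response_deadline,
        "refresh_rate": tr.refresh_rate,
        "window_width": session.window_width,
        "window_height": session.window_height,
    }
    for name, rect in (
        ("home", tr.home_pad),
        ("left", tr.target_boxes["left"]),
        ("right", tr.target_boxes["right"]),
    ):
        row[f"{name}_x0"], row[f"{name}_y0"] = rect.x0, rect.y0
        row[f"{name}_x1"], row[f"{name}_y1"] = rect.x1, rect.y1
    return row


def _row_to_trial(row: dict) -> TrialRecord:
    def rect(prefix: str) -> Rect:
        return Rect(
            float(row[f"{prefix}_x0"]), float(row[f"{prefix}_y0"]),
            float(row[f"{prefix}_x1"]), float(row[f"{prefix}_y1"]),
        )

    return TrialRecord(
        trial_kind=str(row["trial_kind"]),
        staircase=str(row["staircase"]),
        ssd_intended=float(row["ssd_intended"]) if not pd.isna(row["ssd_intended"]) else float("nan"),
        ssd_actual=float(row["ssd_actual"]) if not pd.isna(row["ssd_actual"]) else float("nan"),
        target_side=str(row["target_side"]),
        go_onset=float(row["go_onset"]),
        response_deadline=float(row["response_deadline"]),
        home_pad=rect("home"),
        target_boxes={"left": rect("left"), "right": rect("right")},
        samples=np.empty((0, 3)),
        refresh_rate=float(row["refresh_rate"]),
        block=int(row["block"]),
        trial=int(row["trial"]),
    )


def write_session(session: Session, path: str, dialect: str | None = None) -> None:
    """Write a session in one of two plain-text dialects.

    ``dialect="csv"`` writes a directory with ``trials.csv`` and
    ``samples.csv`` (long format, keyed by participant/block/trial);
    ``dialect="json"`` writes one structured-record file.  The dialect is
    inferred from the path when not given (``.json`` suffix vs directory).
    """
    if dialect is None:
        dialect = "json" if str(path).endswith(".json") else "csv"
    if dialect == "json":
        payload = {
            "participant_id": session.participant_id,
            "refresh_rate": session.refresh_rate,
            "window_width": session.window_width,
            "window_height": session.window_height,
            "trials": [
                dict(
                    _trial_to_row(session, tr),
                    samples=[[float(a) for a in row] for row in tr.samples],
                )
                for tr in session.trials
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    elif dialect == "csv":
        os.makedirs(path, exist_ok=True)
        trials = pd.DataFrame(
            [_trial_to_row(session, tr) for tr in session.trials],
            columns=_TRIAL_COLUMNS,
        )
        frames = []
        for tr in session.trials:
            df = pd.DataFrame(tr.samples, columns=["t", "x", "y"])
            df.insert(0, "trial", tr.trial)
            df.insert(0, "block", tr.block)
            df.insert(0, "participant_id", session.participant_id)
            frames.append(df)
        samples = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=_SAMPLE_COLUMNS)
        )
        trials.to_csv(os.path.join(path, "trials.csv"), index=False)
        samples.to_csv(os.path.join(path, "samples.csv"), index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_session(path: str, dialect: str | None = None) -> Session:
    """Read a session file written by :func:`write_session`.

    Validates all structural invariants; malformed rows are reported with
    their trial identifiers.
    """
    if dialect is None:
        dialect = "json" if str(path).endswith(".json") else "csv"
    if dialect == "json":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("participant_id", "refresh_rate", "trials"):
            if key not in payload:
                raise SchemaError(f"missing field {key!r} in {path}")
        trials = []
        for rec in payload["trials"]:
            tr = _row_to_trial(rec)
            tr.samples = np.asarray(rec.get("samples", []), dtype=float).reshape(-1, 3)
            trials.append(tr)
        session = Session(
            participant_id=payload["participant_id"],
            trials=trials,
            refresh_rate=float(payload["refresh_rate"]),
            window_width=float(payload.get("window_width", float("nan"))),
            window_height=float(payload.get("window_height", float("nan"))),
        )
    elif dialect == "csv":
        tpath = os.path.join(path, "trials.csv")
        spath = os.path.join(path, "samples.csv")
        if not (os.path.exists(tpath) and os.path.exists(spath)):
            raise SchemaError(f"{path} must contain trials.csv and samples.csv")
        tdf = pd.read_csv(tpath, float_precision="round_trip")
        sdf = pd.read_csv(spath, float_precision="round_trip")
        missing = set(_TRIAL_COLUMNS) - set(tdf.columns)
        if missing:
            raise SchemaError(f"trials.csv missing columns: {sorted(missing)}")
        missing = set(_SAMPLE_COLUMNS) - set(sdf.columns)
        if missing:
            raise SchemaError(f"samples.csv missing columns: {sorted(missing)}")
        grouped = {
            key: grp[["t", "x", "y"]].to_numpy(dtype=float)
            for key, grp in sdf.groupby(["block", "trial"], sort=False)
        }
        trials = []
        for _, row in tdf.iterrows():
            tr = _row_to_trial(row)
            tr.samples = grouped.get((tr.block, tr.trial), np.empty((0, 3)))
            trials.append(tr)
        first = tdf.iloc[0] if len(tdf) else None
        session = Session(
            participant_id=str(first["participant_id"]) if first is not None else "",
            trials=trials,
            refresh_rate=float(first["refresh_rate"]) if first is not None else float("nan"),
            window_width=float(first["window_width"]) if first is not None else float("nan"),
            window_height=float(first["window_height"]) if first is not None else float("nan"),
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    session.validate()
    return session
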