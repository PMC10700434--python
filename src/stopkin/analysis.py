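"""Model-object facade over the kinematic + Race-Model pipeline.

`StopTaskAnalysis` plays the role of a model built from data: it holds one
or more classified sessions, and `fit()` runs outcome classification,
exclusion screening, the kinematic single-trial estimators and the
Race-Model integration estimator, returning a `StopTaskResults` object with
per-participant estimates, race-consistency regression slopes and a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import (
    StopEstimates,
    kinematics_table,
    racemodel_regressions,
    summarize_stopping,
)
from .sessions import Session, apply_exclusions

__all__ = ["StopTaskAnalysis", "StopTaskResults"]


class StopTaskAnalysis:
    """Kinematic and Race-Model analysis of one or more sessions."""

    def __init__(self, sessions, apply_exclusion_criteria: bool = True):
        if isinstance(sessions, Session):
            sessions = [sessions]
        self.sessions = list(sessions)
        self.apply_exclusion_criteria = apply_exclusion_criteria

    def fit(self) -> "StopTaskResults":
        for s in self.sessions:
            if s.outcomes is None:
                s.classify()
        retained, report = apply_exclusions(self.sessions)
        if not self.apply_exclusion_criteria:
            retained = self.sessions
        estimates = {s.participant_id: summarize_stopping(s) for s in retained}
        regressions = {s.participant_id: racemodel_regressions(s) for s in retained}
        return StopTaskResults(
            analysis=self,
            retained=retained,
            exclusion_report=report,
            estimates=estimates,
            regressions=regressions,
        )


@dataclass
class StopTaskResults:
    analysis: StopTaskAnalysis
    retained: list
    exclusion_report: pd.DataFrame
    estimates: dict  # participant_id -> StopEstimates
    regressions: dict  # participant_id -> DataFrame

    def estimates_frame(self) -> pd.DataFrame:
        """One row per participant x staircase."""
        rows = []
        for pid, est in self.estimates.items():
            for staircase in ("home", "target"):
                e = est[staircase]
                rows.append(dict(
                    participant_id=pid, staircase=staircase,
                    ssrt_rm=e.ssrt_rm, ssrt_k=e.ssrt_k_mean,
                    sd_ssrt_k=e.sd_ssrt_k, tf_k_percent=e.tf_k_percent,
                    n_trials_used=e.n_trials_used, n_stop_trials=e.n_stop_trials,
                ))
        return pd.DataFrame(rows)

    def regression_frame(self) -> pd.DataFrame:
        frames = []
        for pid, df in self.regressions.items():
            d = df.copy()
            d.insert(0, "participant_id", pid)
            frames.append(d)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def kinematics_frame(self) -> pd.DataFrame:
        return pd.concat(
            [kinematics_table(s) for s in self.retained], ignore_index=True
        ) if self.retained else pd.DataFrame()

    def method_comparison(self) -> pd.DataFrame:
        """Descriptive per-staircase deltas between SSRT estimators."""
        df = self.estimates_frame()
        if df.empty:
            return df
        out = []
        for staircase, grp in df.groupby("staircase"):
            delta = grp["ssrt_k"] - grp["ssrt_rm"]
            out.append(dict(
                staircase=staircase,
                n=len(grp),
                ssrt_rm_mean=grp["ssrt_rm"].mean(),
                ssrt_k_mean=grp["ssrt_k"].mean(),
                mean_difference=delta.mean(),
                sd_difference=delta.std(ddof=1) if len(grp) > 1 else np.nan,
            ))
        return pd.DataFrame(out)

    def summary(self) -> str:
        df = self.estimates_frame()
        lines = ["Stop task kinematic / Race-Model analysis",
                 f"sessions: {len(self.analysis.sessions)}  retained: {len(self.retained)}",
                 ""]
        if not df.empty:
            agg = df.groupby("staircase")[
                ["ssrt_rm", "ssrt_k", "sd_ssrt_k", "tf_k_percent"]
            ].mean(numeric_only=True)
            lines.append(agg.round(1).to_string())
        return "\n".join(lines)
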