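"""Race-Model integration estimator of the stop signal reaction time.

Under the independent-race account, the go and stop processes race to
completion on stop trials.  The integration method finds the point of the
go RT distribution that the stop process beats with probability
p(respond | signal): sort the go RTs ascending, take the RT at 1-based rank
``ceil(p_respond * N)``, and subtract the mean stop signal delay.

The home staircase uses reaction times (home-pad exit) and the target
staircase total response times (target entry), matching each staircase's own
response definition.  Go omissions are assigned the maximum observed latency
before ranking (standard practice; omission rates in this task are a few
per mille, so the impact is negligible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EstimationError
from .sessions import Session

__all__ = [
    "IntegrationInput",
    "p_respond_given_signal",
    "integration_ssrt",
    "integration_input_for_session",
    "integration_ssrt_for_session",
]


@dataclass
class IntegrationInput:
    """Inputs to the integration estimator for one staircase."""

    go_rts: np.ndarray
    p_respond: float
    mean_ssd: float

    def __post_init__(self) -> None:
        self.go_rts = np.asarray(self.go_rts, dtype=float)
        if self.go_rts.size == 0:
            raise EstimationError("integration method needs a non-empty go RT distribution")
        if not (0.0 < self.p_respond < 1.0):
            raise EstimationError(
                f"p_respond must lie strictly in (0, 1); got {self.p_respond}. "
                "With all stops failed (or all successful) the go RT quantile "
                "at p_respond is undefined and SSRT cannot be estimated."
            )


def p_respond_given_signal(session: Session, staircase: str) -> float:
    """Probability of responding given a stop signal (1 - pStop).

    Pooled over all of the staircase's stop trials under its own success
    definition (home: cursor never left the pad; target: cursor never
    entered a target).
    """
    if session.outcomes is None:
        session.classify()
    trials = list(session.iter_classified(kind="stop", staircase=staircase))
    if not trials:
        raise EstimationError(f"no {staircase}-staircase stop trials in session")
    if staircase == "home":
        n_fail = sum(1 for _, oc in trials if not oc.home_stop_success)
    else:
        n_fail = sum(1 for _, oc in trials if not oc.target_stop_success)
    return n_fail / len(trials)


def integration_ssrt(inp: IntegrationInput) -> float:
    """SSRT by the integration method, in ms.

    Rank rule: 1-based rank ``ceil(p_respond * N)`` of the ascending-sorted
    go RTs (a deterministic order-statistic rule; interpolating variants
    shift the estimate by less than one RT quantile step).
    """
    rts = np.sort(inp.go_rts)
    n = rts.size
    rank = int(math.ceil(inp.p_respond * n))
    rank = min(max(rank, 1), n)
    return float(rts[rank - 1] - inp.mean_ssd)


def integration_input_for_session(session: Session, staircase: str) -> IntegrationInput:
    """Assemble integration inputs from a classified session.

    Home staircase: go-trial reaction times; target staircase: go-trial
    total response times.  Go trials without the relevant latency (omissions;
    for the target staircase also missed targets) are assigned the maximum
    observed latency before ranking.
    """
    if session.outcomes is None:
        session.classify()
    lats = []
    n_missing = 0
    for _, oc in session.iter_classified(kind="go"):
        v = oc.reaction_time if staircase == "home" else oc.total_response_time
        if v is None:
            n_missing += 1
        else:
            lats.append(v)
    if not lats:
        raise EstimationError("no go latencies available")
    lats = lats + [max(lats)] * n_missing
    trials = session.stop_trials(staircase)
    if not trials:
        raise EstimationError(f"no {staircase}-staircase stop trials in session")
    mean_ssd = float(np.mean([t.ssd_actual for t in trials]))
    return IntegrationInput(
        go_rts=np.asarray(lats),
        p_respond=p_respond_given_signal(session, staircase),
        mean_ssd=mean_ssd,
    )


def integration_ssrt_for_session(session: Session, staircase: str) -> float:
    return integration_ssrt(integration_input_for_session(session, staircase))
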