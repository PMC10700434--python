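"""Trial-count precision analysis for the kinematic stopping metrics.

How many stop trials are needed before a per-subject summary (mean SSRT,
its intra-individual SD, or the trigger-failure rate) is stable?  Following
the standard resampling procedure, x trials are drawn without replacement from the
subject's own trial set for x on a grid from 5 to 70 in steps of 5, 1000
times per grid point, and the resampled estimates are compared with the
full-sample ("true") value under a +/-5% criterion.

A "within +/-5%" criterion admits two readings, both provided:

* ``rule="reps"`` (default): the smallest x at which at least 90% of the
  resampled estimates fall within +/-tolerance of the true value;
* ``rule="mean"``: the smallest x at which the mean of the resampled
  estimates is within +/-tolerance of the true value.  For unbiased
  statistics (means, proportions) this is satisfied almost immediately, so
  it is informative mainly for biased statistics such as the SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PrecisionResult", "required_trials", "precision_table"]

DEFAULT_GRID = tuple(range(5, 75, 5))


@dataclass
class PrecisionResult:
    metric: str
    staircase: str
    required_trials: int | None  # None = "not reached" on the grid
    tolerance: float
    reps: int
    rule: str
    grid: tuple
    true_value: float
    pass_fraction: dict  # grid point -> fraction of reps within tolerance
    grid_truncated: bool = False


def required_trials(
    trial_values,
    tolerance: float = 0.05,
    reps: int = 1000,
    grid=DEFAULT_GRID,
    seed: int = 0,
    statistic=np.mean,
    rule: str = "reps",
    pass_level: float = 0.90,
    metric: str = "",
    staircase: str = "",
) -> PrecisionResult:
    """Smallest resample size on the grid meeting the +/-tolerance criterion.

    ``trial_values`` is one subject's per-trial metric values; the true
    value is ``statistic`` of the full sample.  Sampling is without
    replacement; if fewer values than max(grid) are available the grid is
    truncated (with a flag) to the feasible sizes.
    """
    values = np.asarray(list(trial_values), dtype=float)
    rng = np.random.default_rng(seed)
    n = values.size
    grid = tuple(sorted(grid))
    truncated = False
    if n < max(grid):
        grid = tuple(x for x in grid if x <= n)
        truncated = True
    if not grid:
        return PrecisionResult(metric, staircase, None, tolerance, reps, rule,
                               grid, np.nan, {}, grid_truncated=True)
    true_value = float(statistic(values))
    band = tolerance * abs(true_value)
    pass_frac = {}
    required = None
    for x in grid:
        est = np.empty(reps)
        for r in range(reps):
            est[r] = statistic(values[rng.permutation(n)[:x]])
        if rule == "reps":
            frac = float(np.mean(np.abs(est - true_value) <= band))
            pass_frac[x] = frac
            ok = frac >= pass_level
        elif rule == "mean":
            dev = abs(float(np.mean(est)) - true_value)
            pass_frac[x] = dev
            ok = dev <= band
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if ok and required is None:
            required = x
    return PrecisionResult(
        metric=metric, staircase=staircase, required_trials=required,
        tolerance=tolerance, reps=reps, rule=rule, grid=grid,
        true_value=true_value, pass_fraction=pass_frac, grid_truncated=truncated,
    )


def precision_table(results) -> pd.DataFrame:
    """Delimited-text-friendly table of PrecisionResults."""
    rows = []
    for r in results:
        rows.append(dict(
            metric=r.metric, staircase=r.staircase,
            required_trials=r.required_trials if r.required_trials is not None else "not reached",
            tolerance=r.tolerance, reps=r.reps, rule=r.rule,
            true_value=r.true_value, grid_truncated=r.grid_truncated,
        ))
    return pd.DataFrame(rows)
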