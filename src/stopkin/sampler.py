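"""Seeded MCMC machinery: adaptive Metropolis and the Gelman-Rubin diagnostic.

The sampler is a component-wise Gaussian random-walk Metropolis scheme run
as several independent chains.  Proposal scales adapt per coordinate during
burn-in (Robbins-Monro steps toward a 0.44 acceptance rate, the standard
target for one-dimensional updates) and are frozen afterwards, so the
post-burn-in chains satisfy detailed balance.  Identical seeds give
identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EstimationError

__all__ = ["gelman_rubin", "ChainSet", "run_metropolis", "truncated_normal_draw"]


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor (R-hat).

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws,
    n_params).  Each chain is split in half before the usual between/within
    variance comparison, so a single long chain that drifts also registers
    as unconverged.  Returns one value per parameter; NaN where the
    within-chain variance is zero (flagged as undefined rather than raised).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
        squeeze = True
    else:
        squeeze = False
    m, n = chains.shape[0], chains.shape[1]
    if m < 2:
        raise EstimationError("gelman_rubin needs at least 2 chains")
    if n < 10:
        raise EstimationError("gelman_rubin needs at least 10 draws per chain")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    n_eff = half
    means = split.mean(axis=1)  # (2m, p)
    variances = split.var(axis=1, ddof=1)  # (2m, p)
    w = variances.mean(axis=0)
    b = n_eff * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n_eff - 1) / n_eff * w + b / n_eff
        rhat = np.sqrt(var_hat / w)
    rhat = np.where(w > 0, rhat, np.nan)
    return float(rhat[0]) if squeeze else rhat


def truncated_normal_draw(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """One draw from N(mean, sd) truncated to [lo, hi] by inverse CDF."""
    from scipy.special import ndtr, ndtri

    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + (b - a) * rng.random()
    u = min(max(u, 1e-15), 1 - 1e-15)
    return mean + sd * ndtri(u)


@dataclass
class ChainSet:
    """Post-burn-in draws: array (n_chains, n_draws, n_params)."""

    draws: np.ndarray
    accept_rate: np.ndarray
    scales: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def rhat(self) -> np.ndarray:
        return gelman_rubin(self.draws)


def run_metropolis(
    log_post,
    x0: np.ndarray,
    n_iter: int,
    rng_chains: list,
    scales: np.ndarray,
    burn_frac: float = 0.5,
    adapt: bool = True,
) -> ChainSet:
    """Component-wise random-walk Metropolis, one independent chain per rng.

    ``x0`` has shape (n_chains, n_params); ``scales`` is the initial
    per-coordinate proposal SD.  The first ``burn_frac`` of iterations are
    discarded; proposal scales adapt only during that window.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    n_chains, n_params = x0.shape
    n_burn = int(burn_frac * n_iter)
    kept = n_iter - n_burn
    draws = np.empty((n_chains, kept, n_params))
    acc_rates = np.empty((n_chains, n_params))
    out_scales = np.empty((n_chains, n_params))

    for c in range(n_chains):
        rng = rng_chains[c]
        x = x0[c].copy()
        lp = log_post(x)
        if not np.isfinite(lp):
            raise EstimationError("log posterior is not finite at the start values")
        log_s = np.log(np.asarray(scales, dtype=float).copy())
        acc = np.zeros(n_params)
        n_prop = np.zeros(n_params)
        for it in range(n_iter):
            for j in range(n_params):
                prop = x.copy()
                prop[j] += np.exp(log_s[j]) * rng.standard_normal()
                lp_prop = log_post(prop)
                n_prop[j] += 1
                accepted = np.log(rng.random()) < lp_prop - lp
                if accepted:
                    x, lp = prop, lp_prop
                    acc[j] += 1
                if adapt and it < n_burn:
                    # Robbins-Monro step toward 0.44 acceptance
                    gamma = min(0.1, 5.0 / (it + 10))
                    log_s[j] += gamma * (float(accepted) - 0.44)
            if it >= n_burn:
                draws[c, it - n_burn] = x
        acc_rates[c] = acc / np.maximum(n_prop, 1)
        out_scales[c] = np.exp(log_s)
    return ChainSet(draws=draws, accept_rate=acc_rates, scales=out_scales)
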