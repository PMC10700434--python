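"""Ex-Gaussian distribution and the two-runner race with trigger failures.

The ex-Gaussian is the convolution of a normal (mu, sigma) and an
exponential (tau) distribution; mean mu + tau, variance sigma^2 + tau^2.
Go and stop finishing times are each ex-Gaussian.  On a stop trial the stop
runner is triggered with probability 1 - TF (TF mapped to the probability
scale from a probit parameter); when triggered, the response is produced
only if the go runner finishes before SSD + stop finishing time.

Closed forms here are stabilised with the scaled complementary error
function: with z = (t - mu)/sigma and a = (sigma/tau - z)/sqrt(2),

    f(t) = erfcx(a) * exp(-z^2/2) / (2 tau),       F(t) = Phi(z) - tau f(t),

which is overflow-free for all parameter regimes including tau -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import erfcx, ndtr
from scipy.stats import norm

from .exceptions import EstimationError

__all__ = [
    "ExGaussRaceParams",
    "exgauss_logpdf",
    "exgauss_density",
    "exgauss_cdf",
    "exgauss_rvs",
    "signal_respond_density",
    "p_inhibit",
    "p_inhibit_grid",
    "sample_race_outcomes",
]

_SQRT2 = np.sqrt(2.0)


def _check(sigma: float, tau: float) -> None:
    if not (sigma > 0 and tau > 0):
        raise ValueError("sigma and tau must be positive")


def exgauss_logpdf(t, mu: float, sigma: float, tau: float):
    _check(sigma, tau)
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    a = (sigma / tau - z) / _SQRT2
    # Piecewise-stable: erfcx is used left of the exponential tail, the
    # normal-CDF form (f = exp(b) Phi(-sqrt(2) a) / tau, b = a^2 - z^2/2)
    # right of it, where erfcx of a negative argument would overflow.
    with np.errstate(divide="ignore", over="ignore"):
        left = np.log(erfcx(np.maximum(a, 0.0))) - 0.5 * z * z - np.log(2.0 * tau)
        b = (sigma / tau) * (sigma / (2.0 * tau) - z)
        right = b + np.log(ndtr(-_SQRT2 * np.minimum(a, 0.0))) - np.log(tau)
    return np.where(a >= 0, left, right)


def exgauss_density(t, mu: float, sigma: float, tau: float):
    """Ex-Gaussian probability density."""
    return np.exp(exgauss_logpdf(t, mu, sigma, tau))


def exgauss_cdf(t, mu: float, sigma: float, tau: float):
    """Ex-Gaussian cumulative distribution function."""
    _check(sigma, tau)
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    return np.clip(ndtr(z) - tau * exgauss_density(t, mu, sigma, tau), 0.0, 1.0)


def exgauss_rvs(mu: float, sigma: float, tau: float, size, rng: np.random.Generator):
    _check(sigma, tau)
    return mu + sigma * rng.standard_normal(size) + tau * rng.exponential(size=size)


@dataclass
class ExGaussRaceParams:
    """Parameters of the two-runner ex-Gaussian race with trigger failures.

    Times are ms; ``tf_probit`` lives on the real line and maps to the
    trigger-failure probability through the standard normal CDF.  Derived
    quantities: SSRT_B = mu_stop + tau_stop, SD-SSRT_B =
    sqrt(sigma_stop^2 + tau_stop^2), TF_B = Phi(tf_probit).
    """

    mu_go: float
    sigma_go: float
    tau_go: float
    mu_stop: float
    sigma_stop: float
    tau_stop: float
    tf_probit: float

    @property
    def tf(self) -> float:
        return float(ndtr(self.tf_probit))

    @property
    def ssrt(self) -> float:
        return self.mu_stop + self.tau_stop

    @property
    def sd_ssrt(self) -> float:
        return float(np.hypot(self.sigma_stop, self.tau_stop))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mu_go, self.sigma_go, self.tau_go,
             self.mu_stop, self.sigma_stop, self.tau_stop, self.tf_probit]
        )

    @classmethod
    def from_array(cls, x) -> "ExGaussRaceParams":
        return cls(*[float(v) for v in x])


def signal_respond_density(t, ssd: float, params: ExGaussRaceParams):
    """Density of responding at time t (from the go signal) on a stop trial.

    A response escapes inhibition either because the stop runner was never
    triggered (probability TF) or because the go runner beat it:

        TF * f_go(t) + (1 - TF) * f_go(t) * (1 - F_stop(t - ssd)),

    with F_stop vanishing for negative arguments.  This is the "failed stop
    response times as a truncated go RT distribution" construction; it is a
    defective density integrating to 1 - p_inhibit(ssd).
    """
    t = np.asarray(t, dtype=float)
    tf = params.tf
    f_go = exgauss_density(t, params.mu_go, params.sigma_go, params.tau_go)
    surv = np.ones_like(t)
    late = t > ssd
    if np.any(late):
        surv = np.where(
            late,
            1.0 - exgauss_cdf(t - ssd, params.mu_stop, params.sigma_stop, params.tau_stop),
            1.0,
        )
    return f_go * (tf + (1.0 - tf) * surv)


def _integration_bounds(ssd: float, params: ExGaussRaceParams) -> tuple[float, float]:
    lo = max(float(ssd), params.mu_go - 10.0 * params.sigma_go)
    hi = max(
        params.mu_go + 10.0 * (params.sigma_go + params.tau_go),
        ssd + params.mu_stop + 10.0 * (params.sigma_stop + params.tau_stop),
    )
    return lo, hi


def p_inhibit(ssd: float, params: ExGaussRaceParams) -> float:
    """Probability of a successful stop at the given SSD.

    (1 - TF) * E_go[F_stop(T_go - ssd)], computed by adaptive quadrature over
    the region where both the go density and the stop CDF have mass, plus an
    analytic tail correction (beyond the upper limit F_stop is 1 to working
    precision, so the remainder is the go survival mass).  Strictly
    decreasing in SSD.
    """
    lo, hi = _integration_bounds(ssd, params)

    def integrand(t: float) -> float:
        return float(
            exgauss_density(t, params.mu_go, params.sigma_go, params.tau_go)
            * exgauss_cdf(t - ssd, params.mu_stop, params.sigma_stop, params.tau_stop)
        )

    if lo >= hi:
        core = 0.0
    else:
        core, err = quad(integrand, lo, hi, epsabs=1e-10, epsrel=1e-8, limit=400)
        if not np.isfinite(core):
            raise EstimationError("p_inhibit quadrature did not converge")
    tail = 1.0 - float(exgauss_cdf(max(lo, hi), params.mu_go, params.sigma_go, params.tau_go))
    return float((1.0 - params.tf) * min(core + tail, 1.0))


# Composite Gauss-Legendre rule reused by the likelihood: fast, vectorised
# over SSDs.  Panel edges sit at landmarks of the go density (multiples of
# sigma around mu, multiples of tau into the exponential tail) so narrow
# Gaussian cores are resolved even when sigma is a few ms.
_GL_ORDER = 12
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_GL_ORDER)
_SIGMA_KNOTS = np.array([-8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0])
_TAU_KNOTS = np.array([1.0, 2.0, 4.0, 7.0, 10.0])


def p_inhibit_grid(ssds: np.ndarray, params: ExGaussRaceParams) -> np.ndarray:
    """Vectorised stop-success probabilities at several SSDs.

    Fixed composite Gauss-Legendre quadrature with the same analytic tail
    correction as :func:`p_inhibit`; used inside the likelihood where an
    adaptive scalar rule would dominate the runtime.
    """
    ssds = np.atleast_1d(np.asarray(ssds, dtype=float))
    lo = np.maximum(ssds, params.mu_go - 10.0 * params.sigma_go)
    hi = np.maximum(
        params.mu_go + 10.0 * (params.sigma_go + params.tau_go),
        ssds + params.mu_stop + 10.0 * (params.sigma_stop + params.tau_stop),
    )
    hi = np.maximum(hi, lo)
    knots = np.concatenate([
        params.mu_go + params.sigma_go * _SIGMA_KNOTS,
        params.mu_go + 4.0 * params.sigma_go + params.tau_go * _TAU_KNOTS,
    ])
    knots.sort()
    # per-SSD edges: lo, interior knots clipped into (lo, hi), hi
    edges = np.clip(knots[None, :], lo[:, None], hi[:, None])
    edges = np.concatenate([lo[:, None], edges, hi[:, None]], axis=1)
    half = 0.5 * np.diff(edges, axis=1)  # (n_ssd, panels)
    mid = 0.5 * (edges[:, :-1] + edges[:, 1:])
    # nodes: (n_ssd, panels, order)
    t = mid[:, :, None] + half[:, :, None] * _GL_NODES
    f_go = exgauss_density(t, params.mu_go, params.sigma_go, params.tau_go)
    F_stop = exgauss_cdf(
        np.maximum(t - ssds[:, None, None], 0.0) + 1e-300,
        params.mu_stop, params.sigma_stop, params.tau_stop,
    )
    F_stop = np.where(t > ssds[:, None, None], F_stop, 0.0)
    core = np.sum(f_go * F_stop * _GL_WEIGHTS, axis=2)
    core = np.sum(core * half, axis=1)
    tail = 1.0 - exgauss_cdf(hi, params.mu_go, params.sigma_go, params.tau_go)
    return (1.0 - params.tf) * np.minimum(core + tail, 1.0)


def sample_race_outcomes(
    params: ExGaussRaceParams, ssd: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo draws of the race at a fixed SSD.

    Returns (responded, rt): a boolean array and the response times of the
    responded trials (NaN where inhibited).  Serves as the simulation oracle
    for :func:`p_inhibit` and :func:`signal_respond_density`.
    """
    go = exgauss_rvs(params.mu_go, params.sigma_go, params.tau_go, n, rng)
    triggered = rng.random(n) >= params.tf
    stop = exgauss_rvs(params.mu_stop, params.sigma_stop, params.tau_stop, n, rng)
    finish = np.where(triggered, ssd + stop, np.inf)
    responded = go < finish
    rt = np.where(responded, go, np.nan)
    return responded, rt
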