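"""Bayesian two-runner ex-Gaussian race model with trigger failures.

This is the BEESTS-style model: go and stop finishing times are
ex-Gaussian, a probit-scale parameter gives the probability that the stop
runner is never triggered, and failed-stop response times are treated as a
go RT distribution truncated by the racing stop process.  Per-subject fits
use weakly informative uniform priors (mu truncated at 0 and 2000 ms,
sigma/tau at 0 and 1000 ms, the trigger-failure probit at -6 and 6); the
hierarchical fit places normal hyper-priors on the group-level means,
centred on the per-subject fits, with fixed group-level standard
deviations, and leaves the trigger-failure parameter untruncated.

Usage follows the Model/Results convention::

    model = ExGaussRaceModel.from_session(session, staircase="home")
    res = model.fit(seed=1)
    print(res.summary())

Internally the sampler works in seconds for the six time parameters (and on
the probit scale for trigger failures); all reported quantities are ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import EstimationError, InsufficientDataError
from .exgauss import (
    ExGaussRaceParams,
    exgauss_cdf,
    exgauss_density,
    exgauss_logpdf,
    exgauss_rvs,
    p_inhibit_grid,
)
from .sampler import ChainSet, gelman_rubin, run_metropolis, truncated_normal_draw
from .sessions import Session, filter_outliers

__all__ = [
    "PriorSpec",
    "StopSignalData",
    "ExGaussRaceModel",
    "ExGaussRaceResults",
    "HierarchicalExGaussRace",
    "HierarchicalResults",
    "posterior_predictive_check",
    "PPCReport",
]

PARAM_NAMES = ["mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop", "tf_probit"]
DERIVED_NAMES = ["ssrt", "sd_ssrt", "tf"]

# sampling-scale bounds (seconds for times, probit for trigger failures)
_SUBJECT_LO = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -6.0])
_SUBJECT_HI = np.array([2.0, 1.0, 1.0, 2.0, 1.0, 1.0, 6.0])
_MS = np.array([1000.0] * 6 + [1.0])  # sampling scale -> ms/probit


@dataclass
class PriorSpec:
    """Uniform subject-level prior truncations on the sampling scale."""

    lo: np.ndarray = field(default_factory=lambda: _SUBJECT_LO.copy())
    hi: np.ndarray = field(default_factory=lambda: _SUBJECT_HI.copy())

    def in_bounds(self, x: np.ndarray) -> bool:
        return bool(np.all(x > self.lo) and np.all(x < self.hi))


@dataclass
class StopSignalData:
    """Stop-task observations for one subject and one staircase.

    ``go_rts`` are the go-trial latencies (reaction times for the home
    staircase, total response times for the target staircase); ``sr_ssd`` /
    ``sr_rt`` the SSDs and latencies of the failed (signal-respond) stop
    trials; ``inhibit_ssds`` the SSDs of the successful stops.  Latency
    outliers (the 100 ms floor and 1.5*IQR rule) are expected to have been
    removed before the likelihood sees the data; ``from_session`` does this.
    """

    go_rts: np.ndarray
    sr_ssd: np.ndarray
    sr_rt: np.ndarray
    inhibit_ssds: np.ndarray
    participant_id: str = ""
    staircase: str = "home"

    def __post_init__(self) -> None:
        self.go_rts = np.asarray(self.go_rts, dtype=float)
        self.sr_ssd = np.asarray(self.sr_ssd, dtype=float)
        self.sr_rt = np.asarray(self.sr_rt, dtype=float)
        self.inhibit_ssds = np.asarray(self.inhibit_ssds, dtype=float)
        uniq, counts = np.unique(self.inhibit_ssds, return_counts=True)
        self._inh_unique = uniq
        self._inh_counts = counts.astype(float)

    @property
    def n_stop(self) -> int:
        return int(self.sr_rt.size + self.inhibit_ssds.size)

    @classmethod
    def from_session(cls, session: Session, staircase: str) -> "StopSignalData":
        """Extract one staircase's likelihood inputs from a classified session.

        Go trials with errors are excluded from the go RT distribution
        (choice errors are extremely rare in this task, which is what
        justifies the two-runner model); latency outliers are filtered.
        """
        if session.outcomes is None:
            session.classify()
        lats = []
        for _, oc in session.iter_classified(kind="go"):
            if oc.go_error != "none":
                continue
            v = oc.reaction_time if staircase == "home" else oc.total_response_time
            if v is not None:
                lats.append(v)
        go_rts, _ = filter_outliers(lats) if lats else (np.empty(0), np.empty(0))
        sr_ssd, sr_rt, inh = [], [], []
        for tr, oc in session.iter_classified(kind="stop", staircase=staircase):
            success = oc.home_stop_success if staircase == "home" else oc.target_stop_success
            lat = oc.reaction_time if staircase == "home" else oc.total_response_time
            if success:
                inh.append(tr.ssd_actual)
            elif lat is not None:
                sr_ssd.append(tr.ssd_actual)
                sr_rt.append(lat)
        if sr_rt:
            kept_mask = np.isin(sr_rt, filter_outliers(sr_rt)[0])
            sr_ssd = np.asarray(sr_ssd)[kept_mask]
            sr_rt = np.asarray(sr_rt)[kept_mask]
        return cls(
            go_rts=go_rts,
            sr_ssd=np.asarray(sr_ssd, dtype=float),
            sr_rt=np.asarray(sr_rt, dtype=float),
            inhibit_ssds=np.asarray(inh, dtype=float),
            participant_id=session.participant_id,
            staircase=staircase,
        )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def log_likelihood(params: ExGaussRaceParams, data: StopSignalData) -> float:
    """Race-model log likelihood of one subject's data.

    Sum of go-trial log densities, signal-respond log densities and
    successful-stop log inhibition probabilities.
    """
    lp = float(np.sum(exgauss_logpdf(data.go_rts, params.mu_go, params.sigma_go, params.tau_go)))
    if data.sr_rt.size:
        f_go = exgauss_density(data.sr_rt, params.mu_go, params.sigma_go, params.tau_go)
        rel = data.sr_rt - data.sr_ssd
        surv = np.where(
            rel > 0,
            1.0 - exgauss_cdf(np.maximum(rel, 0.0) + 1e-300,
                              params.mu_stop, params.sigma_stop, params.tau_stop),
            1.0,
        )
        tf = params.tf
        dens = f_go * (tf + (1.0 - tf) * surv)
        lp += float(np.sum(np.log(np.clip(dens, 1e-300, None))))
    if data._inh_unique.size:
        p = p_inhibit_grid(data._inh_unique, params)
        lp += float(np.sum(data._inh_counts * np.log(np.clip(p, 1e-300, 1.0))))
    return lp


def _params_from_scaled(x: np.ndarray) -> ExGaussRaceParams:
    v = x * _MS
    return ExGaussRaceParams(*[float(a) for a in v])


def _start_values(data: StopSignalData) -> np.ndarray:
    """Moment-based start values on the sampling scale."""
    rts = data.go_rts
    m, s = float(np.mean(rts)), float(np.std(rts, ddof=1))
    with np.errstate(all="ignore"):
        skew = float(np.mean(((rts - m) / s) ** 3)) if s > 0 else 0.0
    tau = np.clip(s * np.cbrt(max(skew, 0.01) / 2.0), 0.05 * s, 0.95 * s)
    sigma = np.sqrt(max(s * s - tau * tau, (0.2 * s) ** 2))
    mu = m - tau
    n_resp = data.sr_rt.size
    p_resp = np.clip(n_resp / max(data.n_stop, 1), 0.05, 0.95)
    q = float(np.quantile(rts, p_resp))
    all_ssd = np.concatenate([data.sr_ssd, data.inhibit_ssds])
    mean_ssd = float(np.mean(all_ssd)) if all_ssd.size else 200.0
    ssrt0 = np.clip(q - mean_ssd, 80.0, 800.0)
    start_ms = np.array([mu, sigma, tau, 0.75 * ssrt0, max(0.15 * ssrt0, 20.0), 0.25 * ssrt0])
    x = np.concatenate([start_ms / 1000.0, [-2.0]])
    return np.clip(x, _SUBJECT_LO + 1e-4, _SUBJECT_HI - 1e-4)


_INIT_SCALES = np.array([0.01, 0.008, 0.008, 0.02, 0.015, 0.015, 0.35])


# ---------------------------------------------------------------------------
# Per-subject model
# ---------------------------------------------------------------------------

class ExGaussRaceModel:
    """Per-subject two-runner ex-Gaussian race model with trigger failures."""

    def __init__(self, data: StopSignalData, priors: PriorSpec | None = None):
        if data.go_rts.size < 10:
            raise InsufficientDataError("fit requires at least 10 go trials")
        if data.n_stop < 1:
            raise InsufficientDataError("fit requires at least 1 stop trial")
        self.data = data
        self.priors = priors or PriorSpec()

    @classmethod
    def from_session(cls, session: Session, staircase: str,
                     priors: PriorSpec | None = None) -> "ExGaussRaceModel":
        return cls(StopSignalData.from_session(session, staircase), priors=priors)

    def log_posterior(self, x: np.ndarray) -> float:
        if not self.priors.in_bounds(x):
            return -np.inf
        return log_likelihood(_params_from_scaled(x), self.data)

    def fit(
        self,
        seed: int,
        n_chains: int = 3,
        n_iter: int = 1400,
        max_iter: int = 5600,
        rhat_threshold: float = 1.1,
        start: np.ndarray | None = None,
    ) -> "ExGaussRaceResults":
        """Sample the posterior until convergence (all R-hat below threshold)
        or the iteration cap; the result records which occurred.

        Chains are seeded from ``seed``; identical seeds give identical
        draws.  Half of every run is burn-in.
        """
        ss = np.random.SeedSequence(seed)
        child_seeds = ss.spawn(n_chains + 1)
        jitter_rng = np.random.default_rng(child_seeds[-1])
        if start is None:
            start = _start_values(self.data)
        x0 = np.array([
            np.clip(
                start * (1.0 + 0.05 * jitter_rng.standard_normal(7))
                + np.array([0.0] * 6 + [0.3]) * jitter_rng.standard_normal(),
                self.priors.lo + 1e-4,
                self.priors.hi - 1e-4,
            )
            for _ in range(n_chains)
        ])
        total = 0
        draws_list = []
        rngs = [np.random.default_rng(s) for s in child_seeds[:n_chains]]
        scales = _INIT_SCALES.copy()
        chains: ChainSet | None = None
        while True:
            chains = run_metropolis(self.log_posterior, x0, n_iter, rngs, scales)
            total += n_iter
            draws_list.append(chains.draws)
            all_draws = np.concatenate(draws_list, axis=1)
            rhat = gelman_rubin(all_draws)
            if np.all(rhat < rhat_threshold) or total >= max_iter:
                break
            x0 = all_draws[:, -1, :]
            scales = chains.scales.mean(axis=0)
        return ExGaussRaceResults(
            model=self,
            draws=all_draws * _MS,
            rhat=rhat,
            converged=bool(np.all(rhat < rhat_threshold)),
            n_iter_total=total,
            seed=seed,
        )


def _summary_block(draws_flat: np.ndarray, names: list, rhat: np.ndarray) -> pd.DataFrame:
    mean = draws_flat.mean(axis=0)
    sd = draws_flat.std(axis=0, ddof=1)
    lo, hi = np.percentile(draws_flat, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "ci_2.5%": lo, "ci_97.5%": hi, "rhat": rhat},
        index=names,
    )


def _derived(draws: np.ndarray) -> np.ndarray:
    """Map raw parameter draws (ms scale) to (ssrt, sd_ssrt, tf)."""
    ssrt = draws[..., 3] + draws[..., 5]
    sd_ssrt = np.hypot(draws[..., 4], draws[..., 5])
    tf = ndtr(draws[..., 6])
    return np.stack([ssrt, sd_ssrt, tf], axis=-1)


@dataclass
class ExGaussRaceResults:
    """Posterior summary of a per-subject race-model fit.

    ``draws`` has shape (n_chains, n_draws, 7) on the ms/probit scale.
    Derived rows: ssrt = mu_stop + tau_stop, sd_ssrt =
    sqrt(sigma_stop^2 + tau_stop^2), tf = Phi(tf_probit).
    """

    model: ExGaussRaceModel
    draws: np.ndarray
    rhat: np.ndarray
    converged: bool
    n_iter_total: int
    seed: int

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def derived_draws(self) -> np.ndarray:
        return _derived(self.flat)

    @property
    def posterior_mean(self) -> ExGaussRaceParams:
        return ExGaussRaceParams.from_array(self.flat.mean(axis=0))

    def summary(self) -> pd.DataFrame:
        der = _derived(self.draws)
        rhat_der = gelman_rubin(der)
        block = _summary_block(self.flat, PARAM_NAMES, self.rhat)
        block_d = _summary_block(der.reshape(-1, 3), DERIVED_NAMES, rhat_der)
        out = pd.concat([block, block_d])
        out.attrs["converged"] = self.converged
        out.attrs["n_iter_total"] = self.n_iter_total
        return out

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        names = PARAM_NAMES + DERIVED_NAMES
        idx = names.index(name)
        pool = np.concatenate([self.flat, self.derived_draws], axis=1)
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(pool[:, idx], [a, 100 - a])
        return float(lo), float(hi)

    def posterior_predictive_check(self, n_reps: int = 200, seed: int = 0) -> "PPCReport":
        return posterior_predictive_check(self, self.model.data, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# Hierarchical model
# ---------------------------------------------------------------------------

class HierarchicalExGaussRace:
    """Hierarchical race model: subject parameters drawn from group normals.

    Subject parameters follow N(group_mean, group_sd); the group means carry
    normal hyper-priors centred on the per-subject fits (scale ``hyper_sd``,
    default 1 on the sampling scale — seconds for the time parameters,
    probit units for trigger failures).  The group-level standard deviations
    are estimated by default, under a half-normal prior of scale
    ``group_sd_scale``; pass ``estimate_group_sd=False`` to fix them at that
    scale instead (the two readings of a "group SD set to 1" convention —
    prior scale vs fixed value — are both available because the convention
    is ambiguous; a fixed SD of 1 second leaves the group means essentially
    unidentified, so estimation is the default).  Time parameters keep the
    per-subject truncations; the trigger-failure parameter is untruncated in
    the hierarchical fit.

    Sampling is Metropolis-within-Gibbs: exact truncated-normal Gibbs
    updates for the group means, log-scale Metropolis for the group SDs,
    component-wise random-walk Metropolis for each subject's parameters.
    """

    def __init__(
        self,
        datasets: list,
        group_sd_scale: float | np.ndarray = 1.0,
        hyper_sd: float | np.ndarray = 1.0,
        estimate_group_sd: bool = True,
    ):
        if len(datasets) < 5:
            raise InsufficientDataError("hierarchical fit requires at least 5 subjects")
        for d in datasets:
            if d.go_rts.size < 10 or d.n_stop < 1:
                raise InsufficientDataError(
                    f"subject {d.participant_id}: needs >=10 go and >=1 stop trial"
                )
        self.datasets = datasets
        self.group_sd_scale = np.broadcast_to(np.asarray(group_sd_scale, float), (7,)).copy()
        self.hyper_sd = np.broadcast_to(np.asarray(hyper_sd, float), (7,)).copy()
        self.estimate_group_sd = estimate_group_sd
        self.priors = PriorSpec()

    @classmethod
    def from_sessions(cls, sessions: list, staircase: str, **kw) -> "HierarchicalExGaussRace":
        return cls([StopSignalData.from_session(s, staircase) for s in sessions], **kw)

    def _subject_logpost(
        self, i: int, theta: np.ndarray, group_mean: np.ndarray, group_sd: np.ndarray
    ) -> float:
        # time parameters truncated; tf_probit unbounded in the hierarchy
        if np.any(theta[:6] <= self.priors.lo[:6]) or np.any(theta[:6] >= self.priors.hi[:6]):
            return -np.inf
        lik = log_likelihood(_params_from_scaled(theta), self.datasets[i])
        prior = -0.5 * float(np.sum(((theta - group_mean) / group_sd) ** 2))
        return lik + prior

    def fit(
        self,
        seed: int,
        n_chains: int = 3,
        n_sweeps: int = 1200,
        max_sweeps: int = 4800,
        rhat_threshold: float = 1.1,
        subject_iter: int = 600,
    ) -> "HierarchicalResults":
        """Two-stage fit: abbreviated per-subject runs set start values and
        hyper-prior centres, then the joint Metropolis-within-Gibbs sampler
        runs until the group-level R-hat criterion or the sweep cap.
        """
        n_sub = len(self.datasets)
        ss = np.random.SeedSequence(seed)
        sub_seeds, chain_seeds = ss.spawn(2)
        per_subject_seeds = sub_seeds.spawn(n_sub)
        subject_starts = np.empty((n_sub, 7))
        for i, d in enumerate(self.datasets):
            res = ExGaussRaceModel(d, priors=self.priors).fit(
                seed=int(np.random.default_rng(per_subject_seeds[i]).integers(2**31)),
                n_iter=subject_iter,
                max_iter=subject_iter,
            )
            subject_starts[i] = res.flat.mean(axis=0) / _MS
        hyper_center = subject_starts.mean(axis=0)

        n_burn = n_sweeps // 2
        kept = n_sweeps - n_burn
        group_draws = np.empty((n_chains, kept, 7))
        group_sd_draws = np.empty((n_chains, kept, 7))
        subj_draws = np.empty((n_chains, kept, n_sub, 7))
        chain_rngs = [np.random.default_rng(s) for s in chain_seeds.spawn(n_chains)]
        s_init = np.maximum(subject_starts.std(axis=0, ddof=1), 0.01)

        for c in range(n_chains):
            rng = chain_rngs[c]
            theta = subject_starts * (1.0 + 0.03 * rng.standard_normal((n_sub, 7)))
            theta[:, :6] = np.clip(theta[:, :6], self.priors.lo[:6] + 1e-4,
                                   self.priors.hi[:6] - 1e-4)
            m = hyper_center + 0.05 * rng.standard_normal(7)
            s = (s_init if self.estimate_group_sd else self.group_sd_scale).copy()
            log_s = np.log(np.tile(_INIT_SCALES, (n_sub, 1)))
            for sweep in range(n_sweeps):
                # Gibbs: group means given subject parameters and group SDs
                prec = n_sub / s**2 + 1.0 / self.hyper_sd**2
                mean = (theta.sum(axis=0) / s**2
                        + hyper_center / self.hyper_sd**2) / prec
                sd = 1.0 / np.sqrt(prec)
                for j in range(7):
                    if j == 6:
                        m[j] = mean[j] + sd[j] * rng.standard_normal()
                    else:
                        m[j] = truncated_normal_draw(
                            mean[j], sd[j], self.priors.lo[j], self.priors.hi[j], rng
                        )
                if self.estimate_group_sd:
                    # Metropolis on log group SDs under a half-normal prior;
                    # the conditional involves no likelihood evaluations.
                    ss = np.sum((theta - m) ** 2, axis=0)
                    for j in range(7):
                        def cond(sj: float) -> float:
                            return (
                                -n_sub * np.log(sj)
                                - ss[j] / (2.0 * sj * sj)
                                - 0.5 * (sj / self.group_sd_scale[j]) ** 2
                            )
                        for _ in range(2):
                            prop = s[j] * np.exp(0.4 * rng.standard_normal())
                            # include the log-scale proposal Jacobian
                            lr = cond(prop) - cond(s[j]) + np.log(prop) - np.log(s[j])
                            if np.log(rng.random()) < lr:
                                s[j] = prop
                # group state moved: refresh subject conditionals
                lps = np.array(
                    [self._subject_logpost(i, theta[i], m, s) for i in range(n_sub)]
                )
                # Metropolis: subject parameters given group means/SDs
                for i in range(n_sub):
                    for j in range(7):
                        prop = theta[i].copy()
                        prop[j] += np.exp(log_s[i, j]) * rng.standard_normal()
                        lp_prop = self._subject_logpost(i, prop, m, s)
                        accepted = np.log(rng.random()) < lp_prop - lps[i]
                        if accepted:
                            theta[i] = prop
                            lps[i] = lp_prop
                        if sweep < n_burn:
                            gamma = min(0.1, 5.0 / (sweep + 10))
                            log_s[i, j] += gamma * (float(accepted) - 0.44)
                if sweep >= n_burn:
                    group_draws[c, sweep - n_burn] = m
                    group_sd_draws[c, sweep - n_burn] = s
                    subj_draws[c, sweep - n_burn] = theta

        rhat = gelman_rubin(group_draws)
        return HierarchicalResults(
            model=self,
            group_draws=group_draws * _MS,
            group_sd_draws=group_sd_draws * _MS,
            subject_draws=subj_draws * _MS,
            rhat=rhat,
            converged=bool(np.all(rhat < rhat_threshold)),
            n_sweeps_total=n_sweeps,
            seed=seed,
        )


@dataclass
class HierarchicalResults:
    """Posterior summaries of the hierarchical fit.

    ``group_draws``: (chains, draws, 7) group-level means (ms/probit scale);
    ``subject_draws``: (chains, draws, n_subjects, 7).
    """

    model: HierarchicalExGaussRace
    group_draws: np.ndarray
    group_sd_draws: np.ndarray
    subject_draws: np.ndarray
    rhat: np.ndarray
    converged: bool
    n_sweeps_total: int
    seed: int

    @property
    def group_flat(self) -> np.ndarray:
        return self.group_draws.reshape(-1, 7)

    def group_summary(self) -> pd.DataFrame:
        der = _derived(self.group_draws)
        rhat_der = gelman_rubin(der)
        out = pd.concat([
            _summary_block(self.group_flat, PARAM_NAMES, self.rhat),
            _summary_block(der.reshape(-1, 3), DERIVED_NAMES, rhat_der),
        ])
        out.attrs["converged"] = self.converged
        return out

    def subject_summary(self, i: int) -> pd.DataFrame:
        draws = self.subject_draws[:, :, i, :]
        rhat = gelman_rubin(draws)
        der = _derived(draws)
        return pd.concat([
            _summary_block(draws.reshape(-1, 7), PARAM_NAMES, rhat),
            _summary_block(der.reshape(-1, 3), DERIVED_NAMES, gelman_rubin(der)),
        ])

    def group_credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        names = PARAM_NAMES + DERIVED_NAMES
        idx = names.index(name)
        pool = np.concatenate([self.group_flat, _derived(self.group_flat)], axis=1)
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(pool[:, idx], [a, 100 - a])
        return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

@dataclass
class PPCReport:
    """Observed statistics against posterior-predictive 95% bands."""

    table: pd.DataFrame
    n_reps: int

    @property
    def violations(self) -> pd.DataFrame:
        return self.table[~self.table["inside_band"]]

    @property
    def ok(self) -> bool:
        return bool(self.table["inside_band"].all())

    def plot(self):  # pragma: no cover - diagnostic convenience
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        tbl = self.table
        x = np.arange(len(tbl))
        ax.errorbar(
            x, tbl["pred_mean"],
            yerr=[tbl["pred_mean"] - tbl["band_lo"], tbl["band_hi"] - tbl["pred_mean"]],
            fmt="o", label="posterior predictive (95%)",
        )
        ax.plot(x, tbl["observed"], "rx", label="observed")
        ax.set_xticks(x)
        ax.set_xticklabels(tbl["statistic"], rotation=90, fontsize=6)
        ax.legend()
        fig.tight_layout()
        return fig


def _ppc_stats(go_rts, sr_ssd, sr_rt, inh_ssd, ssd_edges) -> dict:
    stats = {}
    qs = [10, 30, 50, 70, 90]
    for q, v in zip(qs, np.percentile(go_rts, qs)):
        stats[f"go_rt_q{q}"] = v
    if len(sr_rt):
        for q, v in zip(qs, np.percentile(sr_rt, qs)):
            stats[f"failed_stop_rt_q{q}"] = v
    all_ssd = np.concatenate([sr_ssd, inh_ssd])
    for k in range(len(ssd_edges) - 1):
        lo, hi = ssd_edges[k], ssd_edges[k + 1]
        sel_all = (all_ssd >= lo) & (all_ssd < hi)
        if sel_all.sum() >= 5:
            sel_inh = (inh_ssd >= lo) & (inh_ssd < hi)
            stats[f"pstop_ssd_{int(lo)}_{int(hi)}"] = sel_inh.sum() / sel_all.sum()
    if len(sr_rt) >= 10 and np.ptp(sr_ssd) > 0:
        slope = np.polyfit(sr_ssd, sr_rt, 1)[0]
        stats["failed_stop_rt_vs_ssd_slope"] = slope
    return stats


def posterior_predictive_check(
    results, data: StopSignalData, n_reps: int = 200, seed: int = 0
) -> PPCReport:
    """Simulate replicate datasets from the joint posterior and compare.

    Each replicate draws one posterior parameter vector, simulates the same
    number of go trials and stop trials (at the observed SSDs), and records
    go RT quantiles, failed-stop RT quantiles, the inhibition function over
    SSD bins and the failed-stop RT vs SSD slope.  Observed statistics are
    flagged when they fall outside the central 95% predictive band.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    flat = results.flat if hasattr(results, "flat") else results.group_flat
    rng = np.random.default_rng(seed)
    all_ssd = np.concatenate([data.sr_ssd, data.inhibit_ssds])
    if all_ssd.size == 0:
        raise EstimationError("posterior predictive check needs stop trials")
    edges = np.unique(np.percentile(all_ssd, [0, 25, 50, 75, 100]))
    edges[-1] = edges[-1] + 1e-9
    observed = _ppc_stats(data.go_rts, data.sr_ssd, data.sr_rt, data.inhibit_ssds, edges)

    reps = []
    n_go = data.go_rts.size
    for _ in range(n_reps):
        p = ExGaussRaceParams.from_array(flat[rng.integers(len(flat))])
        go = exgauss_rvs(p.mu_go, p.sigma_go, p.tau_go, n_go, rng)
        trig = rng.random(all_ssd.size) >= p.tf
        stop_fin = all_ssd + exgauss_rvs(p.mu_stop, p.sigma_stop, p.tau_stop, all_ssd.size, rng)
        go_stop = exgauss_rvs(p.mu_go, p.sigma_go, p.tau_go, all_ssd.size, rng)
        responded = ~trig | (go_stop < stop_fin)
        reps.append(_ppc_stats(
            go, all_ssd[responded], go_stop[responded], all_ssd[~responded], edges
        ))
    rep_df = pd.DataFrame(reps)
    rows = []
    for name, obs in observed.items():
        col = rep_df[name].dropna() if name in rep_df else pd.Series(dtype=float)
        if len(col) < max(20, 0.5 * n_reps):
            continue
        lo, hi = np.percentile(col, [2.5, 97.5])
        rows.append(dict(
            statistic=name, observed=obs, pred_mean=col.mean(),
            band_lo=lo, band_hi=hi, inside_band=bool(lo <= obs <= hi),
        ))
    return PPCReport(table=pd.DataFrame(rows), n_reps=n_reps)
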