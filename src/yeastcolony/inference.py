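"""Bayesian calibration and hypothesis testing for the growth model.

The statistical model combines a Gaussian likelihood over the replicate-mean
growth curve (per-timepoint replicate variances) with two Gaussian terms for
the steady-state composition observations, and independent standard-normal
priors over the log-space parameters.  Marginal likelihoods are estimated by
population MCMC over a temperature ladder (power posteriors
``L(theta)^beta_i pi(theta)``) with adaptive random-walk moves, adjacent-
temperature swap moves, and thermodynamic integration over the ladder.
Hypothesis posteriors follow from the marginal likelihoods under a uniform
prior over the switching topologies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._fastode import fast_trajectory
from ._fastode import growth_loglik as _compiled_growth_loglik
from .microenv import (Hypothesis, params_from_vector, simulate_microenv,
                       total_mass)
from .synthdata import GrowthDataset


def _two_stage_minimize(neg, start, bounds=None, nm_maxiter=2000,
                        polish_maxiter=300):
    """Simplex search to cross the cliffs, quasi-Newton polish on the ridge.

    The posterior surface has near-discontinuous drops where trajectories
    degrade; gradient-based methods alone stall there, a simplex alone does
    not converge tightly.
    """
    r1 = minimize(neg, start, method="Nelder-Mead",
                  options={"maxiter": nm_maxiter, "xatol": 1e-4,
                           "fatol": 1e-6})
    r2 = minimize(neg, r1.x, method="L-BFGS-B", bounds=bounds,
                  options={"maxiter": polish_maxiter})
    return (r2.x, r2.fun) if r2.fun <= r1.fun else (r1.x, r1.fun)

__all__ = [
    "TemperatureLadder",
    "ChainSet",
    "EvidenceEstimate",
    "MCMCConfig",
    "log_likelihood",
    "log_prior",
    "make_ladder",
    "run_population_mcmc",
    "init_by_multistart",
    "thermodynamic_evidence",
    "hypothesis_posterior",
    "psrf",
    "map_estimate",
    "swap_log_accept",
]

#: log-likelihood assigned when the trajectory solve fails; keeps chains
#: alive in pathological corners of parameter space instead of raising
FAILED_SOLVE_LOGLIK = -1e10

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# likelihood and prior

#: log-space parameters beyond this magnitude are treated as solve failures
#: (exp() would overflow/underflow; the prior mass there is negligible)
THETA_BOUND = 30.0


def make_growth_loglik(data: GrowthDataset,
                       hyp: Hypothesis) -> Callable[[np.ndarray], float]:
    """Closure evaluating the growth likelihood through the compiled path.

    Precomputes the output grid (data times plus the composition time) so
    repeated calls — samplers, optimizers — avoid all per-call setup.
    """
    hyp = Hypothesis(hyp)
    t_eval = np.union1d(np.union1d(data.times, [0.0]), [data.t_N])
    t_eval = np.ascontiguousarray(t_eval, dtype=float)
    i_N = int(np.searchsorted(t_eval, data.t_N))
    is_data = np.isin(t_eval, data.times).astype(np.int8)
    mean_mass = np.ascontiguousarray(data.mean_mass, dtype=float)
    variance = np.ascontiguousarray(data.variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variances must be strictly positive")
    ve = data.sigma_alpha_e ** 2
    vq = data.sigma_alpha_q ** 2
    n_free = hyp.n_free
    has_b2 = hyp.allows_beta2
    has_b3 = hyp.allows_beta3

    def loglike(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (n_free,):
            raise ValueError(f"expected vector of length {n_free}")
        if not np.all(np.isfinite(theta)) or np.any(
                np.abs(theta) > THETA_BOUND):
            return FAILED_SOLVE_LOGLIK
        vals = np.exp(theta)
        p = np.empty(9)
        p[0] = vals[1]          # mu1
        p[1] = vals[4]          # mu2
        p[2] = vals[2]          # beta1
        p[3] = vals[3]          # K
        i = 8
        if has_b2:
            p[4] = vals[i]
            i += 1
        else:
            p[4] = 0.0
        p[5] = vals[i] if has_b3 else 0.0
        p[6:9] = vals[5:8]      # gamma1..gamma3
        y0 = np.array([vals[0], 0.0, 0.0, 1.0, 0.0])
        return float(_compiled_growth_loglik(
            p, y0, t_eval, is_data, i_N, mean_mass, variance, data.alpha_e,
            data.alpha_q, ve, vq, FAILED_SOLVE_LOGLIK))

    return loglike


def _model_curve_and_fractions(data: GrowthDataset, theta: np.ndarray,
                               hyp: Hypothesis, fast: bool = True):
    """Model total mass at the data grid plus state fractions at t_N."""
    if np.any(np.abs(theta) > THETA_BOUND):
        return None
    try:
        params, init = params_from_vector(theta, hyp)
    except ValueError:
        return None
    t_eval = np.union1d(np.union1d(data.times, [0.0]), [data.t_N])
    if fast:
        traj, ok = fast_trajectory(params.as_array(), init.as_array(), t_eval)
        if not ok or not np.all(np.isfinite(traj)):
            return None
        m = traj[:, :3].sum(axis=1)
        i_N = int(np.searchsorted(t_eval, data.t_N))
        m_N = m[i_N]
        if m_N <= 0:
            return None
        fe, fq = traj[i_N, 1] / m_N, traj[i_N, 2] / m_N
    else:
        from .microenv import IntegrationError, steady_fractions

        try:
            traj = simulate_microenv(params, init, t_eval, hyp)
            fe, fq = steady_fractions(traj, data.t_N)
        except (IntegrationError, ZeroDivisionError):
            return None
        m = total_mass(traj)
    if data.times.size:
        m = np.interp(data.times, t_eval, m)
    else:
        m = np.empty(0)
    return m, fe, fq


def log_likelihood(data: GrowthDataset, theta: np.ndarray, hyp: Hypothesis,
                   fast: bool = True) -> float:
    """Gaussian log-likelihood of the growth + composition data.

    Returns a large negative sentinel when the trajectory solve fails, so
    samplers and optimizers can keep running.
    """
    if np.any(data.variance <= 0):
        raise ValueError("variances must be strictly positive")
    if fast:
        return make_growth_loglik(data, hyp)(np.asarray(theta, float))
    out = _model_curve_and_fractions(data, np.asarray(theta, float),
                                     Hypothesis(hyp), fast)
    if out is None:
        return FAILED_SOLVE_LOGLIK
    m, fe, fq = out
    resid = data.mean_mass - m
    ll = -0.5 * np.sum(resid ** 2 / data.variance
                       + np.log(2.0 * np.pi * data.variance))
    for obs, pred, sd in ((data.alpha_e, fe, data.sigma_alpha_e),
                          (data.alpha_q, fq, data.sigma_alpha_q)):
        ll += -0.5 * ((obs - pred) / sd) ** 2 - 0.5 * np.log(
            2.0 * np.pi * sd ** 2)
    if not np.isfinite(ll):
        return FAILED_SOLVE_LOGLIK
    return float(ll)


def log_prior(theta: np.ndarray) -> float:
    """Independent standard-normal prior over the log-space coordinates."""
    theta = np.asarray(theta, dtype=float)
    return float(-0.5 * theta.size * _LOG_2PI - 0.5 * theta @ theta)


def informed_start(data: GrowthDataset, hyp: Hypothesis) -> np.ndarray:
    """Heuristic log-space start from gross growth-curve features.

    Reads the initial OD, the early exponential slope (growth rate on
    glucose with the normalized initial glucose near 1), and the curve
    plateau (glucose yield) off the data; switching rates start at generic
    slow values.  Coordinates are clipped to the bulk of the prior.
    """
    hyp = Hypothesis(hyp)
    D, t = data.mean_mass, data.times
    m0 = max(float(D[0]), 1e-3)
    d_max = float(D.max())
    mask = (D > 2 * m0) & (D < 0.5 * d_max) & (t < 40)
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(np.maximum(D[mask], 1e-6)), 1)[0]
        mu1 = max(float(slope), 0.05)
    else:
        mu1 = 0.5
    yield_mass = 0.6 * d_max
    vals = [m0, mu1, 0.1, 1.0, 0.1 * mu1, yield_mass, yield_mass, 1.0]
    vals += [0.05] * (hyp.n_free - 8)
    return np.clip(np.log(vals), -2.5, 2.5)


# ---------------------------------------------------------------------------
# temperature ladder

@dataclass(frozen=True)
class TemperatureLadder:
    """Ordered inverse temperatures 0 = beta_1 < ... < beta_N = 1."""

    betas: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", np.asarray(self.betas, dtype=float))
        b = self.betas
        if b.size < 2 or b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ValueError("ladder must be strictly increasing from 0 to 1")

    @property
    def n_beta(self) -> int:
        return self.betas.size


def make_ladder(n_beta: int, power: float = 5.0) -> TemperatureLadder:
    """Power-law ladder ``beta_i = ((i-1)/(N-1))^5`` concentrating low temps."""
    if n_beta < 2:
        raise ValueError("need at least two temperatures")
    i = np.arange(n_beta, dtype=float)
    return TemperatureLadder(betas=(i / (n_beta - 1)) ** power)


# ---------------------------------------------------------------------------
# population MCMC

@dataclass
class MCMCConfig:
    """Sampler settings.

    The defaults are sized for routine test-scale runs; ``full_scale``
    returns the full-scale settings (30 temperatures, 1e5 burn-in sweeps,
    every 1000th sample kept until 2500 samples).
    """

    n_burn: int = 2000
    n_keep: int = 300
    thin: int = 3
    adapt_window: int = 750
    adapt_every: int = 25
    seed: int | None = None
    initial_scale: float = 0.1

    @classmethod
    def full_scale(cls, seed: int | None = None) -> "MCMCConfig":
        return cls(n_burn=100_000, n_keep=2500, thin=1000, adapt_window=7500,
                   seed=seed)


@dataclass
class ChainSet:
    """Per-temperature samples and log-likelihood traces from one run."""

    ladder: TemperatureLadder
    samples: np.ndarray      # (n_temps, n_keep, dim)
    logliks: np.ndarray      # (n_temps, n_keep)
    accept_rate: np.ndarray  # (n_temps,)
    swap_rate: float
    seed: int | None = None

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["swap_rate"] = self.swap_rate
            if self.seed is not None:
                fh.attrs["seed"] = self.seed
            fh.create_dataset("betas", data=self.ladder.betas)
            for i in range(self.ladder.n_beta):
                grp = fh.create_group(f"temperature_{i:03d}")
                grp.attrs["beta"] = self.ladder.betas[i]
                grp.create_dataset("samples", data=self.samples[i])
                grp.create_dataset("loglik", data=self.logliks[i])
                grp.attrs["accept_rate"] = self.accept_rate[i]

    @classmethod
    def from_hdf5(cls, path) -> "ChainSet":
        import h5py

        with h5py.File(path, "r") as fh:
            betas = fh["betas"][...]
            n = betas.size
            samples = np.stack([fh[f"temperature_{i:03d}/samples"][...]
                                for i in range(n)])
            logliks = np.stack([fh[f"temperature_{i:03d}/loglik"][...]
                                for i in range(n)])
            acc = np.array([fh[f"temperature_{i:03d}"].attrs["accept_rate"]
                            for i in range(n)])
            seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
            return cls(TemperatureLadder(betas), samples, logliks, acc,
                       float(fh.attrs["swap_rate"]), seed)


def swap_log_accept(beta_i: float, beta_j: float,
                    loglik_i: float, loglik_j: float) -> float:
    """Log acceptance ratio for exchanging states between two temperatures.

    The product target is ``prod_i L(x_i)^{beta_i} pi(x_i)``; the priors
    cancel in the exchange ratio, leaving
    ``(beta_i - beta_j) * (loglik_j - loglik_i)``.
    """
    return (beta_i - beta_j) * (loglik_j - loglik_i)


def run_population_mcmc(log_like: Callable[[np.ndarray], float],
                        dim: int,
                        ladder: TemperatureLadder,
                        config: MCMCConfig,
                        log_prior_fn: Callable[[np.ndarray], float] = log_prior,
                        init: np.ndarray | None = None) -> ChainSet:
    """Sample the power-posterior product target across the ladder.

    One sweep = one adaptive random-walk Metropolis update per temperature
    followed by one swap attempt between a uniformly chosen adjacent pair.
    Proposal covariances adapt to the trailing ``adapt_window`` samples during
    burn-in and are frozen afterwards; the chilled ``beta = 0`` chain samples
    the prior, the ``beta = 1`` chain the posterior.
    """
    rng = np.random.default_rng(config.seed)
    betas = ladder.betas
    n_t = betas.size
    if init is None:
        x = rng.normal(0.0, 1.0, size=(n_t, dim))
    else:
        x = np.array(init, dtype=float, copy=True)
        if x.shape != (n_t, dim):
            raise ValueError("init must have shape (n_temps, dim)")
    ll = np.array([log_like(x[i]) for i in range(n_t)])
    lp = np.array([log_prior_fn(x[i]) for i in range(n_t)])
    if not np.all(np.isfinite(betas * ll + lp)):
        raise RuntimeError("non-finite posterior at initialization; "
                           "re-initialize (e.g. via init_by_multistart)")

    shape_chol = [np.eye(dim) for _ in range(n_t)]
    log_scale = np.full(n_t, np.log(config.initial_scale))
    history = np.empty((n_t, config.adapt_window, dim))
    h_len = 0
    h_pos = 0
    accepts = np.zeros(n_t)
    proposals = np.zeros(n_t)
    swap_acc = 0
    swap_try = 0
    samples = np.empty((n_t, config.n_keep, dim))
    logliks = np.empty((n_t, config.n_keep))
    kept = 0

    n_sweeps = config.n_burn + config.n_keep * config.thin
    sd_scale = 2.38 ** 2 / dim
    target_acc = 0.25
    for sweep in range(n_sweeps):
        burn = sweep < config.n_burn
        gamma = min(0.1, 5.0 / np.sqrt(sweep + 1.0)) if burn else 0.0
        for i in range(n_t):
            prop = x[i] + np.exp(log_scale[i]) * (
                shape_chol[i] @ rng.normal(size=dim))
            ll_p = log_like(prop)
            lp_p = log_prior_fn(prop)
            log_alpha = (betas[i] * ll_p + lp_p) - (betas[i] * ll[i] + lp[i])
            proposals[i] += 1
            accepted = np.log(rng.random()) < log_alpha
            if accepted:
                x[i] = prop
                ll[i] = ll_p
                lp[i] = lp_p
                accepts[i] += 1
            if burn:
                # acceptance-targeted scale tuning guards against proposal
                # covariance blow-up from swap-injected mode jumps
                log_scale[i] += gamma * (
                    (1.0 if accepted else 0.0) - target_acc)
        # swap moves between uniformly chosen adjacent pairs (one attempt
        # per rung interface keeps modes flowing through the ladder)
        for _ in range(n_t - 1):
            j = int(rng.integers(n_t - 1))
            swap_try += 1
            if np.log(rng.random()) < swap_log_accept(betas[j], betas[j + 1],
                                                      ll[j], ll[j + 1]):
                x[[j, j + 1]] = x[[j + 1, j]]
                ll[[j, j + 1]] = ll[[j + 1, j]]
                lp[[j, j + 1]] = lp[[j + 1, j]]
                swap_acc += 1
        if burn:
            history[:, h_pos] = x
            h_pos = (h_pos + 1) % config.adapt_window
            h_len = min(h_len + 1, config.adapt_window)
            if (h_len >= max(2 * dim, 20)
                    and (sweep + 1) % config.adapt_every == 0):
                for i in range(n_t):
                    cov = np.cov(history[i, :h_len].T)
                    cov = sd_scale * np.atleast_2d(cov) + 1e-8 * np.eye(dim)
                    try:
                        L = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        continue
                    # keep the shape, hand the overall size to log_scale
                    det_scale = np.exp(np.mean(np.log(np.diag(L))))
                    shape_chol[i] = L / det_scale
        elif (sweep - config.n_burn + 1) % config.thin == 0:
            samples[:, kept] = x
            logliks[:, kept] = ll
            kept += 1
    return ChainSet(ladder=ladder, samples=samples, logliks=logliks,
                    accept_rate=accepts / np.maximum(proposals, 1),
                    swap_rate=swap_acc / max(swap_try, 1), seed=config.seed)


def init_by_multistart(log_like: Callable[[np.ndarray], float],
                       dim: int,
                       ladder: TemperatureLadder,
                       n_starts: int = 3,
                       seed: int | None = None,
                       log_prior_fn: Callable[[np.ndarray], float] = log_prior,
                       extra_starts: Sequence[np.ndarray] = (),
                       ) -> np.ndarray:
    """Best local optimum of each power posterior from ``n_starts`` starts.

    Starts are drawn from the prior (the zero vector is always included;
    ``extra_starts`` such as :func:`informed_start` are prepended);
    optimization combines a simplex search with quasi-Newton polish.  The
    ladder is traversed from the posterior (beta = 1) downwards and each
    rung's optimum seeds the next rung, so the dominant posterior mode
    propagates through the whole ladder.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    base_starts = [np.asarray(s, dtype=float) for s in extra_starts]
    base_starts += [np.zeros(dim)]
    base_starts += [rng.normal(0.0, 1.0, dim) for _ in range(n_starts - 1)]
    out = np.empty((ladder.n_beta, dim))
    box = [(-6.0, 6.0)] * dim
    prev: np.ndarray | None = None
    for i in range(ladder.n_beta - 1, -1, -1):
        beta = ladder.betas[i]
        if prev is not None and beta < 1e-3:
            # the power posterior is prior-dominated here: its peak sits
            # between the prior mode and the cascaded optimum, and the
            # sampler equilibrates in a few sweeps; skip the optimization
            out[i] = prev if beta > 0 else np.zeros(dim)
            continue

        def neg(theta, beta=beta):
            return -(beta * log_like(theta) + log_prior_fn(theta))

        best_val, best_x = np.inf, base_starts[0]
        if prev is None:
            # coldest optimized rung: full multistart with simplex + polish
            for s in base_starts:
                xx, vv = _two_stage_minimize(neg, s)
                if vv < best_val:
                    best_val, best_x = vv, xx
        else:
            # warm-started rungs: polish the cascaded optimum
            res = minimize(neg, prev, method="L-BFGS-B", bounds=box,
                           options={"maxiter": 300})
            best_val, best_x = ((res.fun, res.x)
                                if res.fun <= neg(prev) else
                                (neg(prev), prev))
        if not np.isfinite(best_val):
            raise RuntimeError("all optimization starts failed")
        out[i] = best_x
        prev = best_x
    return out


# ---------------------------------------------------------------------------
# evidence and hypothesis posterior

def thermodynamic_evidence(chains: ChainSet,
                           ladder: TemperatureLadder | None = None,
                           ) -> tuple[float, float]:
    """Log marginal likelihood by trapezoidal quadrature over the ladder.

    Integrates the per-temperature posterior mean log-likelihood over beta.
    Returns ``(log_evidence, mc_standard_error)`` where the error term
    propagates the per-temperature standard errors through the trapezoid
    weights (correlations between sweeps are ignored, so this is a lower
    bound on the true uncertainty).
    """
    if ladder is None:
        ladder = chains.ladder
    if chains.logliks.shape[0] != ladder.n_beta:
        raise ValueError("chain set does not match ladder")
    mean_ll = chains.logliks.mean(axis=1)
    betas = ladder.betas
    log_z = float(np.trapezoid(mean_ll, betas))
    w = np.zeros(betas.size)
    db = np.diff(betas)
    w[:-1] += db / 2
    w[1:] += db / 2
    n = chains.logliks.shape[1]
    var = chains.logliks.var(axis=1, ddof=1) / n
    return log_z, float(np.sqrt(np.sum(w ** 2 * var)))


@dataclass
class EvidenceEstimate:
    """Marginal likelihoods and hypothesis posterior probabilities."""

    hypotheses: tuple[str, ...]
    log_evidence: np.ndarray
    posterior: np.ndarray
    mc_error: np.ndarray

    def summary(self) -> str:
        lines = ["hypothesis  log evidence     MC s.e.   posterior"]
        for h, z, e, p in zip(self.hypotheses, self.log_evidence,
                              self.mc_error, self.posterior):
            lines.append(f"{h:>10s}  {z:12.3f}  {e:10.3f}  {p:10.4f}")
        return "\n".join(lines)


def hypothesis_posterior(log_evidences: Sequence[float],
                         prior_probs: Sequence[float] | None = None,
                         ) -> np.ndarray:
    """Posterior over hypotheses from log marginal likelihoods.

    ``-inf`` evidences are allowed and give probability exactly 0; a uniform
    hypothesis prior is used when ``prior_probs`` is omitted.
    """
    log_z = np.asarray(log_evidences, dtype=float)
    if np.any(np.isnan(log_z)) or np.any(log_z == np.inf):
        raise ValueError("log evidences must be finite or -inf")
    if np.all(np.isneginf(log_z)):
        raise ValueError("all evidences are -inf; posterior undefined")
    if prior_probs is None:
        prior_probs = np.full(log_z.size, 1.0 / log_z.size)
    prior_probs = np.asarray(prior_probs, dtype=float)
    if abs(prior_probs.sum() - 1.0) > 1e-9 or np.any(prior_probs < 0):
        raise ValueError("prior probabilities must be a distribution")
    with np.errstate(divide="ignore"):
        log_w = log_z + np.log(prior_probs)
    probs = np.exp(log_w - logsumexp(log_w))
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# diagnostics and MAP

def psrf(chains: Sequence[np.ndarray]) -> np.ndarray:
    """Classic Gelman-Rubin potential scale reduction factor, per parameter.

    ``chains`` is a sequence of (n_samples, dim) arrays from independent
    runs.  Values near 1 indicate between-run agreement.
    """
    arrs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in chains]
    m = len(arrs)
    if m < 2:
        raise ValueError("need at least two independent runs")
    n = arrs[0].shape[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("all runs must have equal shapes")
    stacked = np.stack(arrs)                      # (m, n, dim)
    within = stacked.var(axis=1, ddof=1).mean(axis=0)
    means = stacked.mean(axis=1)                  # (m, dim)
    between = n * means.var(axis=0, ddof=1)
    if np.any(within == 0):
        raise ZeroDivisionError("zero within-chain variance")
    v_hat = (n - 1) / n * within + (1.0 + 1.0 / m) * between / n
    return np.sqrt(v_hat / within)


def map_estimate(chains: ChainSet,
                 log_like: Callable[[np.ndarray], float],
                 log_prior_fn: Callable[[np.ndarray], float] = log_prior,
                 refine: bool = True) -> np.ndarray:
    """Maximum a posteriori point: best beta=1 sample, locally refined.

    The refined point is only accepted if it does not decrease the log
    posterior, so the result is never worse than the best sample.
    """
    post = chains.logliks[-1] + np.array(
        [log_prior_fn(s) for s in chains.samples[-1]])
    best = chains.samples[-1][int(np.argmax(post))].copy()
    if not refine:
        return best
    def neg(theta):
        return -(log_like(theta) + log_prior_fn(theta))

    res = minimize(neg, best, method="L-BFGS-B", options={"maxiter": 500})
    return res.x if -res.fun >= float(np.max(post)) else best
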