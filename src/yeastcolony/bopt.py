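"""Gaussian-process Bayesian optimization of the spatial transfer rates.

The two nutrient transfer rates (within agar, within colony) are the only
free parameters of the lattice simulator; each cost evaluation requires a
full colony simulation, so the log-sum-of-squares footprint cost is minimized
with a GP surrogate (squared-exponential kernel, Gaussian observation noise)
and expected-improvement proposals, initialized from a Latin hypercube
design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.stats import norm, qmc

__all__ = [
    "GPSurrogate",
    "BoptConfig",
    "footprint_cost",
    "sq_exp_kernel",
    "gp_fit",
    "gp_predict",
    "expected_improvement",
    "lhs_design",
    "bayes_optimize",
    "calibrate_spatial",
]

JITTER = 1e-10
SD_FLOOR = 1e-12
COST_FLOOR = 1e-300
#: sentinel recorded when a cost evaluation raises
FAILED_COST = 709.0  # ~ log(1e308)


def footprint_cost(sim_areas: np.ndarray, meas_areas: np.ndarray) -> float:
    """Log of the summed squared footprint-area differences.

    A perfect match would be log(0); the sum is floored at 1e-300 so the
    cost stays finite.
    """
    sim = np.asarray(sim_areas, dtype=float)
    meas = np.asarray(meas_areas, dtype=float)
    if sim.shape != meas.shape or sim.size < 1:
        raise ValueError("area series must have equal nonzero lengths")
    return float(np.log(max(np.sum((sim - meas) ** 2), COST_FLOOR)))


def sq_exp_kernel(x: np.ndarray, x2: np.ndarray,
                  kernel_params: np.ndarray) -> np.ndarray:
    """Squared-exponential kernel; last entry of ``kernel_params`` is the
    signal variance, the rest are per-dimension length-scales."""
    kp = np.asarray(kernel_params, dtype=float)
    x = np.atleast_2d(x)
    x2 = np.atleast_2d(x2)
    ls = kp[:-1]
    d2 = np.sum(((x[:, None, :] - x2[None, :, :]) / ls) ** 2, axis=-1)
    return kp[-1] * np.exp(-0.5 * d2)


@dataclass
class GPSurrogate:
    """Fitted zero-mean GP over standardized cost values."""

    X: np.ndarray
    y: np.ndarray                 # standardized
    kernel_params: np.ndarray     # (d length-scales, signal variance)
    noise_var: float
    y_mean: float
    y_sd: float

    def log_marginal_likelihood(self) -> float:
        return _gp_lml(self.X, self.y, self.kernel_params, self.noise_var)


def _gp_lml(X: np.ndarray, y: np.ndarray, kernel_params: np.ndarray,
            noise_var: float) -> float:
    """Zero-mean Gaussian marginal log-likelihood of the standardized costs."""
    n = X.shape[0]
    K = sq_exp_kernel(X, X, kernel_params)
    K[np.diag_indices_from(K)] += noise_var + JITTER
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance not positive definite after jitter") from err
    alpha = cho_solve((L, True), y)
    return float(-0.5 * y @ alpha - np.sum(np.log(np.diag(L)))
                 - 0.5 * n * np.log(2.0 * np.pi))


def gp_fit(X: np.ndarray, y: np.ndarray,
           init_params: np.ndarray | None = None,
           init_noise_sd: float = 0.1) -> GPSurrogate:
    """Fit kernel hyperparameters and noise variance by maximizing the
    marginal likelihood of the standardized costs (log-space, single start).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two evaluated points")
    if not np.all(np.isfinite(y)):
        raise ValueError("cost values must be finite")
    d = X.shape[1]
    if init_params is None:
        init_params = np.ones(d + 1)
    y_mean = float(y.mean())
    y_sd = float(max(y.std(), SD_FLOOR))
    ys = (y - y_mean) / y_sd

    def neg(log_p):
        kp = np.exp(log_p[:-1])
        nv = np.exp(log_p[-1]) ** 2
        try:
            val = -_gp_lml(X, ys, kp, nv)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    x0 = np.log(np.concatenate([init_params, [init_noise_sd]]))
    # box keeps exp() finite and the covariance factorizable
    box = [(-10.0, 10.0)] * (d + 1) + [(-10.0, 5.0)]
    res = minimize(neg, x0, method="L-BFGS-B", bounds=box,
                   options={"maxiter": 500})
    best = res.x if res.fun <= neg(x0) else x0
    kp = np.exp(best[:-1])
    nv = float(np.exp(best[-1]) ** 2)
    return GPSurrogate(X=X, y=ys, kernel_params=kp, noise_var=nv,
                       y_mean=y_mean, y_sd=y_sd)


def gp_predict(s: GPSurrogate, x_star: np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior predictive mean and sd (including observation noise) at
    ``x_star``, de-standardized to the original cost scale."""
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    K = sq_exp_kernel(s.X, s.X, s.kernel_params)
    K[np.diag_indices_from(K)] += s.noise_var + JITTER
    cf = cho_factor(K, lower=True)
    k_star = sq_exp_kernel(x_star, s.X, s.kernel_params)
    mean = k_star @ cho_solve(cf, s.y)
    v = cho_solve(cf, k_star.T)
    var = (s.kernel_params[-1] + s.noise_var) - np.einsum(
        "ij,ji->i", k_star, v)
    var = np.maximum(var, 0.0)
    return s.y_mean + s.y_sd * mean, s.y_sd * np.sqrt(var)


def expected_improvement(y_hat: np.ndarray, sd: np.ndarray,
                         y_min: float) -> np.ndarray:
    """Closed-form E[max(y_min - Y, 0)] for Gaussian Y ~ N(y_hat, sd^2)."""
    y_hat = np.asarray(y_hat, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (y_min - y_hat) / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(sd > 0,
                  (y_min - y_hat) * norm.cdf(z) + sd * norm.pdf(z),
                  np.maximum(y_min - y_hat, 0.0))
    return np.maximum(ei, 0.0)


def lhs_design(bounds: Sequence[tuple[float, float]], n: int,
               seed: int | None = None) -> np.ndarray:
    """Latin hypercube design: one point per axis stratum per dimension."""
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = np.asarray(bounds, dtype=float)
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, bounds[:, 0], bounds[:, 1])


@dataclass
class BoptConfig:
    """Search bounds and loop settings for the surrogate optimization."""

    bounds: tuple[tuple[float, float], ...] = ((5.0, 75.0), (0.005, 1.0))
    n_init: int = 20
    max_iters: int = 30
    ei_threshold: float = 1e-46
    n_ei_starts: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")
        if self.n_init < 2:
            raise ValueError("n_init must be >= 2")


def _maximize_ei(surrogate: GPSurrogate, y_min: float,
                 bounds: np.ndarray, n_starts: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Multistart local maximization of expected improvement within bounds."""
    starts = lhs_design(bounds, n_starts,
                        seed=int(rng.integers(2 ** 31 - 1)))

    def neg_ei(x):
        mu, sd = gp_predict(surrogate, x)
        return -float(expected_improvement(mu, sd, y_min)[0])

    best_x, best_v = starts[0], np.inf
    for s in starts:
        res = minimize(neg_ei, s, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200})
        if res.fun < best_v:
            best_v, best_x = res.fun, res.x
    return np.clip(best_x, bounds[:, 0], bounds[:, 1]), -best_v


@dataclass
class BoptHistory:
    X: np.ndarray
    y: np.ndarray
    ei: np.ndarray  # EI of the proposal that produced each point (nan for init)

    def incumbent_trace(self) -> np.ndarray:
        return np.minimum.accumulate(self.y)


def bayes_optimize(cost_fn: Callable[[np.ndarray], float],
                   config: BoptConfig,
                   ) -> tuple[np.ndarray, float, BoptHistory]:
    """LHS initialization followed by fit / EI-maximize / evaluate loop.

    Stops when the maximal expected improvement drops below the threshold or
    ``max_iters`` proposals have been evaluated.  Failed cost evaluations are
    recorded with a large sentinel value.
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(config.bounds, dtype=float)

    def safe_cost(x):
        try:
            v = float(cost_fn(np.asarray(x, dtype=float)))
            return v if np.isfinite(v) else FAILED_COST
        except Exception:
            return FAILED_COST

    X = list(lhs_design(bounds, config.n_init,
                        seed=int(rng.integers(2 ** 31 - 1))))
    y = [safe_cost(x) for x in X]
    ei_trace = [np.nan] * config.n_init
    for _ in range(config.max_iters):
        surrogate = gp_fit(np.array(X), np.array(y))
        x_next, ei = _maximize_ei(surrogate, float(np.min(y)), bounds,
                                  config.n_ei_starts, rng)
        if ei < config.ei_threshold:
            break
        X.append(x_next)
        y.append(safe_cost(x_next))
        ei_trace.append(ei)
    hist = BoptHistory(X=np.array(X), y=np.array(y), ei=np.array(ei_trace))
    i_best = int(np.argmin(hist.y))
    return hist.X[i_best], float(hist.y[i_best]), hist


def calibrate_spatial(footprint_data, config: BoptConfig,
                      lattice_config=None,
                      params=None,
                      hyp="H2") -> tuple[np.ndarray, float, BoptHistory]:
    """Fit (lambda_agar, lambda_col) to a footprint-area series.

    Each candidate is scored by simulating the colony at those rates on the
    configured lattice and evaluating the log-sum-of-squares cost at the
    measurement times.
    """
    from .microenv import Hypothesis
    from .spatial import LatticeConfig, simulate_colony
    from .synthdata import default_truth_params

    if lattice_config is None:
        lattice_config = LatticeConfig()
    if params is None:
        params, _ = default_truth_params()
    hyp = Hypothesis(hyp)
    t = footprint_data.times
    horizon = float(t[-1])
    sample_dt = float(t[1] - t[0]) if t.size > 1 else horizon

    def cost(x):
        cfg = lattice_config.replace(lambda_agar=float(x[0]),
                                     lambda_col=float(x[1]))
        times, areas, _ = simulate_colony(cfg, params, hyp, horizon=horizon,
                                          sample_dt=sample_dt)
        sim = np.interp(t, times, areas)
        return footprint_cost(sim, footprint_data.area_mm2)

    return bayes_optimize(cost, config)
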