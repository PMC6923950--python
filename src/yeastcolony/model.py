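"""Model/Results interface over the calibration machinery.

`GrowthModel` wraps the microenvironment ODEs plus the growth-curve
likelihood for one switching hypothesis; `fit` returns a MAP point estimate
and `fit_mcmc` the full population-MCMC posterior with the thermodynamic
evidence.  `select_hypothesis` compares the three switching topologies by
marginal likelihood.  `ColonyCalibrator` fits the two spatial transfer rates
to footprint data via the GP surrogate loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import inference
from .bopt import BoptConfig, BoptHistory, calibrate_spatial
from .microenv import (Hypothesis, MicroenvParams, MicroenvState, param_names,
                       params_from_vector, simulate_microenv,
                       steady_fractions, total_mass)
from .synthdata import GrowthDataset

__all__ = ["GrowthModel", "GrowthResults", "GrowthMCMCResults",
           "select_hypothesis", "ColonyCalibrator", "CalibrationResults"]


class GrowthModel:
    """Three-state growth model bound to a growth dataset and a hypothesis."""

    def __init__(self, data: GrowthDataset,
                 hypothesis: Hypothesis = Hypothesis.H2):
        self.data = data
        self.hypothesis = Hypothesis(hypothesis)
        self._loglike = inference.make_growth_loglik(data, self.hypothesis)

    @classmethod
    def from_csv(cls, path, hypothesis: Hypothesis = Hypothesis.H2,
                 ) -> "GrowthModel":
        return cls(GrowthDataset.from_csv(path), hypothesis)

    @property
    def k_params(self) -> int:
        return self.hypothesis.n_free

    def loglike(self, theta: np.ndarray) -> float:
        return self._loglike(theta)

    def logprior(self, theta: np.ndarray) -> float:
        return inference.log_prior(theta)

    def logposterior(self, theta: np.ndarray) -> float:
        return self.loglike(theta) + self.logprior(theta)

    def fit(self, n_starts: int = 6, seed: int | None = None,
            ) -> "GrowthResults":
        """Multistart MAP estimate.

        Starts from a data-informed heuristic point, the prior mode, and
        prior draws; each start runs a simplex search with quasi-Newton
        polish.
        """
        rng = np.random.default_rng(seed)
        starts = [inference.informed_start(self.data, self.hypothesis),
                  np.zeros(self.k_params)]
        starts += [rng.normal(0.0, 1.0, self.k_params)
                   for _ in range(max(n_starts - 2, 0))]

        def neg(theta):
            return -self.logposterior(theta)

        best_x, best_v = None, np.inf
        for s in starts:
            x, v = inference._two_stage_minimize(neg, s)
            if v < best_v:
                best_v, best_x = v, x
        if best_x is None or not np.isfinite(best_v):
            raise RuntimeError("all optimization starts failed")
        return GrowthResults(model=self, theta=best_x,
                             log_posterior=-best_v)

    def fit_mcmc(self, n_beta: int = 10,
                 config: inference.MCMCConfig | None = None,
                 n_runs: int = 2, seed: int | None = None,
                 multistart_init: bool = True) -> "GrowthMCMCResults":
        """Population MCMC over a temperature ladder; one ChainSet per run."""
        if config is None:
            config = inference.MCMCConfig(seed=seed)
        ladder = inference.make_ladder(n_beta)
        ss = np.random.SeedSequence(config.seed)
        run_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                     ss.spawn(n_runs + 1)]
        init = None
        if multistart_init:
            init = inference.init_by_multistart(
                self.loglike, self.k_params, ladder, n_starts=2,
                seed=run_seeds[-1],
                extra_starts=[inference.informed_start(self.data,
                                                       self.hypothesis)])
        runs = []
        for r in range(n_runs):
            cfg = inference.MCMCConfig(
                n_burn=config.n_burn, n_keep=config.n_keep, thin=config.thin,
                adapt_window=config.adapt_window,
                adapt_every=config.adapt_every, seed=run_seeds[r],
                initial_scale=config.initial_scale)
            runs.append(inference.run_population_mcmc(
                self.loglike, self.k_params, ladder, cfg, init=init))
        return GrowthMCMCResults(model=self, runs=runs, ladder=ladder)


@dataclass
class GrowthResults:
    """MAP fit of a growth model: parameter estimates and fit diagnostics."""

    model: GrowthModel
    theta: np.ndarray
    log_posterior: float

    def __post_init__(self) -> None:
        self.params, self.init_state = params_from_vector(
            self.theta, self.model.hypothesis)

    @property
    def param_names(self) -> tuple[str, ...]:
        return param_names(self.model.hypothesis)

    def trajectory(self, times: np.ndarray | None = None):
        if times is None:
            times = self.model.data.times
        return simulate_microenv(self.params, self.init_state, times,
                                 self.model.hypothesis)

    def fitted_curve(self) -> np.ndarray:
        return total_mass(self.trajectory())

    def resid(self) -> np.ndarray:
        return self.model.data.mean_mass - self.fitted_curve()

    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid() ** 2)))

    def steady_fractions(self) -> tuple[float, float]:
        data = self.model.data
        t_grid = np.union1d(data.times, [data.t_N])
        traj = simulate_microenv(self.params, self.init_state, t_grid,
                                 self.model.hypothesis)
        return steady_fractions(traj, data.t_N)

    def summary(self) -> str:
        fe, fq = self.steady_fractions()
        lines = [
            f"Growth model fit  [{self.model.hypothesis.value}]",
            f"  log posterior : {self.log_posterior:.3f}",
            f"  curve RMSE    : {self.rmse():.5f}",
            f"  fractions at t_N={self.model.data.t_N:g} h : "
            f"ethanol {fe:.3f}, quiescent {fq:.3f}",
            "  parameter      log-space      natural",
        ]
        for name, lv, v in zip(self.param_names, self.theta,
                               np.exp(self.theta)):
            lines.append(f"  {name:<12s} {lv:12.4f} {v:12.5f}")
        return "\n".join(lines)


@dataclass
class GrowthMCMCResults:
    """Posterior sample, evidence estimate, and convergence diagnostics."""

    model: GrowthModel
    runs: list[inference.ChainSet]
    ladder: inference.TemperatureLadder

    def posterior_samples(self) -> np.ndarray:
        """Pooled beta=1 samples across runs, shape (n_total, dim)."""
        return np.concatenate([r.samples[-1] for r in self.runs])

    def log_evidence(self) -> tuple[float, float]:
        pooled = inference.ChainSet(
            ladder=self.ladder,
            samples=np.concatenate([r.samples for r in self.runs], axis=1),
            logliks=np.concatenate([r.logliks for r in self.runs], axis=1),
            accept_rate=np.mean([r.accept_rate for r in self.runs], axis=0),
            swap_rate=float(np.mean([r.swap_rate for r in self.runs])))
        return inference.thermodynamic_evidence(pooled)

    def psrf(self) -> np.ndarray:
        if len(self.runs) < 2:
            raise ValueError("PSRF needs at least two independent runs")
        return inference.psrf([r.samples[-1] for r in self.runs])

    def map_estimate(self) -> GrowthResults:
        pooled = inference.ChainSet(
            ladder=self.ladder,
            samples=np.concatenate([r.samples for r in self.runs], axis=1),
            logliks=np.concatenate([r.logliks for r in self.runs], axis=1),
            accept_rate=np.mean([r.accept_rate for r in self.runs], axis=0),
            swap_rate=float(np.mean([r.swap_rate for r in self.runs])))
        theta = inference.map_estimate(pooled, self.model.loglike)
        return GrowthResults(model=self.model, theta=theta,
                             log_posterior=self.model.logposterior(theta))

    def summary(self) -> str:
        z, se = self.log_evidence()
        lines = [
            f"Population MCMC  [{self.model.hypothesis.value}]  "
            f"({len(self.runs)} runs, {self.ladder.n_beta} temperatures)",
            f"  log evidence  : {z:.3f} (MC s.e. {se:.3f})",
            f"  swap rate     : "
            f"{np.mean([r.swap_rate for r in self.runs]):.3f}",
        ]
        if len(self.runs) >= 2:
            r = self.psrf()
            lines.append(f"  max PSRF      : {np.max(r):.3f}"
                         + ("  (converged < 1.1)" if np.max(r) < 1.1
                            else "  (check convergence)"))
        sample = self.posterior_samples()
        lines.append("  parameter      post. mean     post. sd   (log space)")
        for name, mu, sd in zip(param_names(self.model.hypothesis),
                                sample.mean(axis=0), sample.std(axis=0)):
            lines.append(f"  {name:<12s} {mu:12.4f} {sd:12.4f}")
        return "\n".join(lines)


def select_hypothesis(data: GrowthDataset,
                      hypotheses=(Hypothesis.H1, Hypothesis.H2,
                                  Hypothesis.H3),
                      n_beta: int = 30,
                      config: inference.MCMCConfig | None = None,
                      n_runs: int = 1,
                      seed: int | None = None) -> inference.EvidenceEstimate:
    """Marginal likelihood and posterior probability per switching topology."""
    log_z, errs = [], []
    for hyp in hypotheses:
        model = GrowthModel(data, hyp)
        cfg = config or inference.MCMCConfig()
        # the same sampler seed is reused for every hypothesis (common
        # random numbers): the noisy bottom-ladder contributions are highly
        # correlated across the nested models and partially cancel in the
        # evidence differences that drive the posterior
        cfg = inference.MCMCConfig(
            n_burn=cfg.n_burn, n_keep=cfg.n_keep, thin=cfg.thin,
            adapt_window=cfg.adapt_window, adapt_every=cfg.adapt_every,
            seed=seed, initial_scale=cfg.initial_scale)
        res = model.fit_mcmc(n_beta=n_beta, config=cfg, n_runs=n_runs,
                             seed=cfg.seed)
        z, se = res.log_evidence()
        log_z.append(z)
        errs.append(se)
    post = inference.hypothesis_posterior(log_z)
    return inference.EvidenceEstimate(
        hypotheses=tuple(Hypothesis(h).value for h in hypotheses),
        log_evidence=np.array(log_z), posterior=post,
        mc_error=np.array(errs))


class ColonyCalibrator:
    """Fits the agar/colony nutrient transfer rates to footprint data."""

    def __init__(self, footprint_data, lattice_config=None,
                 params: MicroenvParams | None = None,
                 hypothesis: Hypothesis = Hypothesis.H2):
        self.data = footprint_data
        self.lattice_config = lattice_config
        self.params = params
        self.hypothesis = Hypothesis(hypothesis)

    def fit(self, config: BoptConfig | None = None,
            seed: int | None = None) -> "CalibrationResults":
        if config is None:
            config = BoptConfig(seed=seed)
        elif seed is not None:
            config = BoptConfig(bounds=config.bounds, n_init=config.n_init,
                                max_iters=config.max_iters,
                                ei_threshold=config.ei_threshold,
                                n_ei_starts=config.n_ei_starts, seed=seed)
        best, value, history = calibrate_spatial(
            self.data, config, self.lattice_config, self.params,
            self.hypothesis)
        return CalibrationResults(lambda_agar=float(best[0]),
                                  lambda_col=float(best[1]),
                                  cost=value, history=history,
                                  config=config)


@dataclass
class CalibrationResults:
    """Fitted transfer rates with the full surrogate-evaluation history."""

    lambda_agar: float
    lambda_col: float
    cost: float
    history: BoptHistory
    config: BoptConfig

    def summary(self) -> str:
        n_total = self.history.y.size
        return "\n".join([
            "Spatial calibration (GP Bayesian optimization)",
            f"  lambda_agar : {self.lambda_agar:.4f} 1/h",
            f"  lambda_col  : {self.lambda_col:.4f} 1/h",
            f"  best cost   : {self.cost:.4f} "
            "(log sum of squared area differences)",
            f"  evaluations : {n_total} "
            f"({self.config.n_init} initial + "
            f"{n_total - self.config.n_init} proposals)",
        ])

    def history_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(self.history.y.size),
            "lambda_agar": self.history.X[:, 0],
            "lambda_col": self.history.X[:, 1],
            "cost": self.history.y,
            "expected_improvement": self.history.ei,
        })
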