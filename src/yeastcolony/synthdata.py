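"""Synthetic datasets with the statistical structure the calibration assumes.

Two observables drive the two calibration stages:

* liquid-culture growth curves — total cell mass (OD-equivalent) sampled every
  15 min for 88 h over several replicates, summarized per time point by the
  replicate mean and sample variance, plus steady-state population-composition
  observations (ethanol-state and quiescent fractions) at 80 h;
* colony footprint areas — the area (mm^2) of the region under a colony
  growing on an agar disc, sampled every 20 min for up to 7.5 days.

The generators run the corresponding forward models (the microenvironment
ODEs, the 3D lattice simulator) at known ground-truth parameters and add
measurement noise, so every inference stage can be exercised end-to-end and
checked for parameter recovery without any experimental inputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microenv import (Hypothesis, MicroenvParams, MicroenvState,
                       params_from_vector, simulate_microenv,
                       steady_fractions, total_mass, vector_from_params)

__all__ = [
    "GrowthDataset",
    "FootprintDataset",
    "default_truth_params",
    "default_truth_vector",
    "generate_growth_curves",
    "generate_footprint",
]

#: variance floor so the per-point Gaussian likelihood is always evaluable
VARIANCE_FLOOR = 1e-8

# Ground-truth kinetic constants used throughout the test suite: an H2
# parameterization whose 80 h trajectory carries 29% of the mass in the
# ethanol state and 62% in the quiescent state (the published steady-state
# composition for wild-type cultures), with a clear diauxic shift around
# 6-10 h and a saturating total-mass curve.
_TRUTH = MicroenvParams(mu1=1.0, mu2=0.06881, beta1=0.07591, K=3.03593,
                        beta2=0.0, beta3=0.02418, gamma1=1.5, gamma2=1.5,
                        gamma3=1.0)
_TRUTH_MG0 = 0.1


def default_truth_params() -> tuple[MicroenvParams, MicroenvState]:
    """Ground-truth kinetics and initial state for synthetic wild-type data."""
    return _TRUTH, MicroenvState(m_g=_TRUTH_MG0, g=1.0)


def default_truth_vector(hyp: Hypothesis = Hypothesis.H2) -> np.ndarray:
    """Ground truth as a log-space free-parameter vector under ``hyp``."""
    return vector_from_params(_TRUTH if Hypothesis(hyp) is Hypothesis.H2
                              else _TRUTH, _TRUTH_MG0, hyp)


@dataclass
class GrowthDataset:
    """Replicate-averaged growth curve plus composition observations.

    ``mean_mass[k]`` and ``variance[k]`` are the replicate mean and sample
    variance of total cell mass at ``times[k]``; ``alpha_e``/``alpha_q`` are
    the observed ethanol-state and quiescent mass fractions at ``t_N`` with
    standard deviations ``sigma_alpha_e``/``sigma_alpha_q``.
    """

    times: np.ndarray
    mean_mass: np.ndarray
    variance: np.ndarray
    n_replicates: int
    alpha_e: float
    alpha_q: float
    sigma_alpha_e: float
    sigma_alpha_q: float
    t_N: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_mass = np.asarray(self.mean_mass, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (self.times.size == self.mean_mass.size == self.variance.size):
            raise ValueError("times, mean_mass, variance must align")
        if self.times.size and np.any(self.variance <= 0):
            raise ValueError("variances must be strictly positive")
        if not (0 <= self.alpha_e and 0 <= self.alpha_q
                and self.alpha_e + self.alpha_q <= 1):
            raise ValueError("composition fractions must lie in the simplex")
        if self.times.size and self.t_N > self.times.max():
            raise ValueError("t_N must lie within the sampled time range")

    def to_csv(self, path) -> None:
        header = (f"# n_replicates={self.n_replicates}\n"
                  f"# alpha_e={self.alpha_e!r}\n"
                  f"# alpha_q={self.alpha_q!r}\n"
                  f"# sigma_alpha_e={self.sigma_alpha_e!r}\n"
                  f"# sigma_alpha_q={self.sigma_alpha_q!r}\n"
                  f"# t_N={self.t_N!r}\n")
        df = pd.DataFrame({"time_h": self.times, "mean_mass": self.mean_mass,
                           "variance": self.variance})
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.17g")
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "GrowthDataset":
        meta = {}
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
        df = pd.read_csv(io.StringIO(text), comment="#",
                         float_precision="round_trip")
        return cls(times=df["time_h"].to_numpy(),
                   mean_mass=df["mean_mass"].to_numpy(),
                   variance=df["variance"].to_numpy(),
                   n_replicates=int(meta["n_replicates"]),
                   alpha_e=meta["alpha_e"], alpha_q=meta["alpha_q"],
                   sigma_alpha_e=meta["sigma_alpha_e"],
                   sigma_alpha_q=meta["sigma_alpha_q"], t_N=meta["t_N"])


@dataclass
class FootprintDataset:
    """Colony footprint-area time series (hours, mm^2) for one replicate."""

    times: np.ndarray
    area_mm2: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.area_mm2 = np.asarray(self.area_mm2, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.area_mm2 < 0):
            raise ValueError("areas must be non-negative")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_h": self.times, "area_mm2": self.area_mm2,
                           "replicate": self.replicate})
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FootprintDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(times=df["time_h"].to_numpy(),
                   area_mm2=df["area_mm2"].to_numpy(),
                   replicate=int(df["replicate"].iloc[0]) if len(df) else 0)


def generate_growth_curves(truth: np.ndarray | None = None,
                           hyp: Hypothesis = Hypothesis.H2,
                           n_replicates: int = 6,
                           noise_sd: float = 0.02,
                           seed: int | None = None,
                           t_max: float = 88.0,
                           dt: float = 0.25,
                           t_N: float = 80.0,
                           sigma_alpha: float = 0.02,
                           ) -> GrowthDataset:
    """Simulate replicate growth curves and composition observations.

    Each replicate is the noiseless model total mass on the 15-min grid plus
    i.i.d. additive Gaussian noise; the dataset stores the per-timepoint
    replicate mean and sample variance.  Composition observations at ``t_N``
    are the true state fractions perturbed by truncated Gaussian noise of
    standard deviation ``sigma_alpha``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a sample variance")
    hyp = Hypothesis(hyp)
    if truth is None:
        truth = default_truth_vector(hyp)
    rng = np.random.default_rng(seed)
    params, init = params_from_vector(truth, hyp)
    times = np.arange(0.0, t_max + dt / 2, dt)
    traj = simulate_microenv(params, init, times, hyp)
    m = total_mass(traj)
    if not np.all(np.isfinite(m)):
        raise RuntimeError("ground-truth trajectory is not finite")
    reps = m[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, m.size))
    mean = reps.mean(axis=0)
    var = np.maximum(reps.var(axis=0, ddof=1), VARIANCE_FLOOR)

    frac_e, frac_q = steady_fractions(traj, t_N)

    def _truncated(mu: float) -> float:
        for _ in range(1000):
            x = mu + rng.normal(0.0, sigma_alpha)
            if 0.0 <= x <= 1.0:
                return x
        raise RuntimeError("composition noise rejection failed")

    alpha_e = _truncated(frac_e)
    alpha_q = _truncated(frac_q)
    # keep the pair inside the simplex (noise sd is tiny; loop rarely repeats)
    while alpha_e + alpha_q > 1.0:
        alpha_e = _truncated(frac_e)
        alpha_q = _truncated(frac_q)
    return GrowthDataset(times=times, mean_mass=mean, variance=var,
                         n_replicates=n_replicates, alpha_e=alpha_e,
                         alpha_q=alpha_q, sigma_alpha_e=sigma_alpha,
                         sigma_alpha_q=sigma_alpha, t_N=t_N)


def generate_footprint(truth_rates: tuple[float, float] = (25.42, 0.05),
                       lattice_config=None,
                       params: MicroenvParams | None = None,
                       hyp: Hypothesis = Hypothesis.H2,
                       sampling_dt: float = 1.0 / 3.0,
                       horizon: float = 180.0,
                       noise_sd: float = 0.0,
                       seed: int | None = None,
                       replicate: int = 0) -> FootprintDataset:
    """Simulate a colony and emit its footprint-area series with noise.

    ``truth_rates`` are (lambda_agar, lambda_col) in 1/h.  Noise is additive
    Gaussian truncated at zero (areas cannot be negative).
    """
    from .spatial import LatticeConfig, simulate_colony

    if horizon > 180.0:
        raise ValueError("horizon exceeds the 7.5-day observation window")
    if lattice_config is None:
        lattice_config = LatticeConfig()
    lattice_config = lattice_config.replace(lambda_agar=truth_rates[0],
                                            lambda_col=truth_rates[1])
    if params is None:
        params, _ = default_truth_params()
    rng = np.random.default_rng(seed)
    times, areas, _ = simulate_colony(lattice_config, params, hyp,
                                      horizon=horizon, sample_dt=sampling_dt)
    if noise_sd > 0:
        noisy = areas + rng.normal(0.0, noise_sd, size=areas.size)
        areas = np.maximum(noisy, 0.0)
    return FootprintDataset(times=times, area_mm2=areas, replicate=replicate)
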