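"""Three-state metabolic growth model for budding yeast in homogeneous medium.

Cells are partitioned into a glucose-growing state (mass ``m_g``), an
ethanol-growing state (``m_e``) and a non-growing quiescent state (``m_q``);
the two nutrient pools are glucose ``g`` and ethanol ``e``.  Growth on glucose
produces ethanol as a by-product (diauxie); when glucose runs low, cells switch
to the ethanol state at rate ``beta1/(g + K)`` and may subsequently become
quiescent.  Three nested switching topologies are supported:

* ``H1`` — quiescence reachable from both the glucose and the ethanol state,
* ``H2`` — quiescence only via the ethanol state (``beta2 = 0``),
* ``H3`` — quiescence only directly from the glucose state (``beta3 = 0``).

The observable is the total cell mass ``m = m_g + m_e + m_q`` in OD-equivalent
units.  A respiratory-deficient (petite) strain is modelled by ``mu2 = 0``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "Hypothesis",
    "MicroenvParams",
    "MicroenvState",
    "MicroenvTrajectory",
    "IntegrationError",
    "microenv_rhs",
    "simulate_microenv",
    "total_mass",
    "steady_fractions",
    "params_from_vector",
    "vector_from_params",
    "param_names",
]

#: relative undershoot below which negative values are clamped to zero;
#: anything more negative aborts the integration as a model/solver error.
NEG_TOL = 1e-9


class Hypothesis(str, enum.Enum):
    """Metabolic switching topology (which quiescence routes are open)."""

    H1 = "H1"
    H2 = "H2"
    H3 = "H3"

    @property
    def allows_beta2(self) -> bool:
        return self in (Hypothesis.H1, Hypothesis.H3)

    @property
    def allows_beta3(self) -> bool:
        return self in (Hypothesis.H1, Hypothesis.H2)

    @property
    def n_free(self) -> int:
        """Dimension of the free log-parameter vector (incl. log m_g(0))."""
        return 8 + self.allows_beta2 + self.allows_beta3


# order of the shared log-parameters in a parameter vector
_SHARED = ("m_g0", "mu1", "beta1", "K", "mu2", "gamma1", "gamma2", "gamma3")


def param_names(hyp: Hypothesis) -> tuple[str, ...]:
    """Names of the free log-space coordinates under ``hyp``, in order."""
    hyp = Hypothesis(hyp)
    names = list(_SHARED)
    if hyp.allows_beta2:
        names.append("beta2")
    if hyp.allows_beta3:
        names.append("beta3")
    return tuple(names)


@dataclass(frozen=True)
class MicroenvParams:
    """Kinetic constants of the three-state model.

    Rates are per hour; ``K`` is in normalized glucose units; the yield
    parameters ``gamma1..gamma3`` are dimensionless mass/nutrient ratios.
    """

    mu1: float
    mu2: float
    beta1: float
    K: float
    beta2: float
    beta3: float
    gamma1: float
    gamma2: float
    gamma3: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        for name in ("mu1", "mu2", "beta1", "beta2", "beta3",
                     "gamma1", "gamma2", "gamma3"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.gamma1 <= 0 or self.gamma2 <= 0 or self.gamma3 <= 0:
            raise ValueError("yield parameters must be strictly positive")

    def for_hypothesis(self, hyp: Hypothesis) -> "MicroenvParams":
        """Return a copy with the hypothesis-forbidden rates zeroed."""
        hyp = Hypothesis(hyp)
        out = self
        if not hyp.allows_beta2:
            out = replace(out, beta2=0.0)
        if not hyp.allows_beta3:
            out = replace(out, beta3=0.0)
        return out

    def petite(self) -> "MicroenvParams":
        """Respiratory-deficient variant: no growth on ethanol (mu2 = 0)."""
        return replace(self, mu2=0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.beta1, self.K, self.beta2,
                         self.beta3, self.gamma1, self.gamma2, self.gamma3])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k) for k in
                       ("mu1", "mu2", "beta1", "K", "beta2", "beta3",
                        "gamma1", "gamma2", "gamma3")}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MicroenvParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class MicroenvState:
    """Masses in the three metabolic states plus the two nutrient levels."""

    m_g: float = 0.0
    m_e: float = 0.0
    m_q: float = 0.0
    g: float = 0.0
    e: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_g", "m_e", "m_q", "g", "e"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def total_mass(self) -> float:
        return self.m_g + self.m_e + self.m_q

    def as_array(self) -> np.ndarray:
        return np.array([self.m_g, self.m_e, self.m_q, self.g, self.e])


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last time with a valid state."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


def _rhs_arrays(y: np.ndarray, p: MicroenvParams) -> np.ndarray:
    """Model right-hand side; works on any broadcastable field arrays.

    ``y`` stacks (m_g, m_e, m_q, g, e) along axis 0.
    """
    m_g, m_e, m_q, g, e = y
    switch_ge = p.beta1 / (g + p.K) * m_g
    grow_g = p.mu1 * m_g * g
    grow_e = p.mu2 * m_e * e
    return np.stack([
        grow_g - switch_ge - p.beta2 * m_g,
        grow_e + switch_ge - p.beta3 * m_e,
        p.beta2 * m_g + p.beta3 * m_e,
        -grow_g / p.gamma1,
        grow_g / p.gamma2 - grow_e / p.gamma3,
    ])


def microenv_rhs(state: MicroenvState, params: MicroenvParams,
                 hyp: Hypothesis = Hypothesis.H1) -> MicroenvState:
    """Time derivative of the microenvironment state under ``hyp``.

    Returns the derivative packed in a ``MicroenvState``-shaped tuple-like
    object (fields may be negative, so a plain array is returned).
    """
    p = params.for_hypothesis(hyp)
    y = state.as_array()
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    return _rhs_arrays(y, p)


@dataclass
class MicroenvTrajectory:
    """Solution of the microenvironment ODEs on a time grid (hours)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 5): m_g, m_e, m_q, g, e
    params: MicroenvParams
    hypothesis: Hypothesis = Hypothesis.H1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must have shape (n_times, 5)")

    m_g = property(lambda self: self.states[:, 0])
    m_e = property(lambda self: self.states[:, 1])
    m_q = property(lambda self: self.states[:, 2])
    g = property(lambda self: self.states[:, 3])
    e = property(lambda self: self.states[:, 4])

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "time_h": self.times, "m_g": self.m_g, "m_e": self.m_e,
            "m_q": self.m_q, "g": self.g, "e": self.e,
            "m_total": total_mass(self),
        })
        df.to_csv(path, index=False)


def _clamp_negatives(y: np.ndarray, scale: float, context: str,
                     times: np.ndarray | None = None) -> np.ndarray:
    """Zero tiny integrator undershoots; abort on genuinely negative values."""
    tol = NEG_TOL * max(scale, 1.0)
    low = y.min()
    if low < -tol:
        t_bad = 0.0
        if times is not None:
            bad = np.any(y < -tol, axis=tuple(range(1, y.ndim)))
            first = int(np.argmax(bad))
            t_bad = float(times[first - 1]) if first > 0 else float(times[0])
        raise IntegrationError(
            f"{context}: negative component {low:.3e} exceeds tolerance",
            last_valid_time=t_bad)
    return np.where(y < 0, 0.0, y)


def simulate_microenv(params: MicroenvParams, init: MicroenvState,
                      times: np.ndarray,
                      hyp: Hypothesis = Hypothesis.H1,
                      rtol: float = 1e-8, atol: float = 1e-10,
                      ) -> MicroenvTrajectory:
    """Integrate the model with a stiff solver (LSODA) on ``times``.

    ``times`` must start at 0.  Small negative undershoots (relative size
    below 1e-9 of the initial total content) are clamped to zero.
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0")
    p = params.for_hypothesis(hyp)
    y0 = init.as_array()

    def rhs(y, t):
        return _rhs_arrays(y, p)

    sol, info = odeint(rhs, y0, times, rtol=rtol, atol=atol,
                       full_output=True, mxstep=100_000)
    if info["message"] != "Integration successful.":
        n_ok = int(np.searchsorted(times, info["tcur"][-1], side="right"))
        raise IntegrationError(
            f"LSODA failed: {info['message']}",
            last_valid_time=float(times[max(n_ok - 1, 0)]))
    scale = init.total_mass + init.g + init.e
    sol = _clamp_negatives(sol, scale, "simulate_microenv", times)
    return MicroenvTrajectory(times, sol, p, Hypothesis(hyp))


def total_mass(traj: MicroenvTrajectory) -> np.ndarray:
    """Total cell mass m = m_g + m_e + m_q, the experimentally observed curve."""
    return traj.states[:, :3].sum(axis=1)


def steady_fractions(traj: MicroenvTrajectory, t_N: float) -> tuple[float, float]:
    """Fractions of total mass in the ethanol and quiescent states at ``t_N``."""
    if not (traj.times[0] <= t_N <= traj.times[-1]):
        raise ValueError(f"t_N={t_N} outside trajectory span")
    m_e = float(np.interp(t_N, traj.times, traj.m_e))
    m_q = float(np.interp(t_N, traj.times, traj.m_q))
    m = float(np.interp(t_N, traj.times, total_mass(traj)))
    if m <= 0:
        raise ZeroDivisionError("total mass at t_N is zero; fractions undefined")
    return m_e / m, m_q / m


def params_from_vector(theta: np.ndarray, hyp: Hypothesis,
                       ) -> tuple[MicroenvParams, MicroenvState]:
    """Map a log-space free-parameter vector to kinetic constants + initial state.

    The vector holds logs of (m_g0, mu1, beta1, K, mu2, gamma1, gamma2,
    gamma3) followed by log beta2 and/or log beta3 where the hypothesis allows
    them.  The initial state fixes g(0) = 1 (normalized glucose) and
    e(0) = m_e(0) = m_q(0) = 0: cultures start in glucose-rich medium with all
    cells in the glucose state.
    """
    hyp = Hypothesis(hyp)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (hyp.n_free,):
        raise ValueError(
            f"{hyp.value} expects a vector of length {hyp.n_free}, "
            f"got shape {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("parameter vector must be finite")
    vals = np.exp(theta)
    m_g0, mu1, beta1, K, mu2, gamma1, gamma2, gamma3 = vals[:8]
    i = 8
    beta2 = beta3 = 0.0
    if hyp.allows_beta2:
        beta2 = vals[i]
        i += 1
    if hyp.allows_beta3:
        beta3 = vals[i]
    params = MicroenvParams(mu1=mu1, mu2=mu2, beta1=beta1, K=K, beta2=beta2,
                            beta3=beta3, gamma1=gamma1, gamma2=gamma2,
                            gamma3=gamma3)
    init = MicroenvState(m_g=m_g0, g=1.0)
    return params, init


def vector_from_params(params: MicroenvParams, m_g0: float,
                       hyp: Hypothesis) -> np.ndarray:
    """Inverse of :func:`params_from_vector` (log-space coordinates)."""
    hyp = Hypothesis(hyp)
    vals = [m_g0, params.mu1, params.beta1, params.K, params.mu2,
            params.gamma1, params.gamma2, params.gamma3]
    if hyp.allows_beta2:
        vals.append(params.beta2)
    if hyp.allows_beta3:
        vals.append(params.beta3)
    vals = np.asarray(vals, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("all free parameters must be strictly positive "
                         "to have a log-space representation")
    return np.log(vals)
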