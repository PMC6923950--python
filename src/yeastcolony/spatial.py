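"""Coarse-grained 3D lattice simulator for colony growth on an agar disc.

Space is discretized into elementary cubes (edge 0.1 mm).  Each cube holds a
locally homogeneous microenvironment — cell masses in the three metabolic
states plus glucose and ethanol — evolving under the growth/switching ODEs.
Cubes couple through two flux mechanisms:

* thresholded cell-mass movement: only mass exceeding the fill threshold
  ``th`` (interpreted as pressure) flows, from high to low thresholded total
  mass, carrying the donor cube's metabolic-state fractions along; movement
  into the agar is forbidden;
* nutrient transfer: linear fluxes between neighbouring cubes, with rate
  ``lambda_agar`` for agar-side edges and ``lambda_col`` inside the colony.
  Glucose moves over the union of the agar and the cell-bearing cubes;
  ethanol only over cubes with positive cell mass.

Both mechanisms are antisymmetric per cube pair, so transport conserves total
cell mass exactly and nutrients on closed domains.  Time stepping is explicit
Euler with dt = 0.0025 h.  The calibration observable is the colony footprint
area: the number of lattice columns holding any cell mass times the cube face
area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .microenv import Hypothesis, MicroenvParams

__all__ = [
    "LatticeConfig",
    "ColonyLattice",
    "thresholded_mass",
    "pairwise_mass_flux",
    "mass_movement_rhs",
    "nutrient_transfer_rhs",
    "local_reaction_rhs",
    "euler_step",
    "initialize_colony",
    "footprint_area",
    "simulate_colony",
]

NEG_TOL = 1e-9


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, transport rates, and stepping for the colony lattice.

    Defaults are test-scale: a 21 x 21 x (2 agar + 10 air) lattice with a
    reduced 2 mm agar disc.  The full experimental geometry (1 cm disc,
    101 x 101 footprint) is obtained by enlarging ``dims`` and
    ``disc_diameter_mm``.
    """

    dims: tuple[int, int, int] = (21, 21, 12)
    cube_edge: float = 0.1           # mm
    agar_layers: int = 2             # 0.2 mm agar thickness / cube edge
    th: float = 1.0                  # mass-movement threshold
    lambda_mass: float = 20.0        # 1/h
    lambda_agar: float = 25.42       # 1/h
    lambda_col: float = 0.05         # 1/h
    g0_agar: float = 1.0
    dt: float = 0.0025               # h
    disc_diameter_mm: float = 2.0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError("lattice dims must be >= 1")
        if self.agar_layers >= self.dims[2]:
            raise ValueError("agar layers must leave room for the colony")
        for name in ("cube_edge", "th", "lambda_mass", "lambda_agar",
                     "lambda_col", "g0_agar", "dt", "disc_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "LatticeConfig":
        return _dc_replace(self, **kw)


@dataclass
class ColonyLattice:
    """Per-cube cell-state masses and nutrient levels plus geometry masks."""

    m_g: np.ndarray
    m_e: np.ndarray
    m_q: np.ndarray
    g: np.ndarray
    e: np.ndarray
    agar: np.ndarray  # boolean mask of agar cubes
    config: LatticeConfig
    time: float = 0.0

    @property
    def total_mass(self) -> np.ndarray:
        return (self.m_g + self.m_e) + self.m_q

    def copy(self) -> "ColonyLattice":
        return ColonyLattice(self.m_g.copy(), self.m_e.copy(),
                             self.m_q.copy(), self.g.copy(), self.e.copy(),
                             self.agar, self.config, self.time)

    def to_hdf5_group(self, grp) -> None:
        for name in ("m_g", "m_e", "m_q", "g", "e"):
            grp.create_dataset(name, data=getattr(self, name))
        grp.attrs["time"] = self.time


def thresholded_mass(m, th: float):
    """Mass exceeding the fill threshold: ``max(m - th, 0)`` (the pressure)."""
    return np.maximum(m - th, 0.0)


def pairwise_mass_flux(m: float, m_nb: float, m_state: float,
                       m_state_nb: float, th: float) -> float:
    """Signed state-mass flux into the cube with totals (m, m_state).

    The donor is the cube with the larger thresholded total; the moving mass
    carries the donor's state fraction.  Zero-total donors contribute zero.
    """
    mth, mth_nb = thresholded_mass(m, th), thresholded_mass(m_nb, th)
    if mth == mth_nb:
        return 0.0
    if mth > mth_nb:  # this cube donates
        frac = m_state / m if m > 0 else 0.0
    else:             # neighbour donates
        frac = m_state_nb / m_nb if m_nb > 0 else 0.0
    return (mth_nb - mth) * frac


def _axis_state_flux(mth: np.ndarray, frac: np.ndarray, allowed: np.ndarray,
                     axis: int) -> np.ndarray:
    """Per-cube mass-movement derivative contributions along one axis.

    ``allowed`` marks cube pairs over which movement is permitted (both
    non-agar).  Returns the signed contribution array for this axis.
    """
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    lo, hi = tuple(lo), tuple(hi)
    a, b = mth[lo], mth[hi]
    d = b - a  # flow b -> a when positive
    donor_frac = np.where(d > 0, frac[hi], frac[lo])
    flux = d * donor_frac * allowed[lo] * allowed[hi]
    out = np.zeros_like(mth)
    out[lo] += flux
    out[hi] -= flux
    return out


def mass_movement_rhs(lattice: ColonyLattice) -> tuple[np.ndarray, ...]:
    """Thresholded mass-movement derivatives for (m_g, m_e, m_q).

    Movement into agar cubes is forbidden; missing neighbours at the domain
    boundary contribute zero flux (sealed dish).  The six per-axis sums are
    combined as (x + y) + z so a quarter-turn of a symmetric lattice yields
    bit-identical fields.
    """
    cfg = lattice.config
    m = lattice.total_mass
    mth = thresholded_mass(m, cfg.th)
    allowed = (~lattice.agar).astype(float)
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for field in (lattice.m_g, lattice.m_e, lattice.m_q):
            frac = np.where(m > 0, field / np.where(m > 0, m, 1.0), 0.0)
            dx = _axis_state_flux(mth, frac, allowed, 0)
            dy = _axis_state_flux(mth, frac, allowed, 1)
            dz = _axis_state_flux(mth, frac, allowed, 2)
            out.append(cfg.lambda_mass * ((dx + dy) + dz))
    return tuple(out)


def _edge_rates(cfg: LatticeConfig, axis: int, shape) -> np.ndarray:
    """Nutrient transfer rate per cube pair along ``axis``.

    The colony rate applies to edges lying strictly above the first
    cell-mass layer and to vertical edges leading up out of that layer; all
    edges touching the agar or lateral edges within the first layer use the
    agar rate.
    """
    h = cfg.agar_layers
    nk = shape[2]
    k = np.arange(nk)
    if axis == 2:
        lower = k[:-1]
        col = lower >= h           # vertical edge from first colony layer up
        rates_k = np.where(col, cfg.lambda_col, cfg.lambda_agar)
        return np.broadcast_to(rates_k, (shape[0], shape[1], nk - 1))
    col = k >= h + 1               # lateral edges above the first layer
    rates_k = np.where(col, cfg.lambda_col, cfg.lambda_agar)
    out_shape = list(shape)
    out_shape[axis] -= 1
    return np.broadcast_to(rates_k, tuple(out_shape))


def _axis_nutrient_flux(field: np.ndarray, domain: np.ndarray,
                        rates: np.ndarray, axis: int) -> np.ndarray:
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    lo, hi = tuple(lo), tuple(hi)
    active = domain[lo] * domain[hi]
    flux = rates * (field[hi] - field[lo]) * active
    out = np.zeros_like(field)
    out[lo] += flux
    out[hi] -= flux
    return out


def nutrient_transfer_rhs(field: np.ndarray, lattice: ColonyLattice,
                          which: str) -> np.ndarray:
    """Flux-based nutrient transfer derivative for ``which`` in {glucose, ethanol}.

    Glucose moves over the agar plus all cell-bearing cubes; ethanol moves
    over cell-bearing cubes only (never into the agar) at the colony rate.
    """
    cfg = lattice.config
    has_mass = lattice.total_mass > 0
    if which == "glucose":
        domain = (lattice.agar | has_mass).astype(float)
    elif which == "ethanol":
        domain = (has_mass & ~lattice.agar).astype(float)
    else:
        raise ValueError("which must be 'glucose' or 'ethanol'")
    parts = []
    for axis in range(3):
        if which == "glucose":
            rates = _edge_rates(cfg, axis, field.shape)
        else:
            rates = cfg.lambda_col
        parts.append(_axis_nutrient_flux(field, domain, rates, axis))
    return (parts[0] + parts[1]) + parts[2]


def local_reaction_rhs(lattice: ColonyLattice, params: MicroenvParams,
                       hyp: Hypothesis = Hypothesis.H2,
                       ) -> tuple[np.ndarray, ...]:
    """Microenvironment ODE right-hand side applied cube-wise.

    Cell-free cubes (all of the agar) have identically zero derivatives:
    every reaction term carries a cell-mass factor.
    """
    p = params.for_hypothesis(hyp)
    m_g, m_e, g, e = lattice.m_g, lattice.m_e, lattice.g, lattice.e
    switch = p.beta1 / (g + p.K) * m_g
    grow_g = p.mu1 * m_g * g
    grow_e = p.mu2 * m_e * e
    return (grow_g - switch - p.beta2 * m_g,
            grow_e + switch - p.beta3 * m_e,
            p.beta2 * m_g + p.beta3 * m_e,
            -grow_g / p.gamma1,
            grow_g / p.gamma2 - grow_e / p.gamma3)


class StabilityError(RuntimeError):
    """A field went significantly negative; reduce the Euler step."""


def euler_step(lattice: ColonyLattice, params: MicroenvParams,
               hyp: Hypothesis = Hypothesis.H2,
               transport: bool = True, reactions: bool = True,
               compiled: bool = False) -> ColonyLattice:
    """Advance the lattice by one explicit Euler step of length ``config.dt``.

    ``compiled=True`` routes the full (reaction + transport) derivative
    through the numba kernel used by :func:`simulate_colony`; the vectorized
    route below is the reference definition.
    """
    cfg = lattice.config
    if compiled:
        if not (transport and reactions):
            raise ValueError("compiled path always includes both terms")
        return _euler_step_compiled(lattice, params, hyp)
    dmg, dme, dmq, dg, de = (np.zeros_like(lattice.m_g) for _ in range(5))
    if reactions:
        r = local_reaction_rhs(lattice, params, hyp)
        dmg, dme, dmq, dg, de = (d + x for d, x in zip((dmg, dme, dmq, dg, de), r))
    if transport:
        tg, te, tq = mass_movement_rhs(lattice)
        dmg = dmg + tg
        dme = dme + te
        dmq = dmq + tq
        dg = dg + nutrient_transfer_rhs(lattice.g, lattice, "glucose")
        de = de + nutrient_transfer_rhs(lattice.e, lattice, "ethanol")
    dt = cfg.dt
    new = ColonyLattice(lattice.m_g + dt * dmg, lattice.m_e + dt * dme,
                        lattice.m_q + dt * dmq, lattice.g + dt * dg,
                        lattice.e + dt * de, lattice.agar, cfg,
                        lattice.time + dt)
    for name in ("m_g", "m_e", "m_q", "g", "e"):
        f = getattr(new, name)
        low = f.min()
        if low < -NEG_TOL:
            raise StabilityError(
                f"field {name} reached {low:.3e} at t={new.time:.4f} h; "
                "reduce dt")
        if low < 0:
            np.maximum(f, 0.0, out=f)
    return new


def _euler_step_compiled(lattice: ColonyLattice, params: MicroenvParams,
                         hyp: Hypothesis) -> ColonyLattice:
    from ._fastlattice import colony_derivatives

    cfg = lattice.config
    p = params.for_hypothesis(hyp)
    derivs = [np.empty_like(lattice.m_g) for _ in range(5)]
    colony_derivatives(lattice.m_g, lattice.m_e, lattice.m_q, lattice.g,
                       lattice.e, lattice.agar, cfg.th, cfg.lambda_mass,
                       cfg.lambda_agar, cfg.lambda_col, cfg.agar_layers,
                       p.mu1, p.mu2, p.beta1, p.K, p.beta2, p.beta3,
                       p.gamma1, p.gamma2, p.gamma3, *derivs)
    dt = cfg.dt
    fields = (lattice.m_g, lattice.m_e, lattice.m_q, lattice.g, lattice.e)
    new_fields = []
    for name, f, d in zip(("m_g", "m_e", "m_q", "g", "e"), fields, derivs):
        nf = f + dt * d
        low = nf.min()
        if low < -NEG_TOL:
            raise StabilityError(
                f"field {name} reached {low:.3e} at t="
                f"{lattice.time + dt:.4f} h; reduce dt")
        if low < 0:
            np.maximum(nf, 0.0, out=nf)
        new_fields.append(nf)
    return ColonyLattice(*new_fields, lattice.agar, cfg, lattice.time + dt)


def initialize_colony(config: LatticeConfig) -> ColonyLattice:
    """Agar disc filled with glucose plus one seeded cube at the centre.

    The agar occupies the bottom ``agar_layers`` layers inside the disc
    footprint at glucose level ``g0_agar``.  One cube directly above the agar
    at the lattice centre starts with cell mass ``th`` in the glucose state
    and local glucose level 1.
    """
    ni, nj, nk = config.dims
    radius_cubes = config.disc_diameter_mm / 2.0 / config.cube_edge
    ci, cj = (ni - 1) / 2.0, (nj - 1) / 2.0
    if radius_cubes > min(ci, cj) + 0.5 + 1e-12:
        raise ValueError("agar disc does not fit in the lattice footprint")
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    disc = (ii - ci) ** 2 + (jj - cj) ** 2 <= radius_cubes ** 2
    agar = np.zeros(config.dims, dtype=bool)
    agar[:, :, :config.agar_layers] = disc[:, :, None]
    zeros = np.zeros(config.dims)
    g = np.where(agar, config.g0_agar, 0.0)
    lat = ColonyLattice(zeros.copy(), zeros.copy(), zeros.copy(), g,
                        zeros.copy(), agar, config)
    k_seed = config.agar_layers
    i_seed, j_seed = int(round(ci)), int(round(cj))
    lat.m_g[i_seed, j_seed, k_seed] = config.th
    lat.g[i_seed, j_seed, k_seed] = 1.0
    return lat


def footprint_area(lattice: ColonyLattice) -> float:
    """Area (mm^2) of lattice columns holding any above-agar cell mass."""
    above = lattice.total_mass[:, :, lattice.config.agar_layers:]
    cols = np.any(above > 0, axis=2)
    return float(cols.sum()) * lattice.config.cube_edge ** 2


def simulate_colony(config: LatticeConfig, params: MicroenvParams,
                    hyp: Hypothesis = Hypothesis.H2,
                    horizon: float = 48.0, sample_dt: float = 1.0,
                    snapshot_times: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, list[ColonyLattice]]:
    """Euler loop with footprint sampling and optional lattice snapshots.

    Returns ``(times, areas_mm2, snapshots)`` where ``times`` runs from 0 to
    ``horizon`` in steps of ``sample_dt``.
    """
    n_steps_per_sample = round(sample_dt / config.dt)
    if abs(n_steps_per_sample * config.dt - sample_dt) > 1e-9:
        raise ValueError("sample_dt must be a multiple of dt")
    n_samples = round(horizon / sample_dt)
    if abs(n_samples * sample_dt - horizon) > 1e-9:
        raise ValueError("horizon must be a multiple of sample_dt")
    lat = initialize_colony(config)
    times = np.arange(n_samples + 1) * sample_dt
    areas = np.empty(n_samples + 1)
    areas[0] = footprint_area(lat)
    snaps: list[ColonyLattice] = []
    want = set()
    if snapshot_times is not None:
        want = {round(float(t) / sample_dt) for t in snapshot_times}
    if 0 in want:
        snaps.append(lat.copy())
    from ._fastlattice import advance

    p = params.for_hypothesis(hyp)
    for s in range(1, n_samples + 1):
        done = advance(lat.m_g, lat.m_e, lat.m_q, lat.g, lat.e, lat.agar,
                       n_steps_per_sample, config.dt, NEG_TOL, config.th,
                       config.lambda_mass, config.lambda_agar,
                       config.lambda_col, config.agar_layers, p.mu1, p.mu2,
                       p.beta1, p.K, p.beta2, p.beta3, p.gamma1, p.gamma2,
                       p.gamma3)
        lat.time += done * config.dt
        if done < n_steps_per_sample:
            raise StabilityError(
                f"field went negative beyond tolerance at t={lat.time:.4f} h;"
                " reduce dt")
        areas[s] = footprint_area(lat)
        if s in want:
            snaps.append(lat.copy())
    return times, areas, snaps
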