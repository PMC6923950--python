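"""Tests for the coarse-grained lattice colony simulator."""

import numpy as np
import pytest

from yeastcolony import (Hypothesis, LatticeConfig, euler_step,
                         footprint_area, initialize_colony,
                         local_reaction_rhs, mass_movement_rhs,
                         nutrient_transfer_rhs, pairwise_mass_flux,
                         simulate_colony, simulate_microenv, thresholded_mass)
from yeastcolony.spatial import StabilityError, _euler_step_compiled

from conftest import random_colony


class TestThresholding:
    @pytest.mark.parametrize("m,th,expected", [(0.5, 1.0, 0.0),
                                               (1.0, 1.0, 0.0),
                                               (2.5, 1.0, 1.5)])
    def test_values(self, m, th, expected):
        assert thresholded_mass(m, th) == expected

    def test_pairwise_flux_equal_levels_zero(self):
        assert pairwise_mass_flux(1.2, 1.2, 0.6, 0.3, 1.0) == 0.0
        # both below threshold: zero even though totals differ
        assert pairwise_mass_flux(0.9, 0.2, 0.9, 0.2, 1.0) == 0.0

    def test_pairwise_flux_donor_branch(self):
        # donor at total 2 (thresholded 1), state fraction 1/2, empty
        # neighbour: donor's state equation loses 0.5
        f = pairwise_mass_flux(2.0, 0.0, 1.0, 0.0, 1.0)
        assert f == pytest.approx(-0.5)

    def test_pairwise_flux_antisymmetric(self, rng):
        for _ in range(50):
            m, m_nb = rng.random(2) * 3
            ms = rng.random() * m
            ms_nb = rng.random() * m_nb
            f = pairwise_mass_flux(m, m_nb, ms, ms_nb, 1.0)
            g = pairwise_mass_flux(m_nb, m, ms_nb, ms, 1.0)
            assert f == pytest.approx(-g, abs=1e-15)

    def test_zero_mass_donor_convention(self):
        assert pairwise_mass_flux(0.0, 0.0, 0.0, 0.0, 1.0) == 0.0


class TestMassMovement:
    def test_uniform_field_no_movement(self, small_lattice_config):
        lat = initialize_colony(small_lattice_config)
        lat.m_g[:, :, 2:] = 2.0
        lat.m_g[:, :, :2] = 0.0
        d = mass_movement_rhs(lat)
        # interior is uniform; only the agar boundary blocks columns differ
        assert np.allclose(d[0][:, :, 3:-1], 0.0)

    def test_total_mass_conserved(self, small_lattice_config, rng):
        lat = random_colony(small_lattice_config, rng)
        d = mass_movement_rhs(lat)
        total = sum(f.sum() for f in d)
        scale = lat.total_mass.sum()
        assert abs(total) <= 1e-12 * scale

    def test_single_spilling_cube_spreads_symmetrically(
            self, small_lattice_config):
        lat = initialize_colony(small_lattice_config)
        i = j = 5
        k = small_lattice_config.agar_layers
        lat.m_g[i, j, k] = 2.0 * small_lattice_config.th
        d = mass_movement_rhs(lat)[0]
        lam = small_lattice_config.lambda_mass
        # thresholded excess th, donor fraction 1: each of the 4 lateral
        # + 1 upward neighbours receives lam * th
        flux = lam * small_lattice_config.th
        assert d[i, j, k] == pytest.approx(-5 * flux)
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1)):
            assert d[i + di, j + dj, k + dk] == pytest.approx(flux)
        assert d[i, j, k - 1] == 0.0  # no invasion of the agar


class TestNutrientTransfer:
    def test_uniform_connected_domain_zero(self, small_lattice_config):
        lat = initialize_colony(small_lattice_config)
        lat.g[:] = 0.7
        lat.m_g[:, :, 2] = 0.5  # cover the whole layer above the agar
        d = nutrient_transfer_rhs(lat.g, lat, "glucose")
        dom = lat.agar | (lat.total_mass > 0)
        assert np.allclose(d[dom], 0.0)

    def test_closed_domain_conservation(self, small_lattice_config, rng):
        lat = random_colony(small_lattice_config, rng)
        for which, field in (("glucose", lat.g), ("ethanol", lat.e)):
            d = nutrient_transfer_rhs(field, lat, which)
            assert abs(d.sum()) <= 1e-12 * max(field.sum(), 1.0)

    def test_two_cube_agar_rate(self):
        # two agar cubes with glucose (1, 0): the donor drains at the
        # fitted agar transfer rate
        from yeastcolony.spatial import ColonyLattice

        cfg = LatticeConfig(dims=(2, 1, 3), agar_layers=2,
                            disc_diameter_mm=0.1, lambda_agar=25.42)
        zeros = np.zeros(cfg.dims)
        agar = np.zeros(cfg.dims, dtype=bool)
        agar[:, :, 0] = True
        g = np.zeros(cfg.dims)
        g[0, 0, 0] = 1.0
        lat = ColonyLattice(zeros.copy(), zeros.copy(), zeros.copy(), g,
                            zeros.copy(), agar, cfg)
        d = nutrient_transfer_rhs(lat.g, lat, "glucose")
        assert d[0, 0, 0] == pytest.approx(-25.42)
        assert d[1, 0, 0] == pytest.approx(25.42)

    def test_ethanol_confined_to_colony(self, small_lattice_config):
        lat = initialize_colony(small_lattice_config)
        k = small_lattice_config.agar_layers
        lat.e[5, 5, k] = 1.0
        d = nutrient_transfer_rhs(lat.e, lat, "ethanol")
        # single-cube colony: no neighbour with cell mass, nothing moves
        assert np.allclose(d, 0.0)


class TestReactionsAndStepping:
    def test_cell_free_cube_inert(self, small_lattice_config, truth):
        params, _ = truth
        lat = initialize_colony(small_lattice_config)
        d = local_reaction_rhs(lat, params, Hypothesis.H2)
        agar = lat.agar
        for arr in d:
            assert np.allclose(arr[agar], 0.0)

    def test_single_cube_reduces_to_microenv(self, truth):
        params, _ = truth
        cfg = LatticeConfig(dims=(1, 1, 2), agar_layers=1, dt=0.0025,
                            disc_diameter_mm=0.1, lambda_agar=1e-12,
                            lambda_col=1e-12)
        lat = initialize_colony(cfg)
        n_steps = 2000  # 5 h
        for _ in range(n_steps):
            lat = euler_step(lat, params, Hypothesis.H2)
        times = np.array([0.0, n_steps * cfg.dt])
        from yeastcolony.microenv import MicroenvState
        ref = simulate_microenv(params, MicroenvState(m_g=cfg.th, g=1.0),
                                times, Hypothesis.H2)
        k = cfg.agar_layers
        got = np.array([lat.m_g[0, 0, k], lat.m_e[0, 0, k],
                        lat.m_q[0, 0, k], lat.g[0, 0, k], lat.e[0, 0, k]])
        assert np.allclose(got, ref.states[-1], rtol=1e-2, atol=1e-4)

    def test_zero_lattice_fixed_point(self, small_lattice_config, truth):
        params, _ = truth
        lat = initialize_colony(small_lattice_config)
        lat.m_g[:] = 0.0
        lat.g[:] = 0.0
        new = euler_step(lat, params, Hypothesis.H2)
        for name in ("m_g", "m_e", "m_q", "g", "e"):
            assert np.all(getattr(new, name) == 0.0)

    def test_transport_only_step_conserves_mass(self, small_lattice_config,
                                                rng):
        params = _any_params()
        lat = random_colony(small_lattice_config, rng)
        before = lat.total_mass.sum()
        new = euler_step(lat, params, Hypothesis.H2, reactions=False)
        after = new.total_mass.sum()
        assert abs(after - before) <= 1e-12 * before

    def test_euler_convergence_order(self, small_lattice_config, truth,
                                     rng):
        # Richardson-style check: halving the step roughly halves the
        # one-interval discrepancy, the signature of a first-order scheme
        params, _ = truth

        def run(dt, n):
            cfg = small_lattice_config.replace(dt=dt)
            lat = random_colony(cfg, np.random.default_rng(7), fill=1.5)
            for _ in range(n):
                lat = euler_step(lat, params, Hypothesis.H2)
            return lat.m_g

        base_dt = small_lattice_config.dt
        d1 = np.abs(run(base_dt, 1) - run(base_dt / 2, 2)).max()
        d2 = np.abs(run(base_dt / 2, 2) - run(base_dt / 4, 4)).max()
        assert d1 > 0 and 1.3 < d1 / d2 < 3.5

    def test_compiled_step_matches_reference(self, small_lattice_config,
                                             rng, truth):
        params, _ = truth
        lat = random_colony(small_lattice_config, rng)
        a = euler_step(lat, params, Hypothesis.H2)
        b = _euler_step_compiled(lat, params, Hypothesis.H2)
        for name in ("m_g", "m_e", "m_q", "g", "e"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_unstable_step_raises(self, small_lattice_config, truth, rng):
        params, _ = truth
        cfg = small_lattice_config.replace(dt=1.0, lambda_agar=75.0)
        lat = initialize_colony(cfg)
        lat.g[lat.agar] = rng.integers(0, 2, lat.agar.sum()).astype(float)
        with pytest.raises(StabilityError):
            euler_step(lat, params, Hypothesis.H2)


def _any_params():
    from yeastcolony.synthdata import default_truth_params

    return default_truth_params()[0]


class TestInitialization:
    def test_geometry(self):
        cfg = LatticeConfig()  # 0.2 mm agar / 0.1 mm cubes -> 2 layers
        assert cfg.agar_layers == 2
        lat = initialize_colony(cfg)
        assert lat.agar[:, :, :2].sum() == lat.agar.sum()
        k = cfg.agar_layers
        assert lat.m_g[10, 10, k] == cfg.th == 1.0
        assert lat.total_mass.sum() == cfg.th
        assert lat.g[10, 10, k] == 1.0
        assert np.all(lat.g[lat.agar] == cfg.g0_agar)

    def test_footprint_area_fresh_and_empty(self):
        cfg = LatticeConfig()
        lat = initialize_colony(cfg)
        assert footprint_area(lat) == pytest.approx(0.01)
        lat.m_g[:] = 0.0
        assert footprint_area(lat) == 0.0

    def test_oversized_disc_rejected(self):
        with pytest.raises(ValueError):
            initialize_colony(LatticeConfig(dims=(5, 5, 4),
                                            disc_diameter_mm=2.0))


class TestColonySimulation:
    def test_footprint_grows_monotonically(self, small_lattice_config,
                                           truth):
        params, _ = truth
        times, areas, _ = simulate_colony(small_lattice_config, params,
                                          Hypothesis.H2, horizon=12.0,
                                          sample_dt=1.0)
        assert np.all(np.diff(areas) >= 0.0)
        assert areas[-1] > areas[0]

    def test_rotational_symmetry(self, small_lattice_config, truth):
        params, _ = truth
        _, _, snaps = simulate_colony(small_lattice_config, params,
                                      Hypothesis.H2, horizon=8.0,
                                      sample_dt=2.0,
                                      snapshot_times=[4.0, 8.0])
        for lat in snaps:
            for name in ("m_g", "m_e", "m_q", "g", "e"):
                f = getattr(lat, name)
                assert np.array_equal(f, np.rot90(f, axes=(0, 1)))

    def test_petite_grows_less(self, small_lattice_config, truth):
        params, _ = truth
        _, _, wt = simulate_colony(small_lattice_config, params,
                                   Hypothesis.H2, horizon=16.0,
                                   sample_dt=4.0, snapshot_times=[16.0])
        _, _, pet = simulate_colony(small_lattice_config, params.petite(),
                                    Hypothesis.H2, horizon=16.0,
                                    sample_dt=4.0, snapshot_times=[16.0])
        assert pet[0].total_mass.sum() <= wt[0].total_mass.sum()

    def test_no_agar_invasion(self, small_lattice_config, truth):
        params, _ = truth
        _, _, snaps = simulate_colony(small_lattice_config, params,
                                      Hypothesis.H2, horizon=10.0,
                                      sample_dt=5.0,
                                      snapshot_times=[5.0, 10.0])
        for lat in snaps:
            assert np.all(lat.total_mass[lat.agar] == 0.0)
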