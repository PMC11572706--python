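"""Metadynamics: hill deposition, reflection images, heights, exchange."""

import math

import numpy as np
import pytest

from colvarkit.engine import make_rng
from colvarkit.grids import Grid
from colvarkit.metad import (EbmetadSpec, HillSpec, MetadState,
                             bias_exchange_attempt, deposit_hill,
                             ebmetad_height, metad_force,
                             well_tempered_height)
from colvarkit.units import BOLTZMANN_KCAL_MOL_K as KB


def make_state(reflecting=False, lo=0.0, hi=10.0, bins=100, sigma=0.2,
               height=0.01):
    return MetadState(Grid.make([lo], [hi], [bins]), sigmas=[sigma],
                      height=height, reflecting=reflecting)


class TestDeposit:
    def test_interior_hill_no_images(self):
        st = make_state(reflecting=True)
        images = deposit_hill(st, [5.0])
        assert images == []
        assert len(st.hill_log) == 1

    def test_hill_near_lower_boundary_mirrored(self):
        st = make_state(reflecting=True)
        images = deposit_hill(st, [0.5])
        assert len(images) == 1
        img = images[0]
        assert img.center[0] == pytest.approx(-0.5)  # 2*lo - x_c
        assert img.height == st.height
        assert img.sigmas[0] == st.sigmas[0]
        assert img.image

    def test_corner_hill_three_images_2d(self):
        st = MetadState(Grid.make([0, 0], [10, 10], [50, 50]),
                        sigmas=[0.2, 0.2], height=0.01, reflecting=True)
        images = deposit_hill(st, [0.4, 0.3])
        centers = sorted(tuple(np.round(i.center, 6)) for i in images)
        assert len(images) == 3
        assert centers == [(-0.4, -0.3), (-0.4, 0.3), (0.4, -0.3)]

    def test_no_reflection_when_disabled(self):
        st = make_state(reflecting=False)
        assert deposit_hill(st, [0.1]) == []

    def test_outside_center_rejected(self):
        st = make_state()
        with pytest.raises(ValueError):
            deposit_hill(st, [11.0])

    def test_grid_projection_matches_analytic_hill_sum(self, rng):
        """Total projected bias equals the exact sum of Gaussians at grid
        nodes (within the 6-sigma truncation)."""
        st = make_state(sigma=0.5, height=0.3)
        centers = rng.uniform(3.0, 7.0, 5)
        for c in centers:
            deposit_hill(st, [c])
        x = st.grid.centers(0)
        analytic = sum(0.3 * np.exp(-0.5 * ((x - c) / 0.5) ** 2)
                       for c in centers)
        assert np.allclose(st.potential, analytic, atol=0.3 * math.exp(-18.0) * 10)


class TestForce:
    def test_energy_at_isolated_hill_center(self):
        st = make_state(sigma=0.5, height=0.2)
        deposit_hill(st, [5.0])
        e, f = metad_force(st, [5.0])
        assert e == pytest.approx(0.2, rel=1e-2)  # interpolation tolerance
        assert f[0] == pytest.approx(0.0, abs=1e-6)

    def test_interior_matches_closed_form(self):
        st = make_state(sigma=0.5, height=0.2, bins=500)
        deposit_hill(st, [5.013])  # off-node center
        for z in (4.3, 5.2, 6.1):
            e, f = metad_force(st, [z])
            hill = HillSpec([5.013], [0.5], 0.2)
            assert e == pytest.approx(hill.energy([z]), rel=1e-3, abs=1e-5)
            assert f[0] == pytest.approx(-hill.gradient([z])[0],
                                         rel=1e-2, abs=1e-4)

    def test_outside_boundary_force_zero_potential_frozen(self):
        st = make_state(sigma=0.5, height=0.2)
        deposit_hill(st, [9.5])
        e_b, _ = metad_force(st, [10.0])
        e_out, f_out = metad_force(st, [11.0])
        assert f_out[0] == 0.0
        assert e_out == pytest.approx(e_b)


class TestWellTempered:
    def test_zero_bias_full_height(self):
        assert well_tempered_height(0.1, 0.0, 1000.0, KB) == 0.1

    def test_one_kbdt_gives_w0_over_e(self):
        dT = 1500.0
        w = well_tempered_height(0.1, KB * dT, dT, KB)
        assert w == pytest.approx(0.1 / math.e)

    def test_infinite_delta_t_recovers_standard(self):
        w = well_tempered_height(0.1, 5.0, 1e12, KB)
        assert w == pytest.approx(0.1, rel=1e-6)
        assert well_tempered_height(0.1, 5.0, None, KB) == 0.1


class TestEbmetad:
    def _uniform(self, length=4.0, bins=40):
        grid = Grid.make([0.0], [length], [bins])
        rho = np.full(bins, 1.0 / length)
        return EbmetadSpec(grid, rho)

    def test_uniform_target_scaling_is_identity(self):
        spec = self._uniform()
        # S = ln L, rho = 1/L -> e^S rho = 1
        assert spec.entropy == pytest.approx(math.log(4.0))
        assert ebmetad_height(0.05, spec, [1.7]) == pytest.approx(0.05)

    def test_gaussian_target_height_ratio(self):
        grid = Grid.make([-6.0], [6.0], [1200])
        c = grid.centers(0)
        rho = np.exp(-c ** 2 / 2.0) / math.sqrt(2 * math.pi)
        rho /= rho.sum() * grid.widths[0]
        spec = EbmetadSpec(grid, rho)
        z0 = c[np.argmin(np.abs(c))]
        z1 = c[np.argmin(np.abs(c - 1.0))]
        ratio = (ebmetad_height(1.0, spec, [z1])
                 / ebmetad_height(1.0, spec, [z0]))
        assert ratio == pytest.approx(math.exp((z1**2 - z0**2) / 2), rel=1e-6)

    def test_entropy_converges_under_refinement(self):
        vals = []
        for bins in (100, 400, 1600):
            grid = Grid.make([-6.0], [6.0], [bins])
            c = grid.centers(0)
            rho = np.exp(-c ** 2 / 2.0)
            rho /= rho.sum() * grid.widths[0]
            vals.append(EbmetadSpec(grid, rho).entropy)
        truth = 0.5 * math.log(2 * math.pi * math.e)  # Gaussian entropy
        assert abs(vals[2] - truth) < 1e-4
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])

    def test_zero_density_deposition_rejected(self):
        grid = Grid.make([0.0], [1.0], [10])
        rho = np.zeros(10)
        rho[:5] = 2.0
        spec = EbmetadSpec(grid, rho)
        with pytest.raises(ValueError, match="target density is zero"):
            ebmetad_height(0.1, spec, [0.95])

    def test_unnormalized_target_rejected(self):
        grid = Grid.make([0.0], [1.0], [10])
        with pytest.raises(ValueError, match="integrates"):
            EbmetadSpec(grid, np.ones(10) * 3.0)


class TestBiasExchange:
    def _state_with_hill(self, center, height):
        st = make_state(lo=-5.0, hi=5.0, sigma=1.0, height=height, bins=100)
        deposit_hill(st, [center])
        return st

    def test_identical_always_accepts(self):
        a = self._state_with_hill(0.0, 0.1)
        b = self._state_with_hill(0.0, 0.1)
        beta = 1.0 / (KB * 300.0)
        assert bias_exchange_attempt(a, [1.0], b, [1.0], beta, make_rng(0))

    def test_negative_delta_always_accepts(self):
        # V_a(x_a)=1, V_b(x_b)=2, cross terms ~0 -> delta = -3 < 0
        a = self._state_with_hill(-4.0, 1.0)
        b = self._state_with_hill(4.0, 2.0)
        beta = 1.0 / (KB * 300.0)
        for seed in range(10):
            assert bias_exchange_attempt(a, [-4.0], b, [4.0], beta,
                                         make_rng(seed))

    def test_acceptance_frequency_matches_boltzmann(self):
        """Fixed positive delta: long-run acceptance ~ exp(-beta delta)."""
        beta = 1.0 / (KB * 300.0)
        delta = 0.5  # kcal/mol
        # engineer V_a(x_b) = delta, others 0, using one tall narrow hill
        a = make_state(lo=-5.0, hi=5.0, sigma=0.4, height=delta, bins=400)
        deposit_hill(a, [2.0])
        b = make_state(lo=-5.0, hi=5.0, sigma=0.4, height=delta, bins=400)
        x_a, x_b = [-4.5], [2.0]
        e = metad_force(a, x_b)[0]
        p_expect = math.exp(-beta * e)
        rng = make_rng(123)
        n = 4000
        acc = sum(bias_exchange_attempt(a, x_a, b, x_b, beta, rng)
                  for _ in range(n))
        se = math.sqrt(p_expect * (1 - p_expect) / n)
        assert acc / n == pytest.approx(p_expect, abs=4 * se)


class TestMultipleWalkers:
    def test_shared_hill_log_replayed_by_other_walkers(self):
        """Two walkers on a shared hill log end up with (nearly) the same
        bias: each replays the other's deposits."""
        from colvarkit.engine import EngineParams, Simulation, SystemState
        from colvarkit.geometry import AtomGroup, DistanceZ
        from colvarkit.metad import MetadBias
        from colvarkit.potentials import PotentialSpec

        shared = []

        def walker(i):
            pot = PotentialSpec("double_well_1d", {"h": 2.0})
            params = EngineParams(temperature=300.0, friction=20.0,
                                  timestep=1.0, seed=50)
            st = SystemState(np.array([[(-1.0) ** i, 0.0, 0.0]]),
                             np.zeros((1, 3)), [1.0])
            cv = DistanceZ(AtomGroup([0]), axis=(1, 0, 0))
            ms = make_state(lo=-1.7, hi=1.7, bins=68, sigma=0.15,
                            height=0.05)
            mb = MetadBias([0], ms, period=100, replica_id=i,
                           shared_log=shared)
            return Simulation(pot, params, st, colvars=[cv], biases=[mb]), mb

        (sim_a, mb_a), (sim_b, mb_b) = walker(0), walker(1)
        for _ in range(30):
            sim_a.run(100)
            sim_b.run(100)
        # force one final replay on both
        mb_a._replay_shared()
        mb_b._replay_shared()
        assert len(shared) > 10
        assert np.allclose(mb_a.state.potential, mb_b.state.potential,
                           atol=1e-12)
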