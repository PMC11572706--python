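"""Engine tests: potentials, BAOA integrator, extended variables, walkers."""

import math

import numpy as np
import pytest

from colvarkit.engine import (EngineParams, ExtendedVariable, Simulation,
                              SystemState, baoa_step, baoa_step_extended,
                              make_rng, reflect_bounds, rng_state,
                              run_walkers, set_rng_state)
from colvarkit.potentials import PotentialSpec, evaluate_potential
from colvarkit.units import ACC_KCAL_PER_AMU_A, BOLTZMANN_KCAL_MOL_K as KB


class TestPotentials:
    def test_harmonic_minimum(self):
        res = evaluate_potential(PotentialSpec("harmonic_well", {"k": 1.0}),
                                 np.zeros((1, 3)))
        assert res.energy == 0.0
        assert np.all(res.forces == 0.0)

    def test_double_well_stationary_at_origin(self):
        res = evaluate_potential(PotentialSpec("double_well_1d", {"h": 2.0}),
                                 np.zeros((1, 3)))
        assert res.energy == pytest.approx(2.0)
        assert np.all(res.forces == 0.0)

    @pytest.mark.parametrize("kind,params,lam", [
        ("harmonic_well", {"k": 1.7}, None),
        ("double_well_1d", {"h": 2.0}, None),
        ("rugged_2d", {"a": 0.5, "b": 1.0}, None),
        ("lambda_coupled_dual_harmonic", {"k_a": 1.0, "k_b": 4.0}, 0.3),
        ("flat_with_walls", {"lo": 0.0, "hi": 2.0, "k_wall": 50.0}, None),
    ])
    def test_forces_match_finite_differences(self, kind, params, lam, rng):
        spec = PotentialSpec(kind, params)
        pos = rng.normal(size=(1, 3)) * 2.0 + 0.1
        res = evaluate_potential(spec, pos, lam)
        h = 1e-6
        for k in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[0, k] += h
            pm[0, k] -= h
            fd = -(evaluate_potential(spec, pp, lam).energy
                   - evaluate_potential(spec, pm, lam).energy) / (2 * h)
            assert res.forces[0, k] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_lambda_coupling_interpolates_and_differentiates(self):
        spec = PotentialSpec("lambda_coupled_dual_harmonic",
                             {"k_a": 1.0, "k_b": 4.0})
        pos = np.array([[0.7, 0.0, 0.0]])
        h = 1e-7
        for lam in (0.2, 0.5, 0.9):
            res = evaluate_potential(spec, pos, lam)
            ua = evaluate_potential(spec, pos, 0.0).energy
            ub = evaluate_potential(spec, pos, 1.0).energy
            assert res.energy == pytest.approx((1 - lam) * ua + lam * ub)
            fd = (evaluate_potential(spec, pos, lam + h).energy
                  - evaluate_potential(spec, pos, lam - h).energy) / (2 * h)
            assert res.dU_dlambda == pytest.approx(fd, rel=1e-6)

    def test_lambda_validation(self):
        spec = PotentialSpec("lambda_coupled_dual_harmonic", {})
        with pytest.raises(ValueError):
            evaluate_potential(spec, np.zeros((1, 3)))
        with pytest.raises(ValueError):
            evaluate_potential(spec, np.zeros((1, 3)), 1.2)
        with pytest.raises(ValueError):
            evaluate_potential(PotentialSpec("harmonic_well"),
                               np.zeros((1, 3)), 0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PotentialSpec("lennard_jones")


class TestBaoa:
    def test_ballistic_drift_limit(self):
        state = SystemState(np.zeros((1, 3)), np.array([[0.1, -0.2, 0.3]]),
                            [2.0])
        params = EngineParams(temperature=0.0, friction=0.0, timestep=2.0)
        baoa_step(state, params, np.zeros((1, 3)), make_rng(0))
        assert np.allclose(state.positions, 2.0 * np.array([[0.1, -0.2, 0.3]]))

    def test_determinism_same_seed(self):
        def traj(seed):
            st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)), [1.0])
            params = EngineParams(seed=seed)
            rng = make_rng(seed)
            out = []
            for _ in range(100):
                baoa_step(st, params, -st.positions, rng)
                out.append(st.positions.copy())
            return np.array(out)
        assert np.array_equal(traj(5), traj(5))
        assert not np.array_equal(traj(5), traj(6))

    def test_nonfinite_force_rejected(self):
        st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)), [1.0])
        with pytest.raises(ValueError):
            baoa_step(st, EngineParams(), np.full((1, 3), np.nan), make_rng(0))

    def test_energy_conservation_deterministic_part(self):
        """friction = 0, T = 0: secular total-energy drift on the double
        well stays far below the well depth over 1e4 steps."""
        h = 2.0
        spec = PotentialSpec("double_well_1d", {"h": h})
        st = SystemState(np.array([[0.5, 0.0, 0.0]]),
                         np.array([[0.01, 0.0, 0.0]]), [12.0])
        params = EngineParams(temperature=0.0, friction=0.0, timestep=1.0)
        rng = make_rng(0)
        energies = []
        for _ in range(10_000):
            res = evaluate_potential(spec, st.positions)
            v_before = st.velocities.copy()
            baoa_step(st, params, res.forces, rng)
            # on-step velocity: the kick-drift splitting stores velocities a
            # half step off the positions, so average around the update
            v_mid = 0.5 * (v_before + st.velocities)
            kinetic = 0.5 * float(np.sum(st.masses[:, None]
                                         * v_mid ** 2)) / ACC_KCAL_PER_AMU_A
            energies.append(res.energy + kinetic)
        energies = np.array(energies)
        drift = abs(energies[-1000:].mean() - energies[:1000].mean())
        assert drift < 1e-4 * h

    def test_harmonic_equipartition(self):
        """Configurational variance of a thermalized harmonic oscillator
        matches kT/k within 2% over 1e6 steps (k = 1 kcal/mol/A^2, 300 K)."""
        k = 1.0
        params = EngineParams(temperature=300.0, friction=65.0, timestep=0.5,
                              seed=2024)
        st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)), [0.1])
        rng = make_rng(params.seed)
        n = 1_000_000
        acc = 0.0
        acc2 = 0.0
        for i in range(n):
            baoa_step(st, params, -k * st.positions, rng)
            x = st.positions[0, 0]
            acc += x
            acc2 += x * x
        var = acc2 / n - (acc / n) ** 2
        assert var == pytest.approx(KB * 300.0 / k, rel=0.02)


class TestExtendedVariable:
    def test_reflection_cases(self):
        v = ExtendedVariable(1.1, velocity=0.5, lower_bound=0.0,
                             upper_bound=1.0, reflecting_lower=True,
                             reflecting_upper=True)
        reflect_bounds(v)
        assert v.value == pytest.approx(0.9)
        assert v.velocity == -0.5

        v = ExtendedVariable(0.4, velocity=0.5, lower_bound=0.0,
                             upper_bound=1.0, reflecting_lower=True,
                             reflecting_upper=True)
        reflect_bounds(v)
        assert v.value == 0.4 and v.velocity == 0.5

        v = ExtendedVariable(-0.3, velocity=-0.1, lower_bound=0.0,
                             upper_bound=1.0, reflecting_lower=True,
                             reflecting_upper=True)
        reflect_bounds(v)
        assert v.value == pytest.approx(0.3)
        assert v.velocity == 0.1

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ExtendedVariable(0.5, lower_bound=1.0, upper_bound=0.0)

    def test_bounds_invariant_under_dynamics(self):
        var = ExtendedVariable(0.5, fictitious_mass=100.0, lower_bound=0.0,
                               upper_bound=1.0, reflecting_lower=True,
                               reflecting_upper=True)
        params = EngineParams(temperature=600.0, friction=5.0, timestep=1.0)
        rng = make_rng(3)
        for _ in range(20_000):
            baoa_step_extended(var, params, 0.0, rng)
            assert 0.0 <= var.value <= 1.0


class TestRngSerialization:
    def test_round_trip(self):
        rng = make_rng(17)
        rng.standard_normal(7)
        token = rng_state(rng)
        expected = rng.standard_normal(5)
        rng2 = make_rng(0)
        set_rng_state(rng2, token)
        assert np.array_equal(rng2.standard_normal(5), expected)


class TestRestartInvariance:
    def _sim(self, seed=9):
        pot = PotentialSpec("double_well_1d", {"h": 2.0})
        params = EngineParams(temperature=300.0, friction=10.0, timestep=1.0,
                              seed=seed)
        st = SystemState(np.array([[-1.0, 0.0, 0.0]]), np.zeros((1, 3)), [1.0])
        return Simulation(pot, params, st)

    def test_split_run_is_bitwise_identical(self):
        ref = self._sim()
        ref.run(1000)

        sim = self._sim()
        sim.run(500)
        doc = sim.checkpoint()
        fresh = self._sim()
        fresh.restore(doc)
        fresh.run(500)
        assert np.array_equal(fresh.state.positions, ref.state.positions)
        assert np.array_equal(fresh.state.velocities, ref.state.velocities)


class TestRunWalkers:
    def _factory(self, i):
        pot = PotentialSpec("harmonic_well", {"k": 1.0})
        params = EngineParams(temperature=300.0, friction=10.0, timestep=1.0,
                              seed=40)
        st = SystemState(np.zeros((1, 3)), np.zeros((1, 3)), [1.0])
        return Simulation(pot, params, st, walker_index=i)

    def test_single_walker_matches_direct_run(self):
        sims, _ = run_walkers(self._factory, 1, 300)
        direct = self._factory(0)
        direct.run(300)
        assert np.array_equal(sims[0].state.positions, direct.state.positions)

    def test_distinct_seeds_distinct_trajectories(self):
        sims, _ = run_walkers(self._factory, 2, 200)
        assert not np.array_equal(sims[0].state.positions,
                                  sims[1].state.positions)

    def test_share_event_bookkeeping(self):
        events = []
        sims, n = run_walkers(self._factory, 2, 1000, share_interval=100,
                              share=lambda s: events.append(s[0].state.step))
        assert n == 10
        assert events == [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]

    def test_share_interval_single_walker_warns(self):
        with pytest.warns(UserWarning):
            run_walkers(self._factory, 1, 10, share_interval=5)
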