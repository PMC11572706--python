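"""Toy Langevin dynamics engine.

A minimal molecular-dynamics stand-in: point particles on analytic
potentials, integrated with the BAOA Langevin splitting (kick, half drift,
Ornstein-Uhlenbeck, half drift), plus extended (fictitious) dynamical
variables with optional reflecting bounds, used by extended-system ABF and
lambda-dynamics.  Every source of randomness is an explicitly serializable
per-walker generator so checkpointed runs restart bitwise-identically.

Units: angstrom, femtosecond, amu, kcal/mol, kelvin (see
:mod:`colvarkit.units`).  Extended variables carry their own CV units; their
fictitious masses are expressed in kcal/mol fs^2 / (CV unit)^2 so that
acceleration = force / mass without conversion factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import ACC_KCAL_PER_AMU_A, BOLTZMANN_KCAL_MOL_K, INV_PS_TO_INV_FS

__all__ = [
    "SystemState",
    "EngineParams",
    "ExtendedVariable",
    "baoa_step",
    "baoa_step_extended",
    "reflect_bounds",
    "Simulation",
    "run_walkers",
    "make_rng",
    "rng_state",
    "set_rng_state",
]


def make_rng(seed: int) -> np.random.Generator:
    """A serializable per-walker random generator (PCG64)."""
    return np.random.Generator(np.random.PCG64(int(seed)))


def rng_state(rng: np.random.Generator) -> dict:
    """Serializable token capturing the full generator state."""
    st = rng.bit_generator.state
    return {
        "bit_generator": st["bit_generator"],
        "state": int(st["state"]["state"]),
        "inc": int(st["state"]["inc"]),
        "has_uint32": int(st["has_uint32"]),
        "uinteger": int(st["uinteger"]),
    }


def set_rng_state(rng: np.random.Generator, token: dict) -> None:
    rng.bit_generator.state = {
        "bit_generator": token["bit_generator"],
        "state": {"state": int(token["state"]), "inc": int(token["inc"])},
        "has_uint32": int(token["has_uint32"]),
        "uinteger": int(token["uinteger"]),
    }


@dataclass
class SystemState:
    """Cartesian coordinates, velocities and masses of the toy system."""

    positions: np.ndarray  # (n, 3) angstrom
    velocities: np.ndarray  # (n, 3) angstrom/fs
    masses: np.ndarray  # (n,) amu
    step: int = 0
    cell: np.ndarray | None = None  # orthorhombic box lengths (3,), angstrom

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        n = len(self.positions)
        if len(self.velocities) != n or len(self.masses) != n:
            raise ValueError("positions/velocities/masses length mismatch")
        if not (np.all(np.isfinite(self.positions))
                and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite coordinates or velocities")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.masses.copy(), self.step,
                           None if self.cell is None else self.cell.copy())


@dataclass
class EngineParams:
    """Integrator parameters."""

    temperature: float = 300.0  # K
    friction: float = 1.0  # 1/ps
    timestep: float = 1.0  # fs
    boltzmann_constant: float = BOLTZMANN_KCAL_MOL_K  # kcal/(mol K)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")

    @property
    def beta(self) -> float:
        return 1.0 / (self.boltzmann_constant * self.temperature)


@dataclass
class ExtendedVariable:
    """Fictitious dynamical degree of freedom (eABF spring partner, lambda).

    ``fictitious_mass`` is in kcal/mol fs^2 per squared CV unit; with a
    target thermal standard deviation sigma and oscillation period tau the
    natural choices are coupling = k_B T / sigma^2 and
    mass = coupling (tau / 2 pi)^2.
    """

    value: float
    velocity: float = 0.0
    fictitious_mass: float = 1.0
    coupling_constant: float = 0.0  # kcal/mol per CV unit^2 (eABF spring)
    lower_bound: float | None = None
    upper_bound: float | None = None
    reflecting_lower: bool = False
    reflecting_upper: bool = False

    def __post_init__(self) -> None:
        if self.fictitious_mass <= 0:
            raise ValueError("fictitious mass must be positive")
        if (self.lower_bound is not None and self.upper_bound is not None
                and self.lower_bound >= self.upper_bound):
            raise ValueError("lower bound must be below upper bound")


def reflect_bounds(var: ExtendedVariable) -> ExtendedVariable:
    """Mirror the value across any violated reflecting bound (in place).

    The position is reflected and the velocity negated, repeatedly until the
    value lies inside the interval.
    """
    lo, hi = var.lower_bound, var.upper_bound
    for _ in range(64):
        if (var.reflecting_lower and lo is not None and var.value < lo):
            var.value = 2.0 * lo - var.value
            var.velocity = -var.velocity
        elif (var.reflecting_upper and hi is not None and var.value > hi):
            var.value = 2.0 * hi - var.value
            var.velocity = -var.velocity
        else:
            return var
    raise RuntimeError("reflection did not converge (value far outside bounds)")


def _ou_coeffs(params: EngineParams) -> tuple[float, float]:
    """(c1, thermal prefactor) of the O-step; c2 = sqrt((1-c1^2) kB T)."""
    gamma = params.friction * INV_PS_TO_INV_FS
    c1 = math.exp(-gamma * params.timestep)
    kt = params.boltzmann_constant * params.temperature
    return c1, math.sqrt(max(0.0, 1.0 - c1 * c1) * kt)


def baoa_step(state: SystemState, params: EngineParams, forces: np.ndarray,
              rng: np.random.Generator) -> SystemState:
    """One BAOA step (B: full kick, A: half drift, O: OU, A: half drift).

    Forces are kcal/mol/angstrom; the acceleration conversion to
    angstrom/fs^2 is applied internally.  Raises on non-finite forces.
    """
    f = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite forces passed to baoa_step")
    dt = params.timestep
    m = state.masses[:, None]
    # B: full kick
    state.velocities += dt * ACC_KCAL_PER_AMU_A * f / m
    # A: half drift
    state.positions += 0.5 * dt * state.velocities
    # O: Ornstein-Uhlenbeck
    c1, therm = _ou_coeffs(params)
    if therm > 0.0:
        noise = rng.standard_normal(state.positions.shape)
        state.velocities *= c1
        state.velocities += therm * math.sqrt(ACC_KCAL_PER_AMU_A) / np.sqrt(m) * noise
    else:
        state.velocities *= c1
    # A: half drift
    state.positions += 0.5 * dt * state.velocities
    state.step += 1
    return state


def baoa_step_extended(var: ExtendedVariable, params: EngineParams,
                       force: float, rng: np.random.Generator) -> ExtendedVariable:
    """BAOA step for a single extended variable, then bound reflection."""
    if not math.isfinite(force):
        raise ValueError("non-finite force on extended variable")
    dt = params.timestep
    var.velocity += dt * force / var.fictitious_mass
    var.value += 0.5 * dt * var.velocity
    c1, therm = _ou_coeffs(params)
    var.velocity *= c1
    if therm > 0.0:
        var.velocity += therm / math.sqrt(var.fictitious_mass) * rng.standard_normal()
    var.value += 0.5 * dt * var.velocity
    return reflect_bounds(var)


class Simulation:
    """Couples a toy potential, collective variables and biases.

    Per step: evaluate physical forces, evaluate every declared CV, let each
    bias produce generalized forces on its CVs (propagated to atoms by the
    chain rule) and on any extended variables it owns, then advance atoms
    and extended variables with BAOA.
    """

    def __init__(self, potential, params: EngineParams, state: SystemState,
                 colvars=None, biases=None, lambda_bias=None, walker_index: int = 0):
        from .potentials import evaluate_potential  # local to avoid cycle
        self._evaluate = evaluate_potential
        self.potential = potential
        self.params = params
        self.state = state
        self.colvars = list(colvars or [])
        self.biases = list(biases or [])
        self.lambda_bias = lambda_bias  # bias driving an alchemical lambda
        self.walker_index = walker_index
        self.rng = make_rng(params.seed + walker_index)
        self.cv_history: list[list[float]] = []
        self.traj_rows: list[tuple] = []
        self.traj_positions: list[np.ndarray] = []

    # -- single step ---------------------------------------------------
    def step(self, record_every: int = 0) -> None:
        st = self.state
        lam = None
        if self.lambda_bias is not None:
            lam = self.lambda_bias.extended.value
        pot = self._evaluate(self.potential, st.positions, lam)
        forces = pot.forces.copy()

        cv_values = []
        cv_grads = []
        for cv in self.colvars:
            v, g = cv.evaluate(st.positions)
            cv_values.append(v)
            cv_grads.append(g)
        # exposed for biases that need the bare physical forces (classic ABF)
        self.last_potential = pot
        self.last_cv_grads = cv_grads

        for bias in self.biases:
            gen_forces = bias.update_and_force(cv_values, self)
            for i, gf in enumerate(gen_forces):
                if gf != 0.0:
                    forces += gf * cv_grads[i]

        if record_every and st.step % record_every == 0:
            self.traj_rows.append((st.step, tuple(cv_values)))
            self.traj_positions.append(st.positions.copy())

        baoa_step(st, self.params, forces, self.rng)

        if self.lambda_bias is not None:
            lam_force = -pot.dU_dlambda + self.lambda_bias.update_and_force_lambda(self)
            baoa_step_extended(self.lambda_bias.extended, self.params,
                               lam_force, self.rng)

        for bias in self.biases:
            post = getattr(bias, "post_step", None)
            if post is not None:
                post(self)

    def run(self, n_steps: int, record_every: int = 0) -> None:
        for _ in range(n_steps):
            self.step(record_every=record_every)

    # -- checkpointing -------------------------------------------------
    def checkpoint(self) -> dict:
        doc = {
            "step": int(self.state.step),
            "positions": self.state.positions.tolist(),
            "velocities": self.state.velocities.tolist(),
            "rng_state": rng_state(self.rng),
            "bias_states": [b.state_dict() for b in self.biases],
        }
        if self.lambda_bias is not None:
            doc["lambda_bias"] = self.lambda_bias.state_dict()
        return doc

    def restore(self, doc: dict) -> None:
        self.state.step = int(doc["step"])
        self.state.positions = np.asarray(doc["positions"], dtype=float)
        self.state.velocities = np.asarray(doc["velocities"], dtype=float)
        set_rng_state(self.rng, doc["rng_state"])
        for b, bstate in zip(self.biases, doc["bias_states"]):
            b.load_state_dict(bstate)
        if self.lambda_bias is not None and "lambda_bias" in doc:
            self.lambda_bias.load_state_dict(doc["lambda_bias"])


def run_walkers(factory, n_walkers: int, n_steps: int,
                share_interval: int | None = None, share=None,
                record_every: int = 0):
    """Run several walkers, firing a sharing callback at fixed cadence.

    ``factory(walker_index)`` builds one :class:`Simulation` (seeds must be
    distinct, which factories get for free via ``params.seed + index``).
    ``share(sims)`` is invoked at every multiple of ``share_interval``.
    Returns ``(sims, n_share_events)``.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    if share_interval is not None and n_walkers == 1:
        warnings.warn("share_interval set with a single walker; no-op")
    sims = [factory(i) for i in range(n_walkers)]
    events = 0
    done = 0
    while done < n_steps:
        chunk = n_steps - done
        if share_interval:
            chunk = min(chunk, share_interval - (done % share_interval) or share_interval)
        for sim in sims:
            sim.run(chunk, record_every=record_every)
        done += chunk
        if share_interval and done % share_interval == 0:
            if share is not None and n_walkers > 1:
                share(sims)
            events += 1
    return sims, events
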