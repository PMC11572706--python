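"""Restraint biases: harmonic, maximum-entropy averages (ALB / RAD),
multiple-replica histogram restraints and adiabatic-bias MD.

Maximum-entropy average restraints apply the minimal linear bias
V = lambda * xi whose coupling lambda is adjusted by gradient descent,
lambda <- lambda + c(t) (<xi> - xi_tar), so the simulated running mean of
the observable converges to the target.  ALB pins xi_tar to the
experimental value.  RAD additionally treats xi_tar as a dynamical
quantity: it relaxes toward wherever the bias can be smallest, while a
multiplier gamma — adjusted to hold the aggregate agreement
sum_i |xi_tar_i - xi_exp_i| / (N eta_i) at a configured level — pulls it
back toward the experimental value within the stated error eta.  As
eta -> 0 the pull dominates and RAD reduces to ALB; when the unbiased mean
is already compatible with the data, xi_tar settles there and lambda
decays to zero (no unnecessary bias).

The histogram restraint applies harmonic penalties on the across-replica
mean of kernel functions h_i(x), enforcing a one-dimensional target
probability distribution.  ABMD (ratchet-and-pawl) is a one-sided
history-dependent harmonic centered on the high-water mark of a progress
coordinate, capped at a stopping value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import wrap_periodic

__all__ = ["harmonic_force", "HarmonicRestraint", "AlbState", "alb_update",
           "AlbBias", "RadState", "rad_update", "RadBias", "HistRestraintSpec",
           "histogram_restraint_force", "AbmdState", "abmd_force", "AbmdBias"]


def harmonic_force(center: float, k: float, z: float,
                   periodic: bool = False, period: float = 360.0):
    """V = (k/2) d^2 and F = -k d with the wrap-aware displacement d."""
    if k < 0:
        raise ValueError("force constant must be >= 0")
    d = z - center
    if periodic:
        d = wrap_periodic(d, period)
    return 0.5 * k * d * d, -k * d


class HarmonicRestraint:
    """Fixed harmonic restraint on one CV (Simulation bias)."""

    def __init__(self, cv_index: int, center: float, k: float,
                 periodic: bool = False, period: float = 360.0):
        self.cv_index = cv_index
        self.center = float(center)
        self.k = float(k)
        self.periodic = periodic
        self.period = period
        self.energy = 0.0

    def update_and_force(self, cv_values, sim):
        out = [0.0] * len(cv_values)
        self.energy, f = harmonic_force(self.center, self.k,
                                        cv_values[self.cv_index],
                                        self.periodic, self.period)
        out[self.cv_index] = f
        return out

    def state_dict(self):
        return {"center": self.center, "k": self.k}

    def load_state_dict(self, doc):
        self.center = float(doc["center"])
        self.k = float(doc["k"])


# ---------------------------------------------------------------------------
# Adaptive linear bias (maximum-entropy mean restraint)
# ---------------------------------------------------------------------------

@dataclass
class AlbState:
    """Coupling, learning rate and running-mean bookkeeping for one
    observable."""

    target: float  # xi_tar (for ALB, the experimental value)
    learning_rate: float  # c(t), per update
    coupling: float = 0.0  # lambda, kcal/mol per CV unit
    ewma_tau: float = 500.0  # running-mean time constant, steps
    mean: float | None = None  # exponentially weighted running mean
    samples: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")

    def observe(self, value: float) -> None:
        self.samples += 1
        if self.mean is None:
            self.mean = value
        else:
            a = 1.0 / min(self.samples, self.ewma_tau)
            self.mean += a * (value - self.mean)


def alb_update(state: AlbState, current_mean: float) -> float:
    """One gradient-descent step of the coupling; returns the new lambda.

    With bias V = +lambda xi (force -lambda on xi), a mean above target
    raises lambda, pushing the mean back down.
    """
    state.coupling += state.learning_rate * (current_mean - state.target)
    return state.coupling


class AlbBias:
    """Adaptive linear bias on one CV (Simulation bias).

    The running mean is exponentially weighted (time constant
    ``ewma_tau`` steps), which keeps the update Markovian and
    checkpointable; the coupling is updated every ``update_period`` steps
    once the averaging window has filled.
    """

    def __init__(self, cv_index: int, target: float, learning_rate: float,
                 update_period: int = 100, ewma_tau: float = 500.0):
        self.cv_index = cv_index
        self.state = AlbState(target=target, learning_rate=learning_rate,
                              ewma_tau=ewma_tau)
        self.update_period = int(update_period)

    def update_and_force(self, cv_values, sim):
        z = cv_values[self.cv_index]
        self.state.observe(z)
        if (sim.state.step + 1) % self.update_period == 0 \
                and self.state.samples >= self.state.ewma_tau:
            alb_update(self.state, self.state.mean)
        out = [0.0] * len(cv_values)
        out[self.cv_index] = -self.state.coupling  # force of V = lambda xi
        return out

    def state_dict(self):
        s = self.state
        return {"target": s.target, "coupling": s.coupling, "mean": s.mean,
                "samples": s.samples}

    def load_state_dict(self, doc):
        self.state.target = float(doc["target"])
        self.state.coupling = float(doc["coupling"])
        self.state.mean = doc["mean"]
        self.state.samples = int(doc["samples"])


# ---------------------------------------------------------------------------
# Restrained-average dynamics (RAD)
# ---------------------------------------------------------------------------

@dataclass
class RadState(AlbState):
    """ALB state plus experimental-error handling.

    ``eta`` is the estimated experimental error; ``gamma`` sets the
    strength of the pull of the evolving target toward the experimental
    value and is itself adjusted (multiplicatively) to hold
    |xi_tar - xi_exp| / eta near ``agreement``.
    """

    experimental: float = 0.0  # xi_exp
    eta: float = 1.0  # experimental error > 0
    gamma: float = 1.0  # agreement multiplier
    agreement: float = 1.0  # aggregate target of |xi_tar - xi_exp| / eta
    target_rate: float = 0.01  # learning rate of the xi_tar dynamics
    gamma_rate: float = 0.05  # multiplicative gamma adjustment rate

    def __post_init__(self):
        super().__post_init__()
        if self.eta <= 0:
            raise ValueError("experimental error eta must be > 0")


def rad_update(state: RadState, current_mean: float) -> tuple[float, float]:
    """One RAD step: evolve the target, the multiplier, then the coupling.

    The target moves to reduce the bias (along +lambda, the direction that
    lets the restraint relax) while gamma (xi_tar - xi_exp)/eta pulls it
    back toward the data; gamma grows or shrinks to hold the agreement
    level.  Returns (lambda, xi_tar).
    """
    dev = (state.target - state.experimental) / state.eta
    step = state.target_rate * (state.coupling * state.eta - state.gamma * dev)
    # keep target moves bounded by the stated error so eta -> 0 pins the
    # target to the experimental value (the ALB limit) without overflow
    step = max(-0.5 * state.eta, min(0.5 * state.eta, step))
    state.target += step
    expo = min(50.0, state.gamma_rate * (abs(dev) - state.agreement))
    state.gamma = min(1e6, max(1e-12, state.gamma * math.exp(expo)))
    alb_update(state, current_mean)
    return state.coupling, state.target


class RadBias(AlbBias):
    """RAD restraint on one CV (Simulation bias)."""

    def __init__(self, cv_index: int, experimental: float, eta: float,
                 learning_rate: float, update_period: int = 100,
                 ewma_tau: float = 500.0, agreement: float = 1.0,
                 target_rate: float = 0.01, gamma_rate: float = 0.05):
        self.cv_index = cv_index
        self.state = RadState(target=experimental, learning_rate=learning_rate,
                              ewma_tau=ewma_tau, experimental=experimental,
                              eta=eta, agreement=agreement,
                              target_rate=target_rate, gamma_rate=gamma_rate)
        self.update_period = int(update_period)

    def update_and_force(self, cv_values, sim):
        z = cv_values[self.cv_index]
        self.state.observe(z)
        if (sim.state.step + 1) % self.update_period == 0 \
                and self.state.samples >= self.state.ewma_tau:
            rad_update(self.state, self.state.mean)
        out = [0.0] * len(cv_values)
        out[self.cv_index] = -self.state.coupling
        return out

    def state_dict(self):
        doc = super().state_dict()
        doc.update({"gamma": self.state.gamma,
                    "experimental": self.state.experimental})
        return doc

    def load_state_dict(self, doc):
        super().load_state_dict(doc)
        self.state.gamma = float(doc["gamma"])
        self.state.experimental = float(doc["experimental"])


# ---------------------------------------------------------------------------
# Multiple-replica histogram restraint
# ---------------------------------------------------------------------------

@dataclass
class HistRestraintSpec:
    """Kernel centers, form, force constant and targets (1D CV only)."""

    centers: np.ndarray
    width: float
    force_constant: float
    targets: np.ndarray
    kernel: str = "gaussian"  # or "rectangular"
    n_replicas: int = 1

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("kernel centers must be strictly increasing")
        if len(self.targets) != len(self.centers):
            raise ValueError("one target per kernel required")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.kernel not in ("gaussian", "rectangular"):
            raise ValueError("kernel must be gaussian or rectangular")

    def kernels(self, x: float):
        """h_i(x) and dh_i/dx for all kernels."""
        u = (x - self.centers) / self.width
        if self.kernel == "gaussian":
            h = np.exp(-0.5 * u * u)
            dh = -h * u / self.width
        else:
            h = (np.abs(u) <= 0.5).astype(float)
            dh = np.zeros_like(h)
        return h, dh


def histogram_restraint_force(spec: HistRestraintSpec, replica_values):
    """Energy and per-replica forces of the across-replica mean-histogram
    restraint V = sum_i (K/2) (mean_r h_i(x_r) - target_i)^2.

    A replica whose value lies outside every kernel simply contributes
    zero to all of them.
    """
    x = np.asarray(replica_values, dtype=float)
    if len(x) != spec.n_replicas:
        raise ValueError(f"expected {spec.n_replicas} replica values, got {len(x)}")
    h = np.empty((len(x), len(spec.centers)))
    dh = np.empty_like(h)
    for r, xr in enumerate(x):
        h[r], dh[r] = spec.kernels(xr)
    mean = h.mean(axis=0)
    dev = mean - spec.targets
    energy = 0.5 * spec.force_constant * float(dev @ dev)
    forces = -spec.force_constant * (dh @ dev) / spec.n_replicas
    return energy, forces


# ---------------------------------------------------------------------------
# Adiabatic bias MD (ratchet-and-pawl)
# ---------------------------------------------------------------------------

@dataclass
class AbmdState:
    """High-water mark, force constant, direction and stop value."""

    force_constant: float
    stop_value: float
    direction: str = "increase"  # or "decrease"
    reference: float | None = None  # high-water mark xi_ref

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")


def abmd_force(state: AbmdState, z: float) -> tuple[float, float]:
    """One-sided ratchet: returns (energy, force), updating the mark.

    Increase mode: xi_ref <- min(max(xi_ref, z), xi_stop); the harmonic
    engages only when z < xi_ref (z exactly at the mark feels no force).
    Decrease mode mirrors it.
    """
    st = state
    if st.direction == "increase":
        st.reference = z if st.reference is None else max(st.reference, z)
        st.reference = min(st.reference, st.stop_value)
        if z < st.reference:
            d = z - st.reference
            return 0.5 * st.force_constant * d * d, -st.force_constant * d
    else:
        st.reference = z if st.reference is None else min(st.reference, z)
        st.reference = max(st.reference, st.stop_value)
        if z > st.reference:
            d = z - st.reference
            return 0.5 * st.force_constant * d * d, -st.force_constant * d
    return 0.0, 0.0


class AbmdBias:
    """ABMD on one CV (Simulation bias)."""

    def __init__(self, cv_index: int, force_constant: float, stop_value: float,
                 decrease: bool = False):
        self.cv_index = cv_index
        self.state = AbmdState(force_constant, stop_value,
                               "decrease" if decrease else "increase")

    def update_and_force(self, cv_values, sim):
        out = [0.0] * len(cv_values)
        _, f = abmd_force(self.state, cv_values[self.cv_index])
        out[self.cv_index] = f
        return out

    def state_dict(self):
        return {"reference": self.state.reference}

    def load_state_dict(self, doc):
        self.state.reference = doc["reference"]
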