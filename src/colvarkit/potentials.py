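"""Analytic toy potentials used by the Langevin engine.

Each potential is a closed-form energy function of the particle coordinates
(and, for the alchemically coupled one, of a coupling parameter ``lambda``)
whose forces are exact negative gradients.  They stand in for a force field
so collective variables and biases can be exercised end to end.

Supported kinds
---------------
``harmonic_well``
    Isotropic harmonic well, U = (k/2) |x - x0|^2 summed over atoms.
``double_well_1d``
    U = h (x^2 - 1)^2 acting on the x coordinate of atom 0; minima at
    x = -1, +1 with barrier height ``h`` (kcal/mol).
``rugged_2d``
    Smooth corrugated 2D surface on (x, y) of atom 0.
``lambda_coupled_dual_harmonic``
    U(x, lambda) = (1-lambda) U_A + lambda U_B with U_A, U_B harmonic
    wells of stiffness ``k_a``, ``k_b`` on the x coordinate of atom 0.
    The free-energy profile A(lambda) has the closed form
    (k_B T / 2) ln[(1-lambda) k_a + lambda k_b] + const, so
    A(1) - A(0) = (k_B T / 2) ln(k_b / k_a).
``flat_with_walls``
    Flat interior with half-harmonic confining walls on the x coordinate
    of atom 0: U = (k_wall/2) (x - hi)^2 for x > hi, symmetric at lo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PotentialSpec", "PotentialResult", "evaluate_potential"]


@dataclass
class PotentialSpec:
    """A named analytic potential with its parameter map."""

    kind: str
    parameters: dict = field(default_factory=dict)

    KINDS = (
        "harmonic_well",
        "double_well_1d",
        "rugged_2d",
        "lambda_coupled_dual_harmonic",
        "flat_with_walls",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown potential kind {self.kind!r}")


@dataclass
class PotentialResult:
    energy: float
    forces: np.ndarray  # (n_atoms, 3), kcal/mol/A
    dU_dlambda: float | None = None


def evaluate_potential(spec: PotentialSpec, positions: np.ndarray,
                       lam: float | None = None) -> PotentialResult:
    """Energy, forces and (for coupled potentials) dU/dlambda.

    ``lam`` must be given iff ``spec.kind == 'lambda_coupled_dual_harmonic'``
    and must lie in [0, 1].
    """
    pos = np.asarray(positions, dtype=float)
    coupled = spec.kind == "lambda_coupled_dual_harmonic"
    if coupled:
        if lam is None:
            raise ValueError("lambda_coupled_dual_harmonic requires lambda")
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
    elif lam is not None:
        raise ValueError(f"potential {spec.kind!r} takes no lambda")

    p = spec.parameters
    forces = np.zeros_like(pos)

    if spec.kind == "harmonic_well":
        k = float(p.get("k", 1.0))
        x0 = np.asarray(p.get("center", np.zeros(3)), dtype=float)
        d = pos - x0
        energy = 0.5 * k * float(np.sum(d * d))
        forces = -k * d
        return PotentialResult(energy, forces)

    if spec.kind == "double_well_1d":
        h = float(p.get("h", 2.0))
        x = pos[0, 0]
        energy = h * (x * x - 1.0) ** 2
        forces[0, 0] = -4.0 * h * x * (x * x - 1.0)
        return PotentialResult(energy, forces)

    if spec.kind == "rugged_2d":
        # smooth confining bowl plus a sinusoidal corrugation
        a = float(p.get("a", 0.5))
        b = float(p.get("b", 1.0))
        x, y = pos[0, 0], pos[0, 1]
        energy = a * (x * x + y * y) + b * math.sin(1.3 * x) * math.cos(0.9 * y)
        forces[0, 0] = -(2.0 * a * x + 1.3 * b * math.cos(1.3 * x) * math.cos(0.9 * y))
        forces[0, 1] = -(2.0 * a * y - 0.9 * b * math.sin(1.3 * x) * math.sin(0.9 * y))
        return PotentialResult(energy, forces)

    if spec.kind == "lambda_coupled_dual_harmonic":
        k_a = float(p.get("k_a", 1.0))
        k_b = float(p.get("k_b", 4.0))
        x = pos[0, 0]
        u_a = 0.5 * k_a * x * x
        u_b = 0.5 * k_b * x * x
        energy = (1.0 - lam) * u_a + lam * u_b
        k_eff = (1.0 - lam) * k_a + lam * k_b
        forces[0, 0] = -k_eff * x
        return PotentialResult(energy, forces, dU_dlambda=u_b - u_a)

    if spec.kind == "flat_with_walls":
        lo = float(p.get("lo", 0.0))
        hi = float(p.get("hi", 10.0))
        k_wall = float(p.get("k_wall", 100.0))
        x = pos[0, 0]
        energy = 0.0
        if x < lo:
            energy = 0.5 * k_wall * (x - lo) ** 2
            forces[0, 0] = -k_wall * (x - lo)
        elif x > hi:
            energy = 0.5 * k_wall * (x - hi) ** 2
            forces[0, 0] = -k_wall * (x - hi)
        return PotentialResult(energy, forces)

    raise ValueError(f"unknown potential kind {spec.kind!r}")  # pragma: no cover
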