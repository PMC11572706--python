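"""Geometric collective-variable components.

Each component maps the Cartesian coordinates of named atom groups to a
scalar (distances, angles, best-fit RMSD, polar and Euler angles) together
with analytic per-atom gradients.  Components can be evaluated in a moving
frame of reference defined by a fitting group, with biasing forces
propagated to the fitting atoms through the derivative of the best-fit
rotation; and they can be combined linearly (weighted sums of powers) or
through arbitrary closed-form expressions (:mod:`colvarkit.expressions`).

Angles are reported in degrees with period 360 and range (-180, 180]; the
azimuth at the poles (theta = 0 or 180 deg) is defined as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rotation import (RotationFit, best_fit_rotation, quaternion_derivatives,
                       quaternion_to_matrix)

__all__ = [
    "AtomGroup", "ColvarValue", "MovingFrameSpec", "Component",
    "Distance", "DistanceZ", "DistanceXY", "Angle", "Rmsd",
    "PolarTheta", "PolarPhi", "EulerAngle", "FittedComponent",
    "PolynomialCombination", "polar_angles", "euler_angles",
    "euler_to_quaternion",
]

RAD2DEG = 180.0 / math.pi


@dataclass
class AtomGroup:
    """Ordered atom indices (0-based) with optional positive weights."""

    indices: list
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = list(int(i) for i in self.indices)
        if not self.indices:
            raise ValueError("empty atom group")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("duplicate atom indices in group")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.indices):
                raise ValueError("weights length does not match indices")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.indices)

    def norm_weights(self) -> np.ndarray:
        w = (np.ones(len(self.indices)) if self.weights is None
             else self.weights)
        return w / w.sum()

    def center(self, positions: np.ndarray) -> np.ndarray:
        w = self.norm_weights()
        return (w[:, None] * positions[self.indices]).sum(0)


@dataclass
class ColvarValue:
    value: float | np.ndarray
    periodic: bool = False
    period: float = 360.0


def wrap_periodic(x: float, period: float = 360.0) -> float:
    """Wrap into (-period/2, period/2]."""
    y = x % period
    if y > period / 2.0:
        y -= period
    return y


@dataclass
class MovingFrameSpec:
    """Frame of reference tied to a fitting group."""

    fitting_group: AtomGroup
    reference_positions: np.ndarray
    fit_translation: bool = True
    fit_rotation: bool = True

    def __post_init__(self) -> None:
        self.reference_positions = np.asarray(self.reference_positions, float)
        if len(self.reference_positions) != len(self.fitting_group):
            raise ValueError("reference count != fitting group size")


class Component:
    """Base class: ``evaluate(positions) -> (value, gradients)``.

    Gradients are a dense (n_atoms, 3) array over the whole system; unused
    atoms carry zeros.  ``periodic``/``period`` describe the value's
    topology (used by harmonic restraints for wrap-aware displacements).
    """

    periodic = False
    period = 360.0

    def evaluate(self, positions: np.ndarray):
        raise NotImplementedError


def _scatter(n: int, pairs) -> np.ndarray:
    g = np.zeros((n, 3))
    for idx, vec in pairs:
        g[idx] += vec
    return g


class Distance(Component):
    """|center(group2) - center(group1)| in angstrom."""

    def __init__(self, group1: AtomGroup, group2: AtomGroup):
        self.group1, self.group2 = group1, group2

    def evaluate(self, positions):
        d = self.group2.center(positions) - self.group1.center(positions)
        r = float(np.linalg.norm(d))
        if r == 0.0:
            raise ValueError("coincident group centers: distance gradient undefined")
        u = d / r
        g = np.zeros_like(positions)
        for grp, sgn in ((self.group1, -1.0), (self.group2, 1.0)):
            w = grp.norm_weights()
            for i, idx in enumerate(grp.indices):
                g[idx] += sgn * w[i] * u
        return r, g


class DistanceZ(Component):
    """Projection of the inter-center separation onto a fixed axis.

    With ``ref_group`` unset the main group's absolute center is projected
    (convenient for toy particles on analytic potentials).
    """

    def __init__(self, main: AtomGroup, ref_group: AtomGroup | None = None,
                 axis=(0.0, 0.0, 1.0)):
        self.main, self.ref_group = main, ref_group
        a = np.asarray(axis, dtype=float)
        self.axis = a / np.linalg.norm(a)

    def evaluate(self, positions):
        d = self.main.center(positions)
        if self.ref_group is not None:
            d = d - self.ref_group.center(positions)
        val = float(d @ self.axis)
        g = np.zeros_like(positions)
        w = self.main.norm_weights()
        for i, idx in enumerate(self.main.indices):
            g[idx] += w[i] * self.axis
        if self.ref_group is not None:
            w = self.ref_group.norm_weights()
            for i, idx in enumerate(self.ref_group.indices):
                g[idx] -= w[i] * self.axis
        return val, g


class DistanceXY(Component):
    """Inter-center distance projected on the plane orthogonal to an axis."""

    def __init__(self, group1: AtomGroup, group2: AtomGroup,
                 axis=(0.0, 0.0, 1.0)):
        self.group1, self.group2 = group1, group2
        a = np.asarray(axis, dtype=float)
        self.axis = a / np.linalg.norm(a)

    def evaluate(self, positions):
        d = self.group2.center(positions) - self.group1.center(positions)
        perp = d - (d @ self.axis) * self.axis
        r = float(np.linalg.norm(perp))
        g = np.zeros_like(positions)
        if r > 0.0:
            u = perp / r
            for grp, sgn in ((self.group1, -1.0), (self.group2, 1.0)):
                w = grp.norm_weights()
                for i, idx in enumerate(grp.indices):
                    g[idx] += sgn * w[i] * u
        return r, g


class Angle(Component):
    """Angle (degrees) formed at center2 by centers 1-2-3."""

    def __init__(self, group1: AtomGroup, group2: AtomGroup, group3: AtomGroup):
        self.groups = (group1, group2, group3)

    def evaluate(self, positions):
        c1, c2, c3 = (g.center(positions) for g in self.groups)
        a = c1 - c2
        b = c3 - c2
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        cosv = float(a @ b / (na * nb))
        cosv = max(-1.0, min(1.0, cosv))
        theta = math.acos(cosv)
        sin = math.sqrt(max(1e-300, 1.0 - cosv * cosv))
        # d theta / d a, d b
        da = -(b / (na * nb) - cosv * a / (na * na)) / sin
        db = -(a / (na * nb) - cosv * b / (nb * nb)) / sin
        g = np.zeros_like(positions)
        for grp, vec in ((self.groups[0], da), (self.groups[2], db),
                         (self.groups[1], -(da + db))):
            w = grp.norm_weights()
            for i, idx in enumerate(grp.indices):
                g[idx] += w[i] * vec * RAD2DEG
        return theta * RAD2DEG, g


class Rmsd(Component):
    """Best-fit (optimal superposition) RMSD from reference coordinates."""

    def __init__(self, group: AtomGroup, reference: np.ndarray):
        self.group = group
        self.reference = np.asarray(reference, dtype=float)
        if len(self.reference) != len(group):
            raise ValueError("rmsd reference length mismatch")

    def evaluate(self, positions):
        x = positions[self.group.indices]
        w = self.group.norm_weights()
        fit = best_fit_rotation(x, self.reference, w)
        g = np.zeros_like(positions)
        if fit.rmsd > 1e-12:
            xc = x - (w[:, None] * x).sum(0)
            yc = self.reference - (w[:, None] * self.reference).sum(0)
            # Hellmann-Feynman: rotation stationarity drops dR terms;
            # centering terms cancel because sum w (x' - R^T y') = 0.
            diff = xc - yc @ fit.matrix  # x' - R^T y'
            for i, idx in enumerate(self.group.indices):
                g[idx] = w[i] * diff[i] / fit.rmsd
        return fit.rmsd, g


def polar_angles(vec) -> tuple[float, float]:
    """Polar theta in [0, 180] and azimuth phi in (-180, 180], degrees.

    The azimuth of a vector on the polar axis is 0 by convention.
    """
    v = np.asarray(vec, dtype=float)
    r = np.linalg.norm(v)
    if r == 0.0:
        raise ValueError("zero vector has no polar angles")
    theta = math.acos(max(-1.0, min(1.0, v[2] / r))) * RAD2DEG
    if abs(v[0]) == 0.0 and abs(v[1]) == 0.0:
        return theta, 0.0
    phi = math.atan2(v[1], v[0]) * RAD2DEG
    return theta, phi


class PolarTheta(Component):
    """Polar angle (degrees) of the group center seen from the origin
    (or from a reference group's center)."""

    def __init__(self, group: AtomGroup, ref_group: AtomGroup | None = None):
        self.group, self.ref_group = group, ref_group

    def _vec(self, positions):
        d = self.group.center(positions)
        if self.ref_group is not None:
            d = d - self.ref_group.center(positions)
        return d

    def evaluate(self, positions):
        d = self._vec(positions)
        r = np.linalg.norm(d)
        theta = math.acos(max(-1.0, min(1.0, d[2] / r)))
        rho2 = d[0] * d[0] + d[1] * d[1]
        rho = math.sqrt(rho2)
        if rho < 1e-12:
            grad_d = np.zeros(3)  # pole: gradient degenerate, defined as 0
        else:
            r2 = r * r
            grad_d = np.array([d[0] * d[2], d[1] * d[2], -rho2]) / (r2 * rho)
        g = np.zeros_like(positions)
        for grp, sgn in ((self.group, 1.0),) + (
                ((self.ref_group, -1.0),) if self.ref_group else ()):
            w = grp.norm_weights()
            for i, idx in enumerate(grp.indices):
                g[idx] += sgn * w[i] * grad_d * RAD2DEG
        return theta * RAD2DEG, g


class PolarPhi(Component):
    """Azimuthal angle (degrees); periodic with period 360."""

    periodic = True

    def __init__(self, group: AtomGroup, ref_group: AtomGroup | None = None):
        self.group, self.ref_group = group, ref_group

    def evaluate(self, positions):
        d = self.group.center(positions)
        if self.ref_group is not None:
            d = d - self.ref_group.center(positions)
        rho2 = d[0] * d[0] + d[1] * d[1]
        if rho2 < 1e-24:
            phi, grad_d = 0.0, np.zeros(3)
        else:
            phi = math.atan2(d[1], d[0])
            grad_d = np.array([-d[1], d[0], 0.0]) / rho2
        g = np.zeros_like(positions)
        for grp, sgn in ((self.group, 1.0),) + (
                ((self.ref_group, -1.0),) if self.ref_group else ()):
            w = grp.norm_weights()
            for i, idx in enumerate(grp.indices):
                g[idx] += sgn * w[i] * grad_d * RAD2DEG
        return phi * RAD2DEG, g


# ---------------------------------------------------------------------------
# Euler angles (intrinsic z-y-x / yaw-pitch-roll) from the best-fit quaternion
# ---------------------------------------------------------------------------

def euler_angles(q: np.ndarray, warn_gimbal: bool = True):
    """(roll Phi, pitch Theta, yaw Psi) in degrees from a unit quaternion.

    Intrinsic z-y-x convention: R = Rz(yaw) Ry(pitch) Rx(roll).  The arcsin
    argument of the pitch is clamped to [-1, 1]; near-gimbal inputs emit a
    warning instead of failing.
    """
    q0, q1, q2, q3 = q
    sp = 2.0 * (q0 * q2 - q3 * q1)
    if abs(sp) > 1.0 - 1e-9:
        if warn_gimbal:
            warnings.warn("Euler pitch at gimbal lock; angles ill-conditioned")
        sp = max(-1.0, min(1.0, sp))
    roll = math.atan2(2.0 * (q0 * q1 + q2 * q3),
                      1.0 - 2.0 * (q1 * q1 + q2 * q2))
    pitch = math.asin(sp)
    yaw = math.atan2(2.0 * (q0 * q3 + q1 * q2),
                     1.0 - 2.0 * (q2 * q2 + q3 * q3))
    return roll * RAD2DEG, pitch * RAD2DEG, yaw * RAD2DEG


def euler_to_quaternion(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Unit quaternion of intrinsic z-y-x Euler angles given in degrees."""
    r, p, y = (a / RAD2DEG / 2.0 for a in (roll, pitch, yaw))
    cr, sr, cp, sp, cy, sy = (math.cos(r), math.sin(r), math.cos(p),
                              math.sin(p), math.cos(y), math.sin(y))
    q = np.array([
        cr * cp * cy + sr * sp * sy,
        sr * cp * cy - cr * sp * sy,
        cr * sp * cy + sr * cp * sy,
        cr * cp * sy - sr * sp * cy,
    ])
    from .rotation import _fix_sign
    return _fix_sign(q)


def _euler_grad_q(q: np.ndarray, which: str) -> np.ndarray:
    """d(angle in deg)/dq for one of roll/pitch/yaw."""
    q0, q1, q2, q3 = q
    if which == "pitch":
        sp = 2.0 * (q0 * q2 - q3 * q1)
        denom = math.sqrt(max(1e-12, 1.0 - sp * sp))
        return RAD2DEG * 2.0 * np.array([q2, -q3, q0, -q1]) / denom
    if which == "roll":
        a = 2.0 * (q0 * q1 + q2 * q3)
        b = 1.0 - 2.0 * (q1 * q1 + q2 * q2)
        da = 2.0 * np.array([q1, q0, q3, q2])
        db = -4.0 * np.array([0.0, q1, q2, 0.0])
    else:  # yaw
        a = 2.0 * (q0 * q3 + q1 * q2)
        b = 1.0 - 2.0 * (q2 * q2 + q3 * q3)
        da = 2.0 * np.array([q3, q2, q1, q0])
        db = -4.0 * np.array([0.0, 0.0, q2, q3])
    denom = a * a + b * b
    return RAD2DEG * (b * da - a * db) / max(denom, 1e-12)


class EulerAngle(Component):
    """Roll/pitch/yaw (degrees) of a group's best-fit rotation onto a
    reference structure, differentiated through the overlap eigenproblem."""

    periodic = True

    def __init__(self, group: AtomGroup, reference: np.ndarray, which: str):
        if which not in ("roll", "pitch", "yaw"):
            raise ValueError("which must be roll, pitch or yaw")
        self.group = group
        self.reference = np.asarray(reference, dtype=float)
        self.which = which
        self.periodic = which != "pitch"

    def evaluate(self, positions):
        x = positions[self.group.indices]
        w = self.group.norm_weights()
        fit = best_fit_rotation(x, self.reference, w)
        angles = euler_angles(fit.quaternion, warn_gimbal=True)
        value = {"roll": angles[0], "pitch": angles[1], "yaw": angles[2]}[self.which]
        dq = quaternion_derivatives(fit, x, self.reference, w)  # (m, 3, 4)
        dang = _euler_grad_q(fit.quaternion, self.which)
        g = np.zeros_like(positions)
        local = dq @ dang  # (m, 3)
        for i, idx in enumerate(self.group.indices):
            g[idx] = local[i]
        return value, g


# ---------------------------------------------------------------------------
# Moving frame of reference
# ---------------------------------------------------------------------------

def _dR_dq(q: np.ndarray) -> np.ndarray:
    """dR/dq as a (4, 3, 3) array (analytic; R is quadratic in q)."""
    q0, q1, q2, q3 = q
    d = np.empty((4, 3, 3))
    d[0] = 2.0 * np.array([[q0, -q3, q2], [q3, q0, -q1], [-q2, q1, q0]])
    d[1] = 2.0 * np.array([[q1, q2, q3], [q2, -q1, -q0], [q3, q0, -q1]])
    d[2] = 2.0 * np.array([[-q2, q1, q0], [q1, q2, q3], [-q0, q3, -q2]])
    d[3] = 2.0 * np.array([[-q3, -q0, q1], [q0, -q3, q2], [q1, q2, q3]])
    return d


class FittedComponent(Component):
    """Evaluate an inner component in a moving frame of reference.

    Coordinates are centered on the fitting group, rotated by the best-fit
    rotation onto the fitting reference, and shifted to the reference
    center; the inner component sees these fitted coordinates.  Biasing
    forces reach the fitting atoms through the implicit dependence of the
    rotation and the centering on their coordinates.

    The special case of an RMSD component whose atom group coincides with
    the fitting group (and same reference) has exactly zero fitting
    gradients by definition; it is detected and short-circuited.
    """

    def __init__(self, inner: Component, frame: MovingFrameSpec):
        self.inner = inner
        self.frame = frame
        self.periodic = inner.periodic
        self.period = inner.period
        fg = frame.fitting_group
        self._w = fg.norm_weights()
        ref = frame.reference_positions
        self._ref_center = (self._w[:, None] * ref).sum(0)
        self._self_rmsd = (
            isinstance(inner, Rmsd)
            and inner.group.indices == fg.indices
            and inner.reference.shape == ref.shape
            and bool(np.all(inner.reference == ref)))

    def _transform(self, positions):
        fg = self.frame.fitting_group
        xfit = positions[fg.indices]
        center = (self._w[:, None] * xfit).sum(0)
        fit = None
        R = np.eye(3)
        if self.frame.fit_rotation:
            fit = best_fit_rotation(xfit, self.frame.reference_positions, self._w)
            R = fit.matrix
        shifted = positions - (center if self.frame.fit_translation else 0.0)
        fitted = shifted @ R.T + (self._ref_center if self.frame.fit_translation
                                  else 0.0)
        return fitted, fit, R, center, xfit

    def evaluate(self, positions):
        fitted, fit, R, center, xfit = self._transform(positions)
        value, ginner = self.inner.evaluate(fitted)
        # CV atoms: chain through the (fixed) rotation
        g = ginner @ R
        if self._self_rmsd:
            return value, g  # fitting gradients are zero by definition
        fg = self.frame.fitting_group
        gsum = ginner.sum(0)
        if self.frame.fit_translation:
            # translation term: d fitted_i / d xfit_a = -R w_a / W (all i)
            trans = -np.outer(self._w, gsum @ R)
            for i, idx in enumerate(fg.indices):
                g[idx] += trans[i]
        if self.frame.fit_rotation and fit is not None:
            dq = quaternion_derivatives(fit, xfit, self.frame.reference_positions,
                                        self._w)  # (m, 3, 4)
            dR = _dR_dq(fit.quaternion)  # (4, 3, 3)
            shifted = positions - (center if self.frame.fit_translation else 0.0)
            # M[k,l] = sum_i ginner_i . (dR/dq_m)_{:,l'} ... contract once:
            # T_m = sum_i ginner_i^T dR_m shifted_i  (scalar per quaternion comp)
            T = np.einsum("ia,mab,ib->m", ginner, dR, shifted)  # (4,)
            rot = dq @ T  # (m, 3)
            for i, idx in enumerate(fg.indices):
                g[idx] += rot[i]
        return value, g


class PolynomialCombination(Component):
    """Weighted sum of powers of child components: sum_i c_i zeta_i^p_i."""

    def __init__(self, components, coefficients, exponents):
        self.components = list(components)
        self.coefficients = [float(c) for c in coefficients]
        self.exponents = [int(p) for p in exponents]
        if not (len(self.components) == len(self.coefficients)
                == len(self.exponents)):
            raise ValueError("components/coefficients/exponents length mismatch")
        if any(p < 1 for p in self.exponents):
            raise ValueError("exponents must be >= 1")

    def evaluate(self, positions):
        total = 0.0
        g = np.zeros_like(np.asarray(positions, dtype=float))
        for comp, c, p in zip(self.components, self.coefficients, self.exponents):
            v, gv = comp.evaluate(positions)
            total += c * v ** p
            g += (c * p * v ** (p - 1)) * gv
        return total, g
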