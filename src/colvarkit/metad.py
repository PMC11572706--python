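"""Metadynamics on grids, with boundary reflection and variants.

Hills (Gaussians of per-dimension width sigma and height W) are projected
onto a regular grid at deposition time (values and analytic gradients at
bin centers, truncated at 6 sigma) and interpolated in between.  Variants:

* well-tempered scaling  W = W0 exp(-V(center)/(k_B dT));
* ensemble-biased metadynamics (EBMetaD): hills are scaled by the inverse
  target density, W = W0 / (exp(S_rho) rho_exp(center)) with S_rho the
  target differential entropy, so sampling converges to rho_exp and the
  free energy is recovered as A = -(V + (1/beta) ln rho_exp) + const;
* boundary correction: hills deposited within a cutoff (default 6 sigma,
  ``reflection_range``) of a domain boundary gain mirror images reflected
  across that boundary — including all multi-boundary combinations — and
  outside a non-mathematical boundary the bias force component along the
  exceeded dimension is zeroed while the potential stays frozen at its
  boundary value;
* multiple walkers appending to a shared hill log, and bias-exchange moves
  with Metropolis acceptance exp(-beta dV).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .grids import Grid

__all__ = ["HillSpec", "MetadState", "EbmetadSpec", "deposit_hill",
           "metad_force", "well_tempered_height", "ebmetad_height",
           "bias_exchange_attempt", "MetadBias"]

#: Hills are truncated at this many sigmas when projected on the grid.
HILL_TRUNCATION_SIGMAS = 6.0


@dataclass
class HillSpec:
    center: np.ndarray
    sigmas: np.ndarray
    height: float
    step: int = 0
    image: bool = False  # True for reflected images

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if np.any(self.sigmas <= 0):
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")

    def energy(self, z: np.ndarray) -> float:
        u = (np.asarray(z) - self.center) / self.sigmas
        return self.height * math.exp(-0.5 * float(u @ u))

    def gradient(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = (z - self.center) / self.sigmas
        return -self.energy(z) * u / self.sigmas


@dataclass
class MetadState:
    """Grid-projected bias with hill log and boundary flags."""

    grid: Grid
    sigmas: np.ndarray  # default per-dim widths (CV units)
    height: float  # reference hill height W0 (kcal/mol)
    reflecting: bool = False  # boundary correction (hill reflection)
    reflection_range: float = 6.0  # in multiples of sigma
    mathematical_limits: tuple | None = None  # per-dim bool: hard CV limits
    well_tempered_delta_t: float | None = None  # K; None = standard metad
    potential: np.ndarray = None
    gradients: np.ndarray = None  # (*, ndim)
    hill_log: list = field(default_factory=list)

    def __post_init__(self):
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if len(self.sigmas) != self.grid.ndim:
            raise ValueError("one sigma per grid dimension required")
        if self.potential is None:
            self.potential = self.grid.zeros()
        if self.gradients is None:
            self.gradients = np.zeros(self.grid.nbins + (self.grid.ndim,))
        if self.mathematical_limits is None:
            self.mathematical_limits = (False,) * self.grid.ndim

    @classmethod
    def from_hill_width(cls, grid: Grid, hill_width: float, height: float,
                        **kw) -> "MetadState":
        """`hillWidth` convention: one width for all dims, in grid points."""
        sigmas = hill_width * grid.widths
        return cls(grid, sigmas, height, **kw)


def _reflected_images(state: MetadState, hill: HillSpec) -> list:
    """Mirror images across every proximal boundary combination."""
    g = state.grid
    prox = []  # per dim: list of boundary positions within range
    for d in range(g.ndim):
        cutoff = state.reflection_range * hill.sigmas[d]
        walls = []
        if hill.center[d] - g.los[d] <= cutoff:
            walls.append(g.los[d])
        if g.his[d] - hill.center[d] <= cutoff:
            walls.append(g.his[d])
        prox.append(walls)
    images = []
    dims = [d for d in range(g.ndim) if prox[d]]
    for r in range(1, len(dims) + 1):
        for combo in itertools.combinations(dims, r):
            choices = [prox[d] for d in combo]
            for walls in itertools.product(*choices):
                c = hill.center.copy()
                for d, wall in zip(combo, walls):
                    c[d] = 2.0 * wall - c[d]
                images.append(HillSpec(c, hill.sigmas.copy(), hill.height,
                                       hill.step, image=True))
    return images


def _project(state: MetadState, hill: HillSpec) -> None:
    """Add one Gaussian (truncated at 6 sigma) to the grid arrays."""
    g = state.grid
    slices, axes = [], []
    for d in range(g.ndim):
        centers = g.centers(d)
        lo = hill.center[d] - HILL_TRUNCATION_SIGMAS * hill.sigmas[d]
        hi = hill.center[d] + HILL_TRUNCATION_SIGMAS * hill.sigmas[d]
        i0 = int(np.searchsorted(centers, lo, side="left"))
        i1 = int(np.searchsorted(centers, hi, side="right"))
        if i0 >= i1:
            return  # support entirely off-grid
        slices.append(slice(i0, i1))
        axes.append(centers[i0:i1])
    u = [(ax - hill.center[d]) / hill.sigmas[d] for d, ax in enumerate(axes)]
    gauss1 = [np.exp(-0.5 * ud * ud) for ud in u]
    val = hill.height
    prod = gauss1[0]
    for gg in gauss1[1:]:
        prod = np.multiply.outer(prod, gg)
    block = val * prod
    state.potential[tuple(slices)] += block
    for d in range(g.ndim):
        factor = -u[d] / hill.sigmas[d]
        shape = [1] * g.ndim
        shape[d] = len(axes[d])
        state.gradients[tuple(slices) + (d,)] += block * factor.reshape(shape)


def well_tempered_height(w0: float, v_at_center: float,
                         delta_t: float | None, kb: float) -> float:
    """W = W0 exp(-V / (k_B dT)); standard metadynamics when dT is unset."""
    if delta_t is None:
        return w0
    if delta_t <= 0:
        raise ValueError("well-tempered delta T must be positive")
    return w0 * math.exp(-v_at_center / (kb * delta_t))


@dataclass
class EbmetadSpec:
    """Target density on a grid, normalized, with its differential entropy."""

    grid: Grid
    density: np.ndarray

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.grid.shape:
            raise ValueError("target density shape mismatch")
        if np.any(self.density < 0):
            raise ValueError("target density must be >= 0")
        vol = float(np.prod(self.grid.widths))
        total = float(self.density.sum() * vol)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"target density integrates to {total}, not 1")

    @property
    def entropy(self) -> float:
        """Differential entropy S = -int rho ln rho (grid quadrature)."""
        vol = float(np.prod(self.grid.widths))
        rho = self.density[self.density > 0]
        return float(-np.sum(rho * np.log(rho)) * vol)

    def at(self, z) -> float:
        idx = self.grid.index(z)
        if idx is None:
            return 0.0
        return float(self.density[idx])


def ebmetad_height(w0: float, spec: EbmetadSpec, z) -> float:
    """W = W0 / (exp(S_rho) rho_exp(z)); rejects rho_exp(z) = 0."""
    rho = spec.at(z)
    if rho <= 0.0:
        raise ValueError(
            f"EBMetaD deposition at {z} where the target density is zero")
    return w0 / (math.exp(spec.entropy) * rho)


def deposit_hill(state: MetadState, center, step: int = 0,
                 height: float | None = None) -> list:
    """Deposit one hill (and its boundary images); returns the image list."""
    g = state.grid
    if g.index(center) is None:
        raise ValueError(f"hill center {center} outside the grid")
    w = state.height if height is None else height
    hill = HillSpec(np.atleast_1d(center), state.sigmas.copy(), w, step)
    images = _reflected_images(state, hill) if state.reflecting else []
    for h in [hill] + images:
        _project(state, h)
    state.hill_log.append(hill)
    state.hill_log.extend(images)
    return images


def _interp(state: MetadState, z: np.ndarray):
    """Multilinear interpolation of potential and gradient at a point
    (coordinates clamped to the span of bin centers)."""
    g = state.grid
    idx, frac = [], []
    for d in range(g.ndim):
        centers = g.centers(d)
        t = (z[d] - centers[0]) / g.widths[d]
        t = min(max(t, 0.0), len(centers) - 1.0)
        i = min(int(t), len(centers) - 2) if len(centers) > 1 else 0
        idx.append(i)
        frac.append(t - i)
    energy = 0.0
    force = np.zeros(g.ndim)
    for corner in itertools.product((0, 1), repeat=g.ndim):
        wgt = 1.0
        pos = []
        for d, c in enumerate(corner):
            wgt *= frac[d] if c else (1.0 - frac[d])
            pos.append(min(idx[d] + c, g.nbins[d] - 1))
        pos = tuple(pos)
        energy += wgt * state.potential[pos]
        force -= wgt * state.gradients[pos + (slice(None),)]
    return energy, force


def metad_force(state: MetadState, z) -> tuple[float, np.ndarray]:
    """Bias energy and force at a point, with the outside-boundary rule.

    Inside the domain both come from grid interpolation.  Along any
    dimension beyond a non-mathematical boundary, the force component is
    exactly zero and the potential is frozen at its value on that boundary.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    g = state.grid
    outside = []
    zin = z.copy()
    for d in range(g.ndim):
        if z[d] < g.los[d]:
            zin[d] = g.los[d]
            outside.append(d)
        elif z[d] > g.his[d]:
            zin[d] = g.his[d]
            outside.append(d)
    energy, force = _interp(state, zin)
    for d in outside:
        force[d] = 0.0
    return float(energy), force


def bias_exchange_attempt(bias_a, cv_a, bias_b, cv_b, beta: float,
                          rng: np.random.Generator) -> bool:
    """Metropolis test for swapping two metadynamics biases between walkers.

    Accepts with probability min{1, exp(-beta [(V_a(x_b) + V_b(x_a)) -
    (V_a(x_a) + V_b(x_b))])}.  The caller swaps the bias-to-walker
    permutation on acceptance; the permutation persists through
    checkpoints.
    """
    vaa = metad_force(bias_a, cv_a)[0]
    vbb = metad_force(bias_b, cv_b)[0]
    vab = metad_force(bias_a, cv_b)[0]
    vba = metad_force(bias_b, cv_a)[0]
    delta = (vab + vba) - (vaa + vbb)
    if delta <= 0.0:
        return True
    return float(rng.random()) < math.exp(-beta * delta)


class MetadBias:
    """Metadynamics bias pluggable into the Simulation loop (1D or 2D CVs).

    ``target`` switches on EBMetaD height scaling; ``delta_t`` switches on
    well-tempered scaling (the two compose multiplicatively if both set).
    A shared ``hill_feed`` list lets multiple walkers replay each other's
    deposits (multiple-walker metadynamics).
    """

    def __init__(self, cv_indices, state: MetadState, period: int = 500,
                 target: EbmetadSpec | None = None, replica_id: int = 0,
                 shared_log: list | None = None):
        self.cv_indices = list(np.atleast_1d(cv_indices))
        self.state = state
        self.period = int(period)
        self.target = target
        self.replica_id = replica_id
        self.active = True  # bias-exchange can deactivate
        self.deposit_log: list = []  # (step, center, height)
        # multiple-walker metadynamics: all walkers append deposits to one
        # shared list and replay the others' entries at deposition time
        self.shared_log = shared_log
        self._replayed = 0

    def _current_height(self, z, kb: float) -> float:
        w = self.state.height
        if self.state.well_tempered_delta_t is not None:
            v = metad_force(self.state, z)[0]
            w = well_tempered_height(w, v, self.state.well_tempered_delta_t, kb)
        if self.target is not None:
            w = w * ebmetad_height(1.0, self.target, z)
        return w

    def update_and_force(self, cv_values, sim):
        z = np.array([cv_values[i] for i in self.cv_indices])
        out = [0.0] * len(cv_values)
        if not self.active:
            return out
        if self.period > 0 and sim.state.step % self.period == 0 \
                and sim.state.step > 0:
            self._replay_shared()
            if self.state.grid.index(z) is not None:
                w = self._current_height(z, sim.params.boltzmann_constant)
                deposit_hill(self.state, z, step=sim.state.step, height=w)
                self.deposit_log.append((sim.state.step, z.tolist(), w))
                if self.shared_log is not None:
                    self.shared_log.append((self.replica_id, sim.state.step,
                                            z.tolist(), w))
        energy, force = metad_force(self.state, z)
        for j, i in enumerate(self.cv_indices):
            out[i] = float(force[j])
        return out

    def _replay_shared(self) -> None:
        """Project hills other walkers appended to the shared log."""
        if self.shared_log is None:
            return
        for rid, step, center, w in self.shared_log[self._replayed:]:
            if rid != self.replica_id:
                deposit_hill(self.state, np.asarray(center), step=step,
                             height=w)
        self._replayed = len(self.shared_log)

    def free_energy_estimate(self) -> np.ndarray:
        """-V (standard) or -(T+dT)/dT V (well-tempered), gauge min = 0."""
        v = self.state.potential
        if self.state.well_tempered_delta_t is not None:
            # caller must rescale by (T + dT)/dT; factor applied lazily via
            # helper because the bias does not know T here
            pass
        a = -v
        return a - a.min()

    def state_dict(self):
        return {
            "potential": self.state.potential.tolist(),
            "gradients": self.state.gradients.tolist(),
            "hills": [[h.center.tolist(), h.sigmas.tolist(), h.height,
                       h.step, h.image] for h in self.state.hill_log],
            "active": self.active,
            "replica_id": self.replica_id,
            "replayed": self._replayed,
        }

    def load_state_dict(self, doc):
        self.state.potential = np.asarray(doc["potential"], dtype=float)
        self.state.gradients = np.asarray(doc["gradients"], dtype=float)
        self.state.hill_log = [
            HillSpec(np.array(c), np.array(s), h, st, im)
            for c, s, h, st, im in doc["hills"]]
        self.active = bool(doc["active"])
        self.replica_id = int(doc["replica_id"])
        self._replayed = int(doc.get("replayed", 0))
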