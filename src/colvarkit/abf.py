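"""Adaptive biasing force (ABF) family.

Classic ABF accumulates per-bin running means of the instantaneous
free-energy-gradient estimator and applies minus that mean, ramped in
linearly until a bin holds ``full_samples`` samples.  The extended-system
variant (eABF) couples each CV to a fictitious particle by a stiff spring
and runs ABF on the fictitious coordinate; the CZAR estimator corrects the
extended-system sampling back to the free-energy gradient of the physical
CV.  Multiple walkers ("shared" or mwABF) pool raw sums and counts at a
fixed cadence — each walker keeps its own samples, pooling is exact and
order-independent, and the count-weighted dispersion of per-walker means
provides an error estimate.  A Poisson solver integrates 2D/3D gradient
grids into free-energy surfaces.

lambda-ABF is ABF applied to an alchemical coupling parameter treated as
an extended variable reflected into [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .engine import ExtendedVariable, baoa_step_extended
from .grids import Grid

__all__ = ["AbfState", "abf_update_and_force", "mwabf_share", "SharedAbfResult",
           "EabfState", "czar_estimate", "poisson_integrate",
           "AbfBias", "EabfBias", "LambdaAbfBias"]

DEFAULT_FULL_SAMPLES = 200


def _grow_expansion(partials: list, x: float) -> None:
    """Shewchuk grow-expansion: add x to a list of non-overlapping partials.

    Keeps the accumulated sum *exact* as a sum of doubles, so per-bin force
    sums are independent of accumulation order: pooling walker data in any
    grouping rounds to the bitwise-identical double.
    """
    i = 0
    for y in partials:
        if abs(x) < abs(y):
            x, y = y, x
        hi = x + y
        lo = y - (hi - x)
        if lo:
            partials[i] = lo
            i += 1
        x = hi
    partials[i:] = [x]


@dataclass
class AbfState:
    """Per-bin counts and force sums of one (possibly multi-D) ABF grid.

    Force sums are held as exact (Shewchuk) partial expansions so that
    multiple-walker pooling is associative and order-independent down to
    the last bit.
    """

    grid: Grid
    full_samples: int = DEFAULT_FULL_SAMPLES
    counts: np.ndarray = None
    partials: dict = None  # (flat bin idx, dim) -> list of partial doubles

    def __post_init__(self):
        if self.counts is None:
            self.counts = self.grid.zeros(dtype=np.int64)
        if self.partials is None:
            self.partials = {}

    def copy(self) -> "AbfState":
        return AbfState(self.grid, self.full_samples, self.counts.copy(),
                        {k: list(v) for k, v in self.partials.items()})

    def add_sample(self, idx: tuple, sample: np.ndarray) -> None:
        self.counts[idx] += 1
        for d in range(self.grid.ndim):
            _grow_expansion(self.partials.setdefault((idx, d), []),
                            float(sample[d]))

    def bin_sum(self, idx: tuple, d: int) -> float:
        return math.fsum(self.partials.get((idx, d), ()))

    @property
    def force_sums(self) -> np.ndarray:
        out = np.zeros(self.grid.nbins + (self.grid.ndim,))
        for (idx, d), parts in self.partials.items():
            out[idx + (d,)] = math.fsum(parts)
        return out

    def mean_gradient(self, min_count: int = 1) -> np.ndarray:
        """Per-bin mean gradient; bins below min_count are masked (nan)."""
        sums = self.force_sums
        out = np.full_like(sums, np.nan)
        mask = self.counts >= min_count
        out[mask] = sums[mask] / self.counts[mask][..., None]
        return out


def abf_update_and_force(state: AbfState, z, gradient_sample) -> np.ndarray:
    """Accumulate one sample and return the applied biasing force.

    Outside the grid: no update and zero force.  The applied force is
    -(running mean) scaled by min(1, count / full_samples).
    """
    gs = np.atleast_1d(np.asarray(gradient_sample, dtype=float))
    if not np.all(np.isfinite(gs)):
        raise ValueError("non-finite ABF gradient sample")
    idx = state.grid.index(z)
    if idx is None:
        return np.zeros(state.grid.ndim)
    state.add_sample(idx, gs)
    count = state.counts[idx]
    ramp = min(1.0, count / state.full_samples)
    return -ramp * np.array([state.bin_sum(idx, d)
                             for d in range(state.grid.ndim)]) / count


@dataclass
class SharedAbfResult:
    combined: AbfState
    bin_errors: np.ndarray  # per-bin count-weighted std of walker means


def mwabf_share(states: list) -> SharedAbfResult:
    """Pool walker samples into a combined state plus a dispersion error.

    Sums and counts are added element-wise (pooling is exact: the combined
    state is bitwise what a single walker fed all samples would hold).  The
    per-bin error is the count-weighted standard deviation of the
    per-walker means; walkers with no samples in a bin do not contribute.
    """
    g = states[0].grid
    for st in states[1:]:
        if st.grid != g:
            raise ValueError("walker grids are not congruent")
    combined = AbfState(g, states[0].full_samples)
    for st in states:
        combined.counts += st.counts
        for key, parts in st.partials.items():
            dest = combined.partials.setdefault(key, [])
            for p in parts:
                _grow_expansion(dest, p)
    total = combined.counts
    sums = combined.force_sums
    pooled_mean = np.zeros_like(sums)
    nz = total > 0
    pooled_mean[nz] = sums[nz] / total[nz][..., None]
    var = np.zeros_like(pooled_mean)
    for st in states:
        m = np.zeros_like(pooled_mean)
        wnz = st.counts > 0
        m[wnz] = st.force_sums[wnz] / st.counts[wnz][..., None]
        var += st.counts[..., None] * (m - pooled_mean) ** 2 * wnz[..., None]
    err = np.zeros_like(var)
    err[nz] = np.sqrt(var[nz] / total[nz][..., None])
    # floor at machine precision: walkers with identical data can differ by
    # one ulp in their rounded means, which is not a real dispersion
    err[err < 64.0 * np.finfo(float).eps * (1.0 + np.abs(pooled_mean))] = 0.0
    return SharedAbfResult(combined, err)


# ---------------------------------------------------------------------------
# Extended-system ABF + CZAR
# ---------------------------------------------------------------------------

@dataclass
class EabfState:
    """CZAR bookkeeping for one extended-system CV (1D)."""

    grid: Grid  # over the physical CV z
    abf: AbfState = None  # ABF on the extended coordinate (same grid)
    czar_hist: np.ndarray = None  # counts of z
    czar_lambda_sums: np.ndarray = None  # per-z-bin sums of the extended coord
    czar_z_sums: np.ndarray = None  # per-z-bin sums of z itself

    def __post_init__(self):
        if self.abf is None:
            self.abf = AbfState(self.grid)
        if self.czar_hist is None:
            self.czar_hist = self.grid.zeros(dtype=np.int64)
        if self.czar_lambda_sums is None:
            self.czar_lambda_sums = self.grid.zeros()
        if self.czar_z_sums is None:
            self.czar_z_sums = self.grid.zeros()


def czar_estimate(state: EabfState, beta: float, k_spring: float,
                  min_count: int = 10):
    """CZAR free-energy gradient A'(z) on the grid (1D).

    A'(z) = -(1/beta) d ln rho(z) / dz + k (<lambda>_z - z), with the
    log-density derivative by centered differences (one-sided at the domain
    edges).  The spring term uses the conditional in-bin means of both the
    extended coordinate and z (using the bin center instead of <z>_bin
    introduces a discretization bias amplified by the spring stiffness).
    Bins with fewer than ``min_count`` samples are masked with nan, never
    interpolated.
    """
    if state.grid.ndim != 1:
        raise ValueError("CZAR implemented for 1D grids")
    n = state.grid.nbins[0]
    dz = state.grid.widths[0]
    counts = state.czar_hist.astype(float)
    grad = np.full(n, np.nan)
    ok = state.czar_hist >= min_count
    lnr = np.full(n, np.nan)
    lnr[ok] = np.log(counts[ok])
    for i in range(n):
        if not ok[i]:
            continue
        if 0 < i < n - 1 and ok[i - 1] and ok[i + 1]:
            dln = (lnr[i + 1] - lnr[i - 1]) / (2.0 * dz)
        elif i + 1 < n and ok[min(i + 1, n - 1)] and (i == 0 or not ok[i - 1]):
            dln = (lnr[i + 1] - lnr[i]) / dz
        elif i - 1 >= 0 and ok[i - 1]:
            dln = (lnr[i] - lnr[i - 1]) / dz
        else:
            continue
        lam_mean = state.czar_lambda_sums[i] / counts[i]
        z_mean = state.czar_z_sums[i] / counts[i]
        grad[i] = -dln / beta + k_spring * (lam_mean - z_mean)
    return grad


# ---------------------------------------------------------------------------
# Poisson integration of gradient grids
# ---------------------------------------------------------------------------

def poisson_integrate(grid: Grid, gradients: list, tol: float = 1e-10):
    """Free-energy surface from a gradient field (2D or 3D grids).

    Solves the least-squares integration problem min_A |grad_h A - G|^2 on
    staggered (midpoint-averaged) differences — the normal equations are
    the discrete Poisson equation with Neumann conditions supplied by G.
    The gauge is fixed by min(A) = 0.  Returns (A, residual_norm); raises
    if the conjugate-gradient solver does not converge.
    """
    ndim = grid.ndim
    if ndim not in (2, 3):
        raise ValueError("Poisson integration supports 2D and 3D grids")
    shape = grid.nbins
    n = int(np.prod(shape))
    ops, rhs = [], np.zeros(n)
    for d in range(ndim):
        h = grid.widths[d]
        G = np.asarray(gradients[d], dtype=float)
        if G.shape != shape:
            raise ValueError("gradient grid shape mismatch")
        # staggered forward difference along d: maps nodes -> midpoints
        m = shape[d]
        D1 = sp.diags([-np.ones(m - 1), np.ones(m - 1)], [0, 1],
                      shape=(m - 1, m)) / h
        eyes = [sp.identity(shape[k]) for k in range(ndim)]
        mats = [D1 if k == d else eyes[k] for k in range(ndim)]
        D = mats[0]
        for M in mats[1:]:
            D = sp.kron(D, M)
        D = D.tocsr()
        ops.append(D)
        # midpoint-averaged G along d
        sl_lo = [slice(None)] * ndim
        sl_hi = [slice(None)] * ndim
        sl_lo[d] = slice(0, m - 1)
        sl_hi[d] = slice(1, m)
        Gmid = 0.5 * (G[tuple(sl_lo)] + G[tuple(sl_hi)])
        rhs += D.T @ Gmid.reshape(-1)
    L = sum((D.T @ D for D in ops))
    # Neumann problem: constant nullspace; project it out of the RHS
    rhs -= rhs.mean()
    x, info = spla.cg(L, rhs, rtol=tol, atol=0.0, maxiter=20 * n)
    if info != 0:
        resid = np.linalg.norm(L @ x - rhs)
        raise RuntimeError(f"Poisson CG did not converge (info={info}, "
                           f"residual {resid:.3e})")
    # report the least-squares residual |grad_h A - G_mid|
    res2 = 0.0
    for d, D in enumerate(ops):
        m = shape[d]
        sl_lo = [slice(None)] * ndim
        sl_hi = [slice(None)] * ndim
        sl_lo[d] = slice(0, m - 1)
        sl_hi[d] = slice(1, m)
        G = np.asarray(gradients[d], dtype=float)
        Gmid = 0.5 * (G[tuple(sl_lo)] + G[tuple(sl_hi)])
        res2 += float(np.sum((D @ x - Gmid.reshape(-1)) ** 2))
    A = x.reshape(shape)
    A -= A.min()
    return A, math.sqrt(res2)


# ---------------------------------------------------------------------------
# Bias objects pluggable into the Simulation loop
# ---------------------------------------------------------------------------


def _partials_to_doc(partials: dict) -> list:
    return [[list(idx), d, list(parts)] for (idx, d), parts in partials.items()]


def _partials_from_doc(doc: list) -> dict:
    return {(tuple(int(i) for i in idx), int(d)): [float(p) for p in parts]
            for idx, d, parts in doc}


class AbfBias:
    """Classic ABF on CVs that are linear in the Cartesian coordinates.

    The instantaneous gradient estimator is the bare physical force
    projected on the (constant) CV gradient, sign-flipped — exact for
    linear CVs, where momentum terms vanish from the configurational
    average.
    """

    def __init__(self, cv_index: int, grid: Grid,
                 full_samples: int = DEFAULT_FULL_SAMPLES):
        self.cv_index = cv_index
        self.state = AbfState(grid, full_samples)

    def update_and_force(self, cv_values, sim):
        z = cv_values[self.cv_index]
        grad = sim.last_cv_grads[self.cv_index]
        norm2 = float(np.sum(grad * grad))
        sample = -float(np.sum(sim.last_potential.forces * grad)) / max(norm2, 1e-300)
        f = abf_update_and_force(self.state, z, sample)
        out = [0.0] * len(cv_values)
        out[self.cv_index] = float(f[0])
        return out

    def state_dict(self):
        return {"counts": self.state.counts.tolist(),
                "partials": _partials_to_doc(self.state.partials)}

    def load_state_dict(self, doc):
        self.state.counts = np.asarray(doc["counts"], dtype=np.int64)
        self.state.partials = _partials_from_doc(doc["partials"])


class EabfBias:
    """Extended-system ABF on one CV, with CZAR bookkeeping.

    The CV is tethered to a fictitious particle by a spring of stiffness
    ``coupling``; ABF acts on the fictitious coordinate.  The spring forces
    on the CV and on the extended variable are equal and opposite.
    """

    def __init__(self, cv_index: int, grid: Grid, coupling: float,
                 ext_mass: float | None = None, reflecting: bool = True,
                 full_samples: int = DEFAULT_FULL_SAMPLES,
                 initial_value: float | None = None):
        if coupling <= 0:
            raise ValueError("coupling constant must be positive")
        self.cv_index = cv_index
        self.grid = grid
        self.coupling = coupling
        self.eabf = EabfState(grid)
        self.eabf.abf.full_samples = full_samples
        lo, hi = grid.los[0], grid.his[0]
        if ext_mass is None:
            # mass giving a ~20 fs oscillation period on the spring
            ext_mass = coupling * (20.0 / (2.0 * math.pi)) ** 2
        v0 = 0.5 * (lo + hi) if initial_value is None else initial_value
        self.extended = ExtendedVariable(
            value=v0, fictitious_mass=ext_mass, coupling_constant=coupling,
            lower_bound=lo, upper_bound=hi,
            reflecting_lower=reflecting, reflecting_upper=reflecting)

    def update_and_force(self, cv_values, sim):
        z = cv_values[self.cv_index]
        lam = self.extended.value
        k = self.coupling
        # spring force on the physical CV (propagated to atoms by the engine)
        gf = -k * (z - lam)
        # ABF on the extended coordinate
        sample = k * (lam - z)  # instantaneous dA_ext/dlambda
        abf_force = abf_update_and_force(self.eabf.abf, lam, sample)
        # CZAR histograms in physical-CV bins
        idx = self.grid.index(z)
        if idx is not None:
            self.eabf.czar_hist[idx] += 1
            self.eabf.czar_lambda_sums[idx] += lam
            self.eabf.czar_z_sums[idx] += z
        self._lam_force = k * (z - lam) + float(abf_force[0])
        out = [0.0] * len(cv_values)
        out[self.cv_index] = gf
        return out

    def post_step(self, sim):
        baoa_step_extended(self.extended, sim.params, self._lam_force, sim.rng)

    def czar_gradient(self, params, min_count: int = 10):
        return czar_estimate(self.eabf, params.beta, self.coupling, min_count)

    def state_dict(self):
        return {
            "counts": self.eabf.abf.counts.tolist(),
            "partials": _partials_to_doc(self.eabf.abf.partials),
            "czar_hist": self.eabf.czar_hist.tolist(),
            "czar_lambda_sums": self.eabf.czar_lambda_sums.tolist(),
            "czar_z_sums": self.eabf.czar_z_sums.tolist(),
            "ext_value": self.extended.value,
            "ext_velocity": self.extended.velocity,
        }

    def load_state_dict(self, doc):
        self.eabf.abf.counts = np.asarray(doc["counts"], dtype=np.int64)
        self.eabf.abf.partials = _partials_from_doc(doc["partials"])
        self.eabf.czar_hist = np.asarray(doc["czar_hist"], dtype=np.int64)
        self.eabf.czar_lambda_sums = np.asarray(doc["czar_lambda_sums"], dtype=float)
        self.eabf.czar_z_sums = np.asarray(doc["czar_z_sums"], dtype=float)
        self.extended.value = float(doc["ext_value"])
        self.extended.velocity = float(doc["ext_velocity"])


class LambdaAbfBias:
    """ABF along an alchemical coupling parameter lambda in [0, 1].

    lambda is an extended dynamical variable with reflecting bounds; the
    instantaneous free-energy-gradient estimator is dU/dlambda from the
    coupled potential.  Used as ``Simulation(..., lambda_bias=...)``.
    """

    def __init__(self, grid: Grid, ext_mass: float = 5000.0,
                 full_samples: int = DEFAULT_FULL_SAMPLES,
                 initial_value: float = 0.0):
        self.state = AbfState(grid, full_samples)
        self.extended = ExtendedVariable(
            value=initial_value, fictitious_mass=ext_mass,
            lower_bound=0.0, upper_bound=1.0,
            reflecting_lower=True, reflecting_upper=True)

    def update_and_force_lambda(self, sim) -> float:
        dudl = sim.last_potential.dU_dlambda
        f = abf_update_and_force(self.state, self.extended.value, dudl)
        return float(f[0])

    def free_energy_profile(self, min_count: int = 1):
        """Integrated A(lambda) from the mean-gradient grid (trapezoid on
        bin centers; nan where unsampled)."""
        g = self.state.mean_gradient(min_count)[:, 0]
        dz = self.state.grid.widths[0]
        prof = np.nancumsum(g) * dz
        return prof

    def state_dict(self):
        return {"counts": self.state.counts.tolist(),
                "partials": _partials_to_doc(self.state.partials),
                "ext_value": self.extended.value,
                "ext_velocity": self.extended.velocity}

    def load_state_dict(self, doc):
        self.state.counts = np.asarray(doc["counts"], dtype=np.int64)
        self.state.partials = _partials_from_doc(doc["partials"])
        self.extended.value = float(doc["ext_value"])
        self.extended.velocity = float(doc["ext_velocity"])
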