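"""Path collective variables: progress (s) and tube (zeta).

Two formulations over a discrete chain of N reference nodes:

* the arithmetic (softmax-weighted) form, where
  s = sum_i (i/(N-1)) exp(-lambda D_i) / sum_i exp(-lambda D_i) and
  zeta = -(1/lambda) ln sum_i exp(-lambda D_i), with
  D_i = sum_j c_j (z_j - z_j^(i))^2 the weighted squared distance to node i
  and lambda a smoothing parameter (default: inverse of the mean squared
  inter-node distance).  The exponential sums are max-shifted for
  numerical stability.

* the geometric form, which projects the current point onto the local
  segment geometry around the nearest node using the vectors
  v1 = s_n - z, v2 = z - s_second, v3 = s_n -> s_third, v4 = s_second -> s_n,
  yielding unique values of s and the perpendicular tube distance zeta.
  The sign of the along-path displacement is positive when z lies on the
  lower-index ("left") side of the nearest node.

Both exist in CV space and, through best-fit superposition onto each node
frame, in Cartesian space.

The progress coordinate is normalized so that s(node 0) = 0 and
s(node N-1) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rotation import best_fit_rotation

__all__ = ["PathSpec", "PathValue", "arithmetic_path", "geometric_path",
           "default_lambda", "CartesianPathFrames", "ArithmeticPathCV",
           "GeometricPathCV"]


@dataclass
class PathSpec:
    """Ordered reference nodes in M-dimensional CV space."""

    nodes: np.ndarray  # (N, M)
    weights: np.ndarray | None = None  # c_j, (M,)
    lam: float | None = None  # smoothing parameter

    def __post_init__(self) -> None:
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        n, m = self.nodes.shape
        if n < 2:
            raise ValueError("need at least 2 path nodes")
        if self.weights is None:
            self.weights = np.ones(m)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != m:
                raise ValueError("weights length != CV dimension")
        if np.any(~np.isfinite(self.nodes)):
            raise ValueError("non-finite path nodes")
        if self.lam is None:
            self.lam = default_lambda(self.nodes, self.weights)
        if self.lam <= 0:
            raise ValueError("smoothing parameter lambda must be > 0")


@dataclass
class PathValue:
    s: float
    zeta: float
    nearest_index: int
    s_gradient: np.ndarray | None = None  # d s / d z, (M,)
    zeta_gradient: np.ndarray | None = None


def default_lambda(nodes: np.ndarray, weights: np.ndarray) -> float:
    """Inverse of the mean squared displacement between consecutive nodes."""
    d = np.diff(nodes, axis=0)
    msd = float(np.mean((d * d) @ weights))
    if msd <= 0:
        raise ValueError("degenerate path: coincident consecutive nodes")
    return 1.0 / msd


def arithmetic_path(spec: PathSpec, z) -> PathValue:
    """Softmax-weighted progress and tube variables with gradients."""
    z = np.asarray(z, dtype=float)
    nodes, c, lam = spec.nodes, spec.weights, spec.lam
    n = len(nodes)
    dz = z[None, :] - nodes  # (N, M)
    D = (dz * dz) @ c  # (N,)
    frac = np.arange(n) / (n - 1)
    # max-shifted softmax
    a = -lam * D
    amax = a.max()
    w = np.exp(a - amax)
    wsum = w.sum()
    p = w / wsum
    s = float(p @ frac)
    zeta = float(-(amax + math.log(wsum)) / lam)
    # gradients: dD_i/dz = 2 c * dz_i ; dp_i/dz = p_i (-lam)(dD_i - sum_k p_k dD_k)
    dD = 2.0 * c[None, :] * dz  # (N, M)
    mean_dD = p @ dD
    ds = -lam * ((p * frac) @ dD - s * mean_dD)
    dzeta = mean_dD
    return PathValue(s, zeta, int(np.argmin(D)), ds, dzeta)


def _neighbor_indices(nodes: np.ndarray, z: np.ndarray, c: np.ndarray):
    D = ((z[None, :] - nodes) ** 2) @ c
    n_idx = int(np.argmin(D))  # ties break toward the lower index
    n = len(nodes)
    if n_idx == 0:
        second = 1
    elif n_idx == n - 1:
        second = n - 2
    else:
        second = n_idx - 1 if D[n_idx - 1] <= D[n_idx + 1] else n_idx + 1
    third = 2 * n_idx - second  # mirror neighbor of `second` across nearest
    return n_idx, second, third


def geometric_path(spec: PathSpec, z) -> PathValue:
    """Geometric (unique-valued) progress and tube variables.

    Requires N >= 3 nodes.  At the chain ends the missing third neighbor is
    linearly extrapolated.  Components are measured in the metric scaled by
    sqrt(c_j) so CV weights act as in the arithmetic form.
    """
    z = np.asarray(z, dtype=float)
    nodes, c = spec.nodes, spec.weights
    n = len(nodes)
    if n < 3:
        raise ValueError("geometric path needs at least 3 nodes")
    sq = np.sqrt(c)
    zs = z * sq
    ns = nodes * sq[None, :]
    n_idx, second, third = _neighbor_indices(nodes, z, c)
    s_n = ns[n_idx]
    s_sec = ns[second]
    if 0 <= third < n:
        s_thr = ns[third]
    else:
        s_thr = 2.0 * s_n - s_sec  # extrapolate past the chain end
    v1 = s_n - zs
    v2 = zs - s_sec
    v3 = s_thr - s_n
    v4 = s_n - s_sec
    v3n2 = float(v3 @ v3)
    v13 = float(v1 @ v3)
    root2 = v13 * v13 - v3n2 * float(v1 @ v1 - v2 @ v2)
    root = math.sqrt(max(0.0, root2))
    b = (root - v13) / v3n2 - 1.0
    sign = 1.0 if second < n_idx else -1.0
    s = (n_idx + sign * b / 2.0) / (n - 1)
    f = abs(b) / 2.0
    wvec = v1 - f * v4
    zeta = float(np.linalg.norm(wvec))

    # gradients w.r.t. z (chain through the scaled metric at the end)
    # droot2/dz = 2 v13 (-v3) - v3n2 (-2 v1 - 2 v2) [since dv1/dzs=-I, dv2/dzs=+I]
    if root > 1e-12:
        droot = (-v13 * v3 + v3n2 * (v1 + v2)) / root
    else:
        droot = np.zeros_like(v1)
    db = (droot + v3) / v3n2
    ds = sign * db / (2.0 * (n - 1))
    if zeta > 1e-10:
        sgn_b = 1.0 if b >= 0 else -1.0
        # d wvec/d zs = -I - (sgn_b/2) v4 (db)^T
        dzeta = (-wvec - 0.5 * sgn_b * (wvec @ v4) * db) / zeta
    else:
        dzeta = np.zeros_like(v1)
    return PathValue(float(s), zeta, n_idx, ds * sq, dzeta * sq)


# ---------------------------------------------------------------------------
# Cartesian-space variants
# ---------------------------------------------------------------------------

class CartesianPathFrames:
    """Maps system coordinates into per-node aligned Cartesian CV vectors.

    Each node is a reference frame; the configuration is superposed onto a
    node's frame by the best-fit translation + rotation of the path atoms,
    and the flattened aligned coordinates act as the CV vector.  With this
    mapping the Cartesian path variants reduce exactly to the CV-space
    forms evaluated on aligned coordinates.
    """

    def __init__(self, frames: np.ndarray, align_index: int = 0):
        self.frames = np.asarray(frames, dtype=float)  # (N, n_atoms, 3)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (N, n_atoms, 3)")
        self.align_index = align_index

    def spec(self, lam: float | None = None) -> PathSpec:
        # nodes live in the same aligned frame as cv_vector output
        nvec = np.stack([self.cv_vector(f) for f in self.frames])
        return PathSpec(nvec, lam=lam)

    def cv_vector(self, positions: np.ndarray) -> np.ndarray:
        """Aligned (onto the align_index node) flattened coordinates."""
        ref = self.frames[self.align_index]
        x = np.asarray(positions, dtype=float)
        fit = best_fit_rotation(x, ref)
        xc = x - x.mean(0)
        aligned = xc @ fit.matrix.T + ref.mean(0)
        return aligned.reshape(-1)


class ArithmeticPathCV:
    """Arithmetic path CV over child CV components (aspathCV/azpathCV pair).

    ``evaluate`` returns ((s, zeta), (grad_s, grad_zeta)) as atom gradients.
    """

    def __init__(self, spec: PathSpec, components):
        self.spec = spec
        self.components = list(components)
        if len(self.components) != spec.nodes.shape[1]:
            raise ValueError("one component per CV dimension required")

    def evaluate(self, positions):
        vals, grads = [], []
        for comp in self.components:
            v, g = comp.evaluate(positions)
            vals.append(v)
            grads.append(g)
        pv = arithmetic_path(self.spec, np.array(vals))
        gs = sum(d * g for d, g in zip(pv.s_gradient, grads))
        gz = sum(d * g for d, g in zip(pv.zeta_gradient, grads))
        return pv, (gs, gz)


class GeometricPathCV(ArithmeticPathCV):
    """Geometric path CV over child components (gspathCV/gzpathCV pair)."""

    def evaluate(self, positions):
        vals, grads = [], []
        for comp in self.components:
            v, g = comp.evaluate(positions)
            vals.append(v)
            grads.append(g)
        pv = geometric_path(self.spec, np.array(vals))
        gs = sum(d * g for d, g in zip(pv.s_gradient, grads))
        gz = sum(d * g for d, g in zip(pv.zeta_gradient, grads))
        return pv, (gs, gz)
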