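"""Optimal-superposition rotations via the quaternion overlap eigenproblem.

The rotation minimizing the weighted RMSD between a structure and a
reference is the top eigenvector of the 4x4 overlap (Kearsley) matrix built
from the correlation matrix of centered coordinates.  Because the rotation
is an eigenvector, its derivative with respect to the input coordinates
follows from first-order eigenvector perturbation theory; that derivative is
what propagates biasing forces through moving frames of reference onto the
fitting atoms.

Conventions: quaternions are (q0, q1, q2, q3) with q0 >= 0 (ties broken by
the first nonzero component being positive); ``matrix`` maps *centered
positions* onto the reference frame, i.e. R x' ~= y' minimizes
sum w |R x' - y'|^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RotationFit", "best_fit_rotation", "quaternion_to_matrix",
           "matrix_to_quaternion", "quaternion_derivatives"]

#: Relative eigenvalue-gap threshold below which the fit is flagged degenerate.
DEGENERACY_GAP = 1e-8


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    q0, q1, q2, q3 = q
    return np.array([
        [q0*q0 + q1*q1 - q2*q2 - q3*q3, 2*(q1*q2 - q0*q3), 2*(q1*q3 + q0*q2)],
        [2*(q1*q2 + q0*q3), q0*q0 - q1*q1 + q2*q2 - q3*q3, 2*(q2*q3 - q0*q1)],
        [2*(q1*q3 - q0*q2), 2*(q2*q3 + q0*q1), q0*q0 - q1*q1 - q2*q2 + q3*q3],
    ])


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (q0 >= 0) of a proper rotation matrix."""
    tr = np.trace(R)
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2.0
        q = np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return _fix_sign(q / np.linalg.norm(q))


def _fix_sign(q: np.ndarray) -> np.ndarray:
    for comp in q:
        if comp != 0.0:
            return q if comp > 0 else -q
    return q


def _overlap_from_correlation(C: np.ndarray) -> np.ndarray:
    """Kearsley 4x4 overlap matrix S from the 3x3 correlation matrix C."""
    cxx, cxy, cxz = C[0]
    cyx, cyy, cyz = C[1]
    czx, czy, czz = C[2]
    return np.array([
        [cxx + cyy + czz, cyz - czy, czx - cxz, cxy - cyx],
        [cyz - czy, cxx - cyy - czz, cxy + cyx, cxz + czx],
        [czx - cxz, cxy + cyx, -cxx + cyy - czz, cyz + czy],
        [cxy - cyx, cxz + czx, cyz + czy, -cxx - cyy + czz],
    ])


# dS/dC as a constant sparse map: for each (a, b) entry of C, the 4x4
# matrix of coefficients; built once.
def _build_dS_dC() -> np.ndarray:
    t = np.zeros((3, 3, 4, 4))
    for a in range(3):
        for b in range(3):
            C = np.zeros((3, 3))
            C[a, b] = 1.0
            t[a, b] = _overlap_from_correlation(C)
    return t


_DS_DC = _build_dS_dC()


@dataclass
class RotationFit:
    """Best-fit rotation with the data needed to differentiate it."""

    quaternion: np.ndarray  # (4,)
    matrix: np.ndarray  # (3, 3), maps centered positions onto reference
    rmsd: float
    eigenvalues: np.ndarray  # (4,) ascending
    eigenvectors: np.ndarray  # (4, 4), columns
    degenerate: bool

    def rotate(self, x: np.ndarray) -> np.ndarray:
        return x @ self.matrix.T


def best_fit_rotation(positions: np.ndarray, reference: np.ndarray,
                      weights: np.ndarray | None = None) -> RotationFit:
    """Rotation minimizing the weighted RMSD of positions onto reference.

    Both inputs are centered internally with the same weights.  Degenerate
    geometries (collinear or coincident points, for which the optimal
    rotation is not unique) are flagged via ``fit.degenerate`` rather than
    failing, since downstream force propagation is what breaks there.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError("positions and reference shapes differ")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a unique rotation")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    xc = x - (w[:, None] * x).sum(0) / wsum
    yc = y - (w[:, None] * y).sum(0) / wsum
    C = (w[:, None] * xc).T @ yc
    S = _overlap_from_correlation(C)
    evals, evecs = np.linalg.eigh(S)
    q = _fix_sign(evecs[:, -1])
    lam = evals[-1]
    scale = max(abs(evals[-1]), 1.0)
    degenerate = (evals[-1] - evals[-2]) < DEGENERACY_GAP * scale
    msd = max(0.0, (np.sum(w[:, None] * (xc * xc + yc * yc)) - 2.0 * lam) / wsum)
    R = quaternion_to_matrix(q)
    return RotationFit(q, R, math.sqrt(msd), evals, evecs, degenerate)


def quaternion_derivatives(fit: RotationFit, positions: np.ndarray,
                           reference: np.ndarray,
                           weights: np.ndarray | None = None) -> np.ndarray:
    """dq/dx for every input coordinate: array (n, 3, 4).

    First-order perturbation of the top overlap eigenvector:
    dq = sum_{m<3} (v_m^T dS q) / (lam_top - lam_m) v_m, with dS assembled
    from dC/dx (reference held fixed).  Centering is included: moving atom a
    shifts the common center by w_a / W.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(reference, dtype=float)
    n = len(x)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    yc = y - (w[:, None] * y).sum(0) / wsum
    # dC/dx_{a,k}: C = sum_i w_i (x_i - xbar) yc_i^T; d xbar/dx_{a,k} = w_a/W e_k
    # => dC_{kb}/dx_{a,k} = w_a yc_{a,b} - w_a/W sum_i w_i yc_{i,b};
    # the centering term vanishes because sum_i w_i yc_i = 0.
    evals, evecs = fit.eigenvalues, fit.eigenvectors
    q = fit.quaternion
    # align the stored top eigenvector with the sign-fixed quaternion
    top = evecs[:, -1]
    if float(top @ q) < 0:
        top = -top
    gaps = evals[-1] - evals[:-1]
    if np.any(gaps < DEGENERACY_GAP * max(abs(evals[-1]), 1.0)):
        raise ValueError("degenerate rotation fit: derivative undefined")
    # dS q for each (a, k): dS = sum_b (w_a yc_{a,b}) * _DS_DC[k, b]
    dq = np.zeros((n, 3, 4))
    Sq = np.einsum("abij,j->abi", _DS_DC, q)  # (3, 3, 4): dS/dC_{kb} . q
    for m in range(3):
        vm = evecs[:, m]
        coef = np.einsum("abi,i->ab", Sq, vm) / gaps[m]  # (3, 3)
        # dq_{a,k} += (w_a yc_{a,b} coef[k,b]) vm
        amp = (w[:, None] * (yc @ coef.T))  # (n, 3)
        dq += amp[:, :, None] * vm[None, None, :]
    return dq
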