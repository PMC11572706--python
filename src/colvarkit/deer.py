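"""DEER (double electron-electron resonance) forward model.

The time-domain DEER signal of a nearly isolated spin pair at distance r
(nm) is modeled as

    F(t_d) = [(1 - L1) + L1 k(t_d, r)] exp[-(L2 |t_d|)^(D/3)]

where L1 is the modulation depth, L2 the intermolecular background rate
(1/us), D the sample dimensionality (3 in solution, 2 in a membrane), and
k the dipolar kernel

    k(t, r) = sqrt(pi / (6 w t)) [C(z) cos(w t) + S(z) sin(w t)],
    z = sqrt(6 w t / pi),   w = K_dip / r^3,

with C, S the cosine/sine Fresnel integrals and w the dipolar frequency.
The kernel equals the powder average integral_0^1 cos[(3u^2 - 1) w t] du;
a small-argument series handles w t -> 0 so k(0, r) = 1 exactly.

K_dip = g^2 mu_B^2 mu_0 / (4 pi hbar) for nitroxide g ~ 2.0023, in units
rad us^-1 nm^3.  Ensemble traces average the kernel inside the bracket:
<F> = [(1 - L1) + L1 <k>] * background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.optimize import least_squares

__all__ = ["DIPOLAR_CONSTANT", "DeerModel", "deer_kernel", "deer_signal",
           "average_signal", "fit_background", "BackgroundFit"]


def _dipolar_constant() -> float:
    g = 2.0023  # nitroxide electron g-factor
    mu_b = 9.2740100657e-24  # Bohr magneton, J/T
    mu_0 = 1.25663706127e-6  # vacuum permeability, T^2 m^3 / J
    hbar = 1.054571817e-34  # J s
    k_si = g * g * mu_b * mu_b * mu_0 / (4.0 * np.pi * hbar)  # m^3 rad/s
    return k_si * 1.0e27 * 1.0e-6  # -> nm^3 rad/us


#: Dipolar coupling constant for nitroxide spin labels, rad us^-1 nm^3.
DIPOLAR_CONSTANT = _dipolar_constant()

#: Below this w*t the series expansion of the powder average is used.
_SERIES_THRESHOLD = 1e-4


@dataclass
class DeerModel:
    """Time grid and experimental parameters of a DEER trace."""

    t_grid: np.ndarray  # microseconds
    lambda1: float = 0.3  # modulation depth, in [0, 1]
    lambda2: float = 0.05  # background rate, 1/us
    dimensionality: int = 3  # 3 solution, 2 membrane
    dipolar_constant: float = field(default=DIPOLAR_CONSTANT)

    def __post_init__(self) -> None:
        self.t_grid = np.atleast_1d(np.asarray(self.t_grid, dtype=float))
        if not np.all(np.isfinite(self.t_grid)):
            raise ValueError("non-finite time grid")
        if not 0.0 <= self.lambda1 <= 1.0:
            raise ValueError("modulation depth must lie in [0, 1]")
        if self.lambda2 < 0:
            raise ValueError("background rate must be >= 0")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")

    def background(self) -> np.ndarray:
        return np.exp(-(self.lambda2 * np.abs(self.t_grid))
                      ** (self.dimensionality / 3.0))


def deer_kernel(t, r: float, dipolar_constant: float = DIPOLAR_CONSTANT):
    """Dipolar kernel k(t, r); t in us (scalar or array), r in nm."""
    if r <= 0:
        raise ValueError("spin-spin distance must be positive")
    t = np.asarray(t, dtype=float)
    w = dipolar_constant / r ** 3
    x = w * np.abs(t)  # dimensionless w t
    out = np.empty_like(x)
    small = x < _SERIES_THRESHOLD
    # series of int_0^1 cos[(3u^2-1)x] du: 1 - (2/5) x^2 + O(x^4)
    xs = x[small]
    out[small] = 1.0 - 0.4 * xs * xs
    xl = x[~small]
    z = np.sqrt(6.0 * xl / np.pi)
    s_fr, c_fr = special.fresnel(z)
    out[~small] = (np.sqrt(np.pi / (6.0 * xl))
                   * (c_fr * np.cos(xl) + s_fr * np.sin(xl)))
    return out if out.ndim else float(out)


def deer_signal(model: DeerModel, r: float) -> np.ndarray:
    """Full time-domain signal F(t_d) for a single distance."""
    k = deer_kernel(model.t_grid, r, model.dipolar_constant)
    return ((1.0 - model.lambda1) + model.lambda1 * k) * model.background()


def average_signal(model: DeerModel, r_series) -> np.ndarray:
    """Ensemble trace: the kernel is averaged inside the bracket."""
    r_series = np.atleast_1d(np.asarray(r_series, dtype=float))
    if r_series.size == 0:
        raise ValueError("empty distance series")
    kbar = np.zeros_like(model.t_grid)
    for r in r_series:
        kbar += deer_kernel(model.t_grid, r, model.dipolar_constant)
    kbar /= len(r_series)
    return ((1.0 - model.lambda1) + model.lambda1 * kbar) * model.background()


@dataclass
class BackgroundFit:
    lambda1: float
    lambda2: float
    cost: float
    residuals: np.ndarray
    success: bool
    message: str


def fit_background(trace, model: DeerModel, kernel_mean=None,
                   initial=(0.5, 0.1)) -> BackgroundFit:
    """Best-fit modulation depth and background rate to a measured trace.

    ``kernel_mean`` is the predicted <k(t_d)> (defaults to the kernel-free
    background-only model, the large-time fitting regime).  Bounded least
    squares with L1 in [0, 1] and L2 >= 0; non-convergence is reported in
    the result, never silently.
    """
    y = np.asarray(trace, dtype=float)
    if y.shape != model.t_grid.shape:
        raise ValueError("trace length does not match the model time grid")
    if y.size < 4:
        raise ValueError("need at least 4 trace points to fit 2 parameters")
    kbar = (np.zeros_like(model.t_grid) if kernel_mean is None
            else np.asarray(kernel_mean, dtype=float))
    texp = np.abs(model.t_grid) ** (model.dimensionality / 3.0)

    def resid(p):
        l1, l2 = p
        return ((1.0 - l1) + l1 * kbar) * np.exp(-(l2 ** (model.dimensionality / 3.0)) * texp) - y

    res = least_squares(resid, x0=np.asarray(initial, dtype=float),
                        bounds=([0.0, 0.0], [1.0, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise RuntimeError(
            f"background fit did not converge: {res.message} "
            f"(cost {res.cost:.3e}, params {res.x})")
    return BackgroundFit(float(res.x[0]), float(res.x[1]), float(res.cost),
                         res.fun, bool(res.success), res.message)


class DeerCV:
    """Vector-valued CV: the DEER signal of the distance between two spin
    centers, one component per time point.  ``kernel_only=True`` gives the
    deerkernel variant (identical to L1 = 1, L2 = 0)."""

    def __init__(self, model: DeerModel, distance_component, kernel_only=False):
        self.model = model
        self.distance = distance_component
        self.kernel_only = bool(kernel_only)

    def evaluate_vector(self, positions):
        r, grad_r = self.distance.evaluate(positions)
        if self.kernel_only:
            vec = deer_kernel(self.model.t_grid, r, self.model.dipolar_constant)
        else:
            vec = deer_signal(self.model, r)
        return vec, r, grad_r
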