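"""Deterministic toy-system fixtures.

Each fixture writes the input files for a reproducible test scenario (a
configuration, and where relevant reference structures, path nodes, target
densities or distance series).  All randomness flows from the caller's
seed, so the same call produces identical files.
"""

from __future__ import annotations

import math
import os

import numpy as np

from .engine import make_rng
from .grids import Grid, write_grid
from .traj import write_xyz

__all__ = ["FIXTURES", "generate_fixture"]


def _write(path, text):
    with open(path, "w") as fh:
        fh.write(text)


def _double_well_1d(outdir, params, seed):
    h = params.get("h", 2.0)
    _write(os.path.join(outdir, "double_well_1d.colvars"), f"""\
engine {{
    potential double_well_1d
    parameter h {h}
    temperature 300.0
    friction 20.0
    timestep 1.0
    seed {seed}
    masses 1.0
    initialPositions -1.0 0.0 0.0
}}
colvar {{
    name x
    distanceZ {{
        atomNumbers 1
        axis 1 0 0
    }}
}}
""")


def _rugged_2d(outdir, params, seed):
    _write(os.path.join(outdir, "rugged_2d.colvars"), f"""\
engine {{
    potential rugged_2d
    parameter a {params.get('a', 0.5)}
    parameter b {params.get('b', 1.0)}
    temperature 300.0
    friction 20.0
    timestep 1.0
    seed {seed}
    masses 1.0
    initialPositions 0.0 0.0 0.0
}}
colvar {{
    name x
    distanceZ {{
        atomNumbers 1
        axis 1 0 0
    }}
}}
colvar {{
    name y
    distanceZ {{
        atomNumbers 1
        axis 0 1 0
    }}
}}
""")


def _flat_with_walls(outdir, params, seed):
    # scaled-down wall-bounded flat landscape: steep half-harmonic walls,
    # small frequent hills (height and sigma follow the wall-artifact
    # demonstration recipe, rescaled to the toy engine)
    lo = params.get("lo", 0.0)
    hi = params.get("hi", 10.0)
    _write(os.path.join(outdir, "flat_with_walls.colvars"), f"""\
engine {{
    potential flat_with_walls
    parameter lo {lo}
    parameter hi {hi}
    parameter k_wall {params.get('k_wall', 100.0)}
    temperature 300.0
    friction 20.0
    timestep 1.0
    seed {seed}
    masses 1.0
    initialPositions {(lo + hi) / 2.0} 0.0 0.0
}}
colvar {{
    name x
    distanceZ {{
        atomNumbers 1
        axis 1 0 0
    }}
}}
metadynamics {{
    colvars x
    lowerBoundary {lo}
    upperBoundary {hi}
    bins 100
    gaussianSigmas 0.2
    hillWeight {params.get('hill_weight', 0.006)}
    newHillFrequency 200
    useHillsReflection on
}}
""")


def _rigid_ligand_cloud(outdir, params, seed):
    """Random rigid cloud plus a rotated/translated copy with known
    rotation (default 30 degrees about z)."""
    rng = make_rng(seed)
    n = int(params.get("n_atoms", 12))
    angle = math.radians(params.get("angle_deg", 30.0))
    ref = rng.normal(size=(n, 3)) * 2.0
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    moved = ref @ R.T + np.asarray(params.get("translation", [1.0, -2.0, 0.5]))
    write_xyz(ref, os.path.join(outdir, "rigid_ligand_reference.xyz"))
    write_xyz(moved, os.path.join(outdir, "rigid_ligand_moved.xyz"))


def _straight_path_nodes(outdir, params, seed):
    n = int(params.get("n_nodes", 11))
    m = int(params.get("dim", 2))
    nodes = np.zeros((n, m))
    nodes[:, 0] = np.linspace(0.0, float(n - 1), n)
    lines = [" ".join("%.14e" % v for v in row) for row in nodes]
    _write(os.path.join(outdir, "straight_path_nodes.txt"),
           "\n".join(lines) + "\n")


def _lambda_dual_well(outdir, params, seed):
    _write(os.path.join(outdir, "lambda_dual_well.colvars"), f"""\
engine {{
    potential lambda_coupled_dual_harmonic
    parameter k_a {params.get('k_a', 1.0)}
    parameter k_b {params.get('k_b', 4.0)}
    temperature 300.0
    friction 20.0
    timestep 1.0
    seed {seed}
    masses 1.0
    initialPositions 0.5 0.0 0.0
}}
colvar {{
    name x
    distanceZ {{
        atomNumbers 1
        axis 1 0 0
    }}
}}
""")


def _deer_distance_series(outdir, params, seed):
    """Gaussian distance fluctuations around a mean spin-spin distance."""
    rng = make_rng(seed)
    n = int(params.get("n_frames", 200))
    mean = params.get("mean_nm", 3.0)
    std = params.get("std_nm", 0.3)
    r = np.clip(rng.normal(mean, std, n), 1.0, None)
    _write(os.path.join(outdir, "deer_distance_series.txt"),
           "\n".join("%.14e" % v for v in r) + "\n")


def _gaussian_mixture_target(outdir, params, seed):
    """Normalized two-Gaussian target density on a double-well domain."""
    grid = Grid.make([params.get("lo", -1.7)], [params.get("hi", 1.7)],
                     [int(params.get("bins", 68))])
    c = grid.centers(0)
    w = grid.widths[0]
    rho = (0.6 * np.exp(-(c - 1.0) ** 2 / (2 * 0.5 ** 2))
           + 0.4 * np.exp(-(c + 1.0) ** 2 / (2 * 0.5 ** 2)))
    rho /= rho.sum() * w
    write_grid(grid, {"density": rho},
               os.path.join(outdir, "gaussian_mixture_target.grid"))


FIXTURES = {
    "double_well_1d": _double_well_1d,
    "rugged_2d": _rugged_2d,
    "flat_with_walls": _flat_with_walls,
    "rigid_ligand_cloud": _rigid_ligand_cloud,
    "straight_path_nodes": _straight_path_nodes,
    "lambda_dual_well": _lambda_dual_well,
    "deer_distance_series": _deer_distance_series,
    "gaussian_mixture_target": _gaussian_mixture_target,
}


def generate_fixture(name: str, outdir, params: dict | None = None,
                     seed: int = 1) -> None:
    """Write one named fixture into outdir (created if missing)."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: "
                         + ", ".join(sorted(FIXTURES)))
    os.makedirs(outdir, exist_ok=True)
    FIXTURES[name](outdir, params or {}, seed)
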