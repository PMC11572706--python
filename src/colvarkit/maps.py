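"""Volumetric-map collective variables.

A map CV sums a scalar field phi(x) (stored on a regular 3D lattice,
interpolated trilinearly) over the atoms of a group — e.g. the number of
molecules inside a region of space when phi is an indicator-like density.
Atoms outside the grid contribute zero value and zero gradient.  Several
map CVs can be combined with per-map weights through the ordinary
polynomial-combination machinery.

Text format (x-fastest order)::

    # colvarkit volumetric map 1
    origin ox oy oz
    spacing dx dy dz
    dimensions nx ny nz
    v(0,0,0) v(1,0,0) ... one value per line or whitespace-separated
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AtomGroup, Component

__all__ = ["VolumetricMap", "MapColvar", "read_map", "write_map"]


@dataclass
class VolumetricMap:
    origin: np.ndarray  # (3,) angstrom
    spacings: np.ndarray  # (3,) angstrom
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacings = np.asarray(self.spacings, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacings <= 0):
            raise ValueError("spacings must be positive")
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite map values")

    @property
    def dimensions(self):
        return self.values.shape

    def interpolate(self, point) -> tuple[float, np.ndarray]:
        """Trilinear value and gradient at a point; zero outside the grid."""
        t = (np.asarray(point, dtype=float) - self.origin) / self.spacings
        idx = np.floor(t).astype(int)
        frac = t - idx
        nx, ny, nz = self.values.shape
        if np.any(idx < 0) or idx[0] >= nx - 1 or idx[1] >= ny - 1 or idx[2] >= nz - 1:
            return 0.0, np.zeros(3)
        i, j, k = idx
        c = self.values[i:i + 2, j:j + 2, k:k + 2]
        fx, fy, fz = frac
        wx = np.array([1.0 - fx, fx])
        wy = np.array([1.0 - fy, fy])
        wz = np.array([1.0 - fz, fz])
        val = float(np.einsum("i,j,k,ijk->", wx, wy, wz, c))
        dx = float(np.einsum("j,k,jk->", wy, wz, c[1] - c[0])) / self.spacings[0]
        dy = float(np.einsum("i,k,ik->", wx, wz, c[:, 1] - c[:, 0])) / self.spacings[1]
        dz = float(np.einsum("i,j,ij->", wx, wy, c[:, :, 1] - c[:, :, 0])) / self.spacings[2]
        return val, np.array([dx, dy, dz])


class MapColvar(Component):
    """Sum of the interpolated map over a group's atoms (optionally
    weighted per atom)."""

    def __init__(self, vmap: VolumetricMap, group: AtomGroup,
                 atom_weights=None):
        self.map = vmap
        self.group = group
        self.atom_weights = (np.ones(len(group)) if atom_weights is None
                             else np.asarray(atom_weights, dtype=float))

    def evaluate(self, positions):
        total = 0.0
        g = np.zeros_like(np.asarray(positions, dtype=float))
        for w, idx in zip(self.atom_weights, self.group.indices):
            v, grad = self.map.interpolate(positions[idx])
            total += w * v
            g[idx] = w * grad
        return total, g


def write_map(vmap: VolumetricMap, path) -> None:
    nx, ny, nz = vmap.dimensions
    with open(path, "w") as fh:
        fh.write("# colvarkit volumetric map 1\n")
        fh.write("origin %.14e %.14e %.14e\n" % tuple(vmap.origin))
        fh.write("spacing %.14e %.14e %.14e\n" % tuple(vmap.spacings))
        fh.write(f"dimensions {nx} {ny} {nz}\n")
        flat = vmap.values.transpose(2, 1, 0).reshape(-1)  # x fastest
        for v in flat:
            fh.write("%.14e\n" % v)


def read_map(path) -> VolumetricMap:
    with open(path) as fh:
        header = fh.readline()
        if "volumetric map" not in header:
            raise ValueError(f"not a colvarkit map file: {path}")
        origin = np.array([float(x) for x in fh.readline().split()[1:4]])
        spacing = np.array([float(x) for x in fh.readline().split()[1:4]])
        dims = [int(x) for x in fh.readline().split()[1:4]]
        data = np.array([float(tok) for line in fh for tok in line.split()])
    if data.size != dims[0] * dims[1] * dims[2]:
        raise ValueError("map value count does not match dimensions")
    values = data.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return VolumetricMap(origin, spacing, values)
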