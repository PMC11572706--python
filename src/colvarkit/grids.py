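"""Regular multidimensional grids over collective-variable domains.

One :class:`Grid` describes the lattice (per-dimension lower/upper edge and
bin count); data arrays (counts, force sums, bias potentials, target
densities) are plain numpy arrays shaped like the lattice and stored next
to it by the biases.  A shared text format serializes a grid plus named
arrays (one row per bin: bin centers, then values), used for ABF gradients,
metadynamics FES exports and target distributions alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "write_grid", "read_grid"]


@dataclass(frozen=True)
class Grid:
    los: tuple
    his: tuple
    nbins: tuple

    def __post_init__(self):
        if not (len(self.los) == len(self.his) == len(self.nbins)):
            raise ValueError("grid dimension mismatch")
        if any(h <= l for l, h in zip(self.los, self.his)):
            raise ValueError("upper edge must exceed lower edge")
        if any(n < 1 for n in self.nbins):
            raise ValueError("need at least one bin per dimension")

    @classmethod
    def make(cls, los, his, nbins) -> "Grid":
        return cls(tuple(float(x) for x in np.atleast_1d(los)),
                   tuple(float(x) for x in np.atleast_1d(his)),
                   tuple(int(x) for x in np.atleast_1d(nbins)))

    @property
    def ndim(self) -> int:
        return len(self.nbins)

    @property
    def widths(self) -> np.ndarray:
        return (np.array(self.his) - np.array(self.los)) / np.array(self.nbins)

    @property
    def shape(self) -> tuple:
        return self.nbins

    def zeros(self, dtype=float) -> np.ndarray:
        return np.zeros(self.nbins, dtype=dtype)

    def index(self, z) -> tuple | None:
        """Bin multi-index of a point, or None if outside the domain."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        idx = []
        for k in range(self.ndim):
            if not self.los[k] <= z[k] <= self.his[k]:
                return None
            i = int((z[k] - self.los[k]) / self.widths[k])
            idx.append(min(i, self.nbins[k] - 1))
        return tuple(idx)

    def centers(self, dim: int = 0) -> np.ndarray:
        w = self.widths[dim]
        return self.los[dim] + w * (np.arange(self.nbins[dim]) + 0.5)

    def meshcenters(self) -> list:
        return np.meshgrid(*[self.centers(d) for d in range(self.ndim)],
                           indexing="ij")


def write_grid(grid: Grid, arrays: dict, path) -> None:
    """Write named per-bin arrays in the shared text grid format."""
    names = list(arrays)
    flat = {n: np.asarray(a, dtype=float).reshape(-1) for n, a in arrays.items()}
    mesh = [m.reshape(-1) for m in grid.meshcenters()]
    with open(path, "w") as fh:
        fh.write("# colvarkit grid 1\n")
        fh.write(f"# ndim {grid.ndim}\n")
        for d in range(grid.ndim):
            fh.write(f"# dim {grid.los[d]:.14e} {grid.his[d]:.14e} {grid.nbins[d]}\n")
        fh.write("# columns: " + " ".join(
            [f"center{d}" for d in range(grid.ndim)] + names) + "\n")
        for i in range(mesh[0].size):
            row = [m[i] for m in mesh] + [flat[n][i] for n in names]
            fh.write(" ".join("%.14e" % v for v in row) + "\n")


def read_grid(path) -> tuple[Grid, dict]:
    los, his, nbins, names = [], [], [], []
    data = []
    with open(path) as fh:
        first = fh.readline()
        if "colvarkit grid" not in first:
            raise ValueError(f"not a colvarkit grid file: {path}")
        for line in fh:
            if line.startswith("# ndim"):
                continue
            if line.startswith("# dim "):
                toks = line.split()
                los.append(float(toks[2]))
                his.append(float(toks[3]))
                nbins.append(int(toks[4]))
            elif line.startswith("# columns:"):
                names = line.split(":", 1)[1].split()
            elif line.startswith("#"):
                continue
            else:
                data.append([float(t) for t in line.split()])
    grid = Grid.make(los, his, nbins)
    arr = np.array(data)
    ndim = grid.ndim
    out = {}
    for j, name in enumerate(names[ndim:]):
        out[name] = arr[:, ndim + j].reshape(grid.nbins)
    return grid, out
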