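"""Trajectory text formats and running averages.

Two dialects: XYZ for Cartesian positions (element symbols are cosmetic for
toy particles) and a ``.colvars.traj``-style table of CV values per step —
a ``#``-prefixed header naming the columns, then fixed-width scientific
notation rows.  Vector CVs expand into indexed columns (``name_0`` ...).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["write_traj", "read_traj", "write_xyz", "read_xyz",
           "running_average"]

_FMT = "%.14e"


def write_traj(column_names, rows) -> str:
    """Render (step, values...) rows as .colvars.traj text."""
    lines = ["# step " + " ".join(column_names)]
    width = len(column_names)
    for step, values in rows:
        vals = list(np.atleast_1d(np.asarray(values, dtype=float)))
        if len(vals) != width:
            raise ValueError("row width does not match the declared columns")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite CV value at step {step}")
        lines.append("%10d " % step + " ".join(_FMT % v for v in vals))
    return "\n".join(lines) + "\n"


def read_traj(text: str):
    """Parse .colvars.traj text into (column_names, rows)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing .colvars.traj header line")
    names = lines[0].lstrip("#").split()[1:]  # drop 'step'
    rows = []
    for ln in lines[1:]:
        toks = ln.split()
        if len(toks) != len(names) + 1:
            raise ValueError(f"bad column count in line: {ln!r}")
        rows.append((int(toks[0]), np.array([float(t) for t in toks[1:]])))
    return names, rows


def expand_columns(cv_names, cv_values) -> tuple[list, list]:
    """Flatten vector CVs into indexed column names + scalar values."""
    names, vals = [], []
    for name, v in zip(cv_names, cv_values):
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 1:
            names.append(name)
            vals.append(float(arr[0]))
        else:
            for i, x in enumerate(arr):
                names.append(f"{name}_{i}")
                vals.append(float(x))
    return names, vals


def write_xyz(frames, path, element: str = "X", comment: str = "") -> None:
    """Write one or more (n, 3) frames as multi-frame XYZ."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(frame)}\n{comment}\n")
            for row in frame:
                fh.write(f"{element} " + " ".join(_FMT % v for v in row) + "\n")


def read_xyz(path) -> np.ndarray:
    """Read a multi-frame XYZ file -> (n_frames, n_atoms, 3)."""
    frames = []
    with open(path) as fh:
        while True:
            first = fh.readline()
            if not first.strip():
                break
            n = int(first)
            fh.readline()  # comment
            rows = []
            for _ in range(n):
                toks = fh.readline().split()
                rows.append([float(t) for t in toks[1:4]])
            frames.append(rows)
    if not frames:
        raise ValueError("empty XYZ file")
    return np.asarray(frames, dtype=float)


def running_average(series, window: int, cumulative: bool = False):
    """Right-aligned running mean of a series.

    ``cumulative=True`` (or a window longer than the series) averages all
    values seen so far; otherwise a sliding window of the given length.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if cumulative or window > len(x):
        return np.cumsum(x) / np.arange(1, len(x) + 1)
    out = np.empty_like(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(len(x)):
        j = max(0, i - window + 1)
        out[i] = (c[i + 1] - c[j]) / (i + 1 - j)
    return out
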