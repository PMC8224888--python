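"""Plain-text I/O for gridded fields, ABF state, and trajectories.

Gridded-field format (bit-exact round trip):

    # axis 1 <lower> <upper> <width>
    # axis 2 <lower> <upper> <width>
    # axis 3 <lower> <upper> <width>        (omitted for 2-D fields)
    i<TAB>j<TAB>k<TAB>value<TAB>mask

with zero-based integer bin indices in lexicographic (i, j, k) order and
mask 0/1. Floats are printed with 17 significant digits so that
write-then-read reproduces them bit for bit.

The ABF state file uses the same header with per-bin columns
``i j k count fsum1 fsum2 fsum3``; trajectories are TSV with columns
``step d1 d2 d3`` (Å).
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np

from .grids import FreeEnergyField, GridSpec, ProbabilityField, ScalarField

__all__ = [
    "write_field",
    "read_field",
    "write_abf_state",
    "read_abf_state",
    "write_trajectory",
    "read_trajectory",
]

_F = "%.17g"


def _grid_header(grid: GridSpec) -> str:
    lines = []
    for a in range(grid.ndim):
        lines.append(
            "# axis %d %s %s %s"
            % (a + 1, _F % grid.lower[a], _F % grid.upper[a], _F % grid.width)
        )
    return "\n".join(lines)


def _parse_header(lines: list[str]) -> tuple[GridSpec, int]:
    lower, upper = [], []
    width = None
    n_axes = 0
    for line in lines:
        if not line.startswith("# axis"):
            break
        _, _, idx, lo, hi, w = line.split()
        if int(idx) != n_axes + 1:
            raise ValueError("axis header lines out of order")
        lower.append(float(lo))
        upper.append(float(hi))
        width = float(w)
        n_axes += 1
    if n_axes < 2:
        raise ValueError("missing axis header lines")
    return GridSpec(tuple(lower), tuple(upper), width), n_axes


def write_field(field: ScalarField, path) -> None:
    grid = field.grid
    rows = [_grid_header(grid)]
    for idx in itertools.product(*(range(n) for n in grid.shape)):
        rows.append(
            "\t".join(str(i) for i in idx)
            + "\t" + (_F % field.values[idx])
            + "\t" + str(int(field.mask[idx]))
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_field(path, kind: str = "scalar") -> ScalarField:
    """Read a gridded field; ``kind`` is 'scalar', 'probability' or 'energy'."""
    lines = Path(path).read_text().splitlines()
    grid, n_axes = _parse_header(lines)
    values = np.zeros(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    for line in lines[n_axes:]:
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        idx = tuple(int(p) for p in parts[:n_axes])
        values[idx] = float(parts[n_axes])
        mask[idx] = bool(int(parts[n_axes + 1]))
    cls = {"scalar": ScalarField, "probability": ProbabilityField,
           "energy": FreeEnergyField}[kind]
    return cls(grid, values, mask)


def write_abf_state(state, path) -> None:
    """Write per-bin count and force-sum accumulators (see abf.ABFGridState)."""
    grid = state.params.grid
    rows = [_grid_header(grid), "# step %d" % state.step]
    for idx in itertools.product(*(range(n) for n in grid.shape)):
        rows.append(
            "\t".join(str(i) for i in idx)
            + "\t%d" % state.counts[idx]
            + "".join("\t" + (_F % state.force_sum[idx + (a,)]) for a in range(3))
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_abf_state(path, params):
    """Read accumulators into a fresh ABFGridState with the given params."""
    from .abf import ABFGridState

    lines = Path(path).read_text().splitlines()
    grid, n_axes = _parse_header(lines)
    if grid != params.grid:
        raise ValueError("state file grid does not match params.grid")
    state = ABFGridState.empty(params)
    for line in lines[n_axes:]:
        if not line:
            continue
        if line.startswith("# step"):
            state.step = int(line.split()[2])
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        idx = tuple(int(p) for p in parts[:n_axes])
        state.counts[idx] = int(parts[n_axes])
        for a in range(3):
            state.force_sum[idx + (a,)] = float(parts[n_axes + 1 + a])
    return state


def write_trajectory(trajectory: np.ndarray, path) -> None:
    """TSV with columns step, d1, d2, d3 (Å), 17 significant digits."""
    with open(path, "w") as fh:
        fh.write("step\td1\td2\td3\n")
        for row in trajectory:
            fh.write(
                "%d\t%s\t%s\t%s\n"
                % (int(row[0]), _F % row[1], _F % row[2], _F % row[3])
            )


def read_trajectory(path) -> np.ndarray:
    """Read a reaction-coordinate time series.

    Accepts the package's own 4-column format (step, d1, d2, d3) and the
    5-column shape MD colvars output takes (step, time, d1, d2, d3); the
    time column, when present, is dropped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue  # header line
            if len(vals) == 4:
                rows.append(vals)
            elif len(vals) == 5:
                rows.append([vals[0], vals[2], vals[3], vals[4]])
            else:
                raise ValueError("expected 4 or 5 columns in trajectory file")
    return np.asarray(rows, dtype=float)
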