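"""Regular rectangular binning of reaction-coordinate space and gridded fields.

The landscape analysis lives on a regular grid over the three base-pair
distances (d1, d2, d3). Bins are half-open ``[lower + k*w, lower + (k+1)*w)``
except the last bin on each axis, which is closed at the upper bound, so the
sampling window ``lower <= d <= upper`` is covered exactly.

Fields carry an explicit per-bin boolean ``mask`` marking visited/defined
bins; unvisited bins hold a placeholder value and are excluded from every
sum, never represented as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "ScalarField",
    "ProbabilityField",
    "FreeEnergyField",
    "RegionSpec",
    "default_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Per-axis lower/upper bounds (Å) and a shared bin width (Å).

    The default study grid is ``4.0 <= d_i <= 9.0`` with width 0.5 Å,
    i.e. 10 bins per axis and 1000 bins in three dimensions.
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    width: float

    def __post_init__(self) -> None:
        lower = tuple(float(x) for x in self.lower)
        upper = tuple(float(x) for x in self.upper)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "width", float(self.width))
        if len(lower) != len(upper) or not lower:
            raise ValueError("lower and upper must have equal, nonzero length")
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        for lo, hi in zip(lower, upper):
            n = (hi - lo) / self.width
            if hi <= lo or abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(
                    "(upper - lower) must be a positive integer multiple of width"
                )

    @property
    def ndim(self) -> int:
        return len(self.lower)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(
            int(round((hi - lo) / self.width))
            for lo, hi in zip(self.lower, self.upper)
        )

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))

    def centers(self, axis: int) -> np.ndarray:
        """Bin-center coordinates along one axis (0-based)."""
        n = self.shape[axis]
        return self.lower[axis] + (np.arange(n) + 0.5) * self.width

    def bin_of(self, d) -> tuple[int, ...] | None:
        """Bin index of a point, or None if outside the grid on any axis.

        Total function: never raises for finite input. The upper bound is
        inclusive (closed last bin).
        """
        d = np.asarray(d, dtype=float)
        idx = []
        for a in range(self.ndim):
            x = d[a]
            if x < self.lower[a] or x > self.upper[a]:
                return None
            k = int((x - self.lower[a]) / self.width)
            if k >= self.shape[a]:  # x == upper exactly
                k = self.shape[a] - 1
            idx.append(k)
        return tuple(idx)

    def dropped(self, keep_axes_zero_based: tuple[int, int]) -> "GridSpec":
        """The 2-D grid obtained by keeping the given (0-based) axes."""
        a, b = keep_axes_zero_based
        return GridSpec(
            lower=(self.lower[a], self.lower[b]),
            upper=(self.upper[a], self.upper[b]),
            width=self.width,
        )


def default_grid() -> GridSpec:
    """The study grid: 4.0–9.0 Å on all three axes, 0.5 Å bins."""
    return GridSpec(lower=(4.0, 4.0, 4.0), upper=(9.0, 9.0, 9.0), width=0.5)


@dataclass
class ScalarField:
    """A real value per grid bin plus a visited/defined mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("masked values must be finite")

    def copy(self) -> "ScalarField":
        return type(self)(self.grid, self.values.copy(), self.mask.copy())

    def same_grid(self, other: "ScalarField") -> bool:
        return self.grid == other.grid


class ProbabilityField(ScalarField):
    """Per-bin probabilities: nonnegative, summing to 1 over masked bins."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.mask.any():
            raise ValueError("no defined bins")
        v = self.values[self.mask]
        if np.any(v < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 over masked bins")
        self.values[~self.mask] = 0.0

    @classmethod
    def from_weights(cls, grid: GridSpec, weights: np.ndarray,
                     mask: np.ndarray | None = None) -> "ProbabilityField":
        """Normalize nonnegative weights into a probability field."""
        w = np.asarray(weights, dtype=float)
        if mask is None:
            mask = w > 0
        mask = np.asarray(mask, dtype=bool)
        total = w[mask].sum()
        if not mask.any() or total <= 0:
            raise ValueError("no defined bins")
        v = np.zeros_like(w)
        v[mask] = w[mask] / total
        return cls(grid, v, mask)


class FreeEnergyField(ScalarField):
    """Per-bin free energies in k_B*T, min-shifted to 0 over masked bins."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.mask.any():
            raise ValueError("no defined bins")
        if abs(self.values[self.mask].min()) > 1e-12:
            raise ValueError("free energy must be min-shifted to zero")
        self.values[~self.mask] = 0.0

    @classmethod
    def from_values(cls, grid: GridSpec, values: np.ndarray,
                    mask: np.ndarray | None = None) -> "FreeEnergyField":
        """Min-shift arbitrary finite values into a free-energy field."""
        v = np.array(values, dtype=float)
        if mask is None:
            mask = np.ones(v.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("no defined bins")
        out = np.zeros_like(v)
        out[mask] = v[mask] - v[mask].min()
        return cls(grid, out, mask)


@dataclass(frozen=True)
class RegionSpec:
    """A cubic region ``low <= d_i <= high`` applied to all axes at once.

    Bin membership is decided on bin centers. With the default grid the
    bound region [4.0, 6.0] selects centers 4.25–5.75 and the unbound
    region [7.0, 9.0] selects centers 7.25–8.75.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("region low must be < high")

    def member_mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean mask over grid bins whose centers lie in the region."""
        per_axis = []
        for a in range(grid.ndim):
            c = grid.centers(a)
            per_axis.append((c >= self.low) & (c <= self.high))
        m = per_axis[0]
        for pa in per_axis[1:]:
            m = np.multiply.outer(m, pa)
        return m


BOUND_REGION = RegionSpec(4.0, 6.0)
UNBOUND_REGION = RegionSpec(7.0, 9.0)
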