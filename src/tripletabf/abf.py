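"""Multidimensional adaptive-biasing-force estimator.

ABF accumulates, per reaction-coordinate bin, the number of samples and
the sum of the instantaneous systematic force components along each
coordinate. The running mean force in a bin estimates -dG/dd there; once
a bin has collected ``full_samples`` samples (200 by default) the negated
mean is applied as a bias, progressively flattening the landscape so that
barriers no longer limit sampling. The free-energy surface is then
recovered from the mean-force gradient field by a global least-squares
integration.

Because the toy coordinates are themselves the dynamical variables, the
instantaneous generalized force is simply the negative gradient of the
potential plus walls — there are no Jacobian correction terms. This is a
documented simplification relative to all-atom ABF on derived collective
variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from . import _kernels
from .dynamics import LangevinParams
from .grids import FreeEnergyField, GridSpec, ProbabilityField, default_grid
from .landscape import CheckpointSeries, probability_from_free_energy
from .potentials import TripletPotential, WallParams
from .thermo import Thermo

__all__ = [
    "ABFParams",
    "ABFGridState",
    "GradientField",
    "ABFRunResult",
    "accumulate",
    "bias_force",
    "mean_force_gradient",
    "integrate_gradient",
    "checkpoint",
    "run_abf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ABFParams:
    """ABF protocol settings.

    full_samples is the per-bin activation threshold: the bias stays
    exactly zero in a bin until that many samples have been collected
    there (hard on/off; optional linear ramp via ``ramp``, off by
    default). Boundary restraints sit outside the grid at
    restraint_low/high with the spring stored in kT/Å².
    """

    grid: GridSpec = field(default_factory=default_grid)
    full_samples: int = 200
    checkpoint_stride: int = 50_000
    restraint_low: float = 3.0
    restraint_high: float = 10.0
    restraint_spring: float = 0.23364421019483617  # 10 pN/Å at 310 K
    ramp: bool = False

    def __post_init__(self) -> None:
        if self.full_samples < 1:
            raise ValueError("full_samples must be >= 1")
        if self.checkpoint_stride < 1:
            raise ValueError("checkpoint_stride must be >= 1")
        lo = min(self.grid.lower)
        hi = max(self.grid.upper)
        if not (self.restraint_low < lo and hi < self.restraint_high):
            raise ValueError("restraints must lie strictly outside the grid")

    @property
    def walls(self) -> WallParams:
        return WallParams(self.restraint_low, self.restraint_high,
                          self.restraint_spring)


@dataclass
class ABFGridState:
    """Per-bin sample counts and accumulated instantaneous-force sums."""

    params: ABFParams
    counts: np.ndarray
    force_sum: np.ndarray
    step: int = 0

    @classmethod
    def empty(cls, params: ABFParams) -> "ABFGridState":
        shape = params.grid.shape
        return cls(
            params=params,
            counts=np.zeros(shape, dtype=np.int64),
            force_sum=np.zeros(shape + (3,)),
        )

    @property
    def total_samples(self) -> int:
        return int(self.counts.sum())


@dataclass
class GradientField:
    """Estimated dG/dd_i (kT/Å) per bin; masked where count >= 1."""

    grid: GridSpec
    g_grad: np.ndarray  # shape grid.shape + (3,)
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.g_grad.shape != self.grid.shape + (3,):
            raise ValueError("gradient shape does not match grid")
        if not np.all(np.isfinite(self.g_grad[self.mask])):
            raise ValueError("masked gradients must be finite")


def accumulate(state: ABFGridState, d, systematic_force) -> ABFGridState:
    """Add one sample (in place): increments the bin count and force sum.

    ``systematic_force`` must be the instantaneous unbiased force along
    each coordinate (potential plus walls, excluding the adaptive bias).
    Out-of-grid samples are discarded.
    """
    idx = state.params.grid.bin_of(d)
    if idx is not None:
        state.counts[idx] += 1
        state.force_sum[idx] += np.asarray(systematic_force, dtype=float)
    state.step += 1
    return state


def bias_force(state: ABFGridState, bin_idx) -> np.ndarray:
    """Adaptive bias in a bin: zero until activation, then -(mean force).

    With the default hard rule the bias switches on exactly at
    full_samples; with ``ramp=True`` it scales linearly with
    count/full_samples below the threshold.
    """
    idx = tuple(bin_idx)
    c = state.counts[idx]
    if c == 0:
        return np.zeros(3)
    mean = state.force_sum[idx] / c
    if c >= state.params.full_samples:
        return -mean
    if state.params.ramp:
        return -(c / state.params.full_samples) * mean
    return np.zeros(3)


def mean_force_gradient(state: ABFGridState) -> GradientField:
    """dG/dd_i estimate per visited bin: the negated running mean force."""
    mask = state.counts >= 1
    grad = np.zeros(state.counts.shape + (3,))
    c = np.where(mask, state.counts, 1)[..., None]
    grad = -state.force_sum / c
    grad[~mask] = 0.0
    return GradientField(grid=state.params.grid, g_grad=grad, mask=mask)


def integrate_gradient(grad: GradientField) -> FreeEnergyField:
    """Least-squares (discrete Poisson) integration of a gradient field.

    Each pair of adjacent masked bins along axis a contributes one
    equation (G[j] - G[i]) / w = (g_a[i] + g_a[j]) / 2 — the midpoint
    rule, exact for quadratic landscapes. The normal equations are solved
    sparsely with one gauge anchor per connected component of the mask
    (components are integrated independently; their relative offsets are
    not determined by the data and a warning is logged), then the result
    is min-shifted to zero. Deterministic for a given input.
    """
    mask = grad.mask
    if not mask.any():
        raise ValueError("no defined bins")
    grid = grad.grid
    ndim = grid.ndim
    structure = ndimage.generate_binary_structure(ndim, 1)
    labels, n_comp = ndimage.label(mask, structure=structure)
    if n_comp > 1:
        msg = f"gradient mask has {n_comp} disconnected components; " \
              "integrating each independently"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    var_id = -np.ones(grid.shape, dtype=np.int64)
    midx = np.argwhere(mask)
    for n, idx in enumerate(midx):
        var_id[tuple(idx)] = n
    n_var = len(midx)

    rows, cols, data, rhs = [], [], [], []
    eq = 0
    w = grid.width
    for a in range(ndim):
        sl_lo = [slice(None)] * ndim
        sl_hi = [slice(None)] * ndim
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        for idx in np.argwhere(pair):
            i = tuple(idx)
            j = list(idx)
            j[a] += 1
            j = tuple(j)
            rows += [eq, eq]
            cols += [var_id[j], var_id[i]]
            data += [1.0, -1.0]
            rhs.append(w * 0.5 * (grad.g_grad[i + (a,)] + grad.g_grad[j + (a,)]))
            eq += 1
    # one gauge anchor per connected component
    for comp in range(1, n_comp + 1):
        first = np.argwhere(labels == comp)[0]
        rows.append(eq)
        cols.append(var_id[tuple(first)])
        data.append(1.0)
        rhs.append(0.0)
        eq += 1

    A = sparse.csr_matrix((data, (rows, cols)), shape=(eq, n_var))
    b = np.asarray(rhs)
    x = spsolve((A.T @ A).tocsc(), A.T @ b)
    x = np.atleast_1d(x)

    g = np.zeros(grid.shape)
    g[mask] = x
    return FreeEnergyField.from_values(grid, g, mask)


def checkpoint(
    state: ABFGridState, thermo: Thermo | None = None
) -> tuple[int, ProbabilityField]:
    """Integrate the current mean-force gradient into (tau, P)."""
    if state.total_samples == 0:
        raise ValueError("no visited bins to checkpoint")
    g = integrate_gradient(mean_force_gradient(state))
    p = probability_from_free_energy(g, thermo)
    return state.step, p


@dataclass
class ABFRunResult:
    """Output of one ABF trial."""

    trajectory: np.ndarray  # rows (step, d1, d2, d3)
    state: ABFGridState
    checkpoints: CheckpointSeries

    @property
    def final_probability(self) -> ProbabilityField:
        return self.checkpoints.fields[-1]


def run_abf(
    potential: TripletPotential,
    dynamics: LangevinParams,
    abf: ABFParams,
    seed: int,
    d0=None,
    thermo: Thermo | None = None,
) -> ABFRunResult:
    """One seeded ABF trial of the toy system.

    Evolves overdamped Langevin dynamics under potential + walls + bias,
    accumulating the ABF state, recording the reaction-coordinate time
    series at ``dynamics.record_stride``, and emitting an integrated-PMF
    probability checkpoint every ``abf.checkpoint_stride`` steps. Fully
    reproducible from the seed.
    """
    grid = abf.grid
    nb = grid.shape[0]
    if grid.shape != (nb, nb, nb):
        raise ValueError("the toy ABF runner expects a cubic grid")
    d0 = np.asarray(d0 if d0 is not None else (6.5, 6.5, 6.5), dtype=float)
    traj, counts, fsum, chk_counts, chk_fsum, ok = _kernels.abf_loop(
        d0, potential.packed(),
        abf.restraint_low, abf.restraint_high, abf.restraint_spring,
        grid.lower[0], grid.upper[0], grid.width, nb,
        abf.full_samples, dynamics.timestep, np.asarray(dynamics.diffusion),
        dynamics.n_steps, dynamics.record_stride, abf.checkpoint_stride,
        int(seed) % (2**31),
    )
    if not ok:
        raise FloatingPointError(
            "ABF dynamics diverged to non-finite coordinates "
            f"(seed={seed}, preset={potential.name})"
        )
    state = ABFGridState(params=abf, counts=counts, force_sum=fsum,
                         step=dynamics.n_steps)
    taus, fields = [], []
    for k in range(chk_counts.shape[0]):
        snap = ABFGridState(params=abf, counts=chk_counts[k],
                            force_sum=chk_fsum[k],
                            step=(k + 1) * abf.checkpoint_stride)
        if snap.total_samples == 0:
            continue
        tau, p = checkpoint(snap, thermo)
        taus.append(tau)
        fields.append(p)
    return ABFRunResult(
        trajectory=traj,
        state=state,
        checkpoints=CheckpointSeries(taus=taus, fields=fields),
    )
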