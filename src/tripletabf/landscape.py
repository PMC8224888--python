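"""Probability/free-energy conversions, binding scores, projections, convergence.

The free-energy landscape G(d1, d2, d3) and the state probability
P(d1, d2, d3) are linked by the Boltzmann relation

    P = exp(-G / kT) / sum_bins exp(-G / kT)
    G = -kT ln P + const,   with min G over sampled bins set to 0.

Because all internal energies are already expressed in kT units, the
conversions below are temperature-free; a Thermo argument is accepted for
callers that track temperature explicitly for reporting.

Binding is scored by probability-weighted mean free energies over the
bound (all d_i in [4, 6] Å) and unbound (all d_i in [7, 9] Å) regions:

    G_bound   = sum_bound G P / sum_bound P
    G_unbound = sum_unbound G P / sum_unbound P
    dG_binding = G_bound - G_unbound

Two-dimensional projections marginalize G as the P-weighted mean over the
dropped axis and then recompute the 2-D P from the projected G by Boltzmann
normalization (not by summing P). Convergence of a run is tracked by the
summed squared difference L between consecutive checkpointed P fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .grids import FreeEnergyField, GridSpec, ProbabilityField, RegionSpec
from .thermo import Thermo

__all__ = [
    "ScoreSet",
    "CheckpointSeries",
    "probability_from_free_energy",
    "free_energy_from_probability",
    "average_probability",
    "binding_scores",
    "project",
    "convergence_series",
    "welch_t_test",
]


@dataclass(frozen=True)
class ScoreSet:
    """Bound/unbound free-energy scores and their gap, in k_B*T."""

    g_bound: float
    g_unbound: float

    @property
    def dg_binding(self) -> float:
        return self.g_bound - self.g_unbound


@dataclass
class CheckpointSeries:
    """Strictly increasing checkpoint times tau with their P fields."""

    taus: list[float]
    fields: list[ProbabilityField]

    def __post_init__(self) -> None:
        if len(self.taus) != len(self.fields):
            raise ValueError("taus and fields must have equal length")
        if any(b <= a for a, b in zip(self.taus, self.taus[1:])):
            raise ValueError("tau must be strictly increasing")
        g0 = self.fields[0].grid if self.fields else None
        if any(f.grid != g0 for f in self.fields):
            raise ValueError("all checkpoints must share one grid")

    def __len__(self) -> int:
        return len(self.taus)


def probability_from_free_energy(
    g: FreeEnergyField, thermo: Thermo | None = None
) -> ProbabilityField:
    """Boltzmann-invert a free-energy field (kT units) into probabilities.

    Unmasked bins receive probability 0 and stay unmasked.
    """
    if not g.mask.any():
        raise ValueError("no defined bins")
    w = np.zeros_like(g.values)
    # subtract the max exponent for numerical stability; cancels on normalization
    gm = g.values[g.mask]
    w[g.mask] = np.exp(-(gm - gm.min()))
    return ProbabilityField.from_weights(g.grid, w, g.mask)


def free_energy_from_probability(
    p: ProbabilityField, thermo: Thermo | None = None
) -> FreeEnergyField:
    """G = -kT ln P + const with min over masked bins set to 0.

    Bins with P = 0 become unmasked rather than infinite.
    """
    mask = p.mask & (p.values > 0)
    if not mask.any():
        raise ValueError("no defined bins with positive probability")
    g = np.zeros_like(p.values)
    g[mask] = -np.log(p.values[mask])
    return FreeEnergyField.from_values(p.grid, g, mask)


def average_probability(trials: Sequence[ProbabilityField]) -> ProbabilityField:
    """Arithmetic per-bin mean of trial probability fields, renormalized.

    A bin is defined in the result if it was visited in at least one trial;
    trials that did not visit a bin contribute probability 0 there.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    grid = trials[0].grid
    if any(t.grid != grid for t in trials):
        raise ValueError("trials must share one grid")
    mean = np.mean([t.values for t in trials], axis=0)
    mask = np.any([t.mask for t in trials], axis=0)
    return ProbabilityField.from_weights(grid, mean, mask)


def binding_scores(
    g: FreeEnergyField,
    p: ProbabilityField,
    bound: RegionSpec | None = None,
    unbound: RegionSpec | None = None,
) -> ScoreSet:
    """Probability-weighted mean G over the bound and unbound regions.

    A bin belongs to a region iff its center satisfies low <= c <= high on
    every axis. Raises if a region carries zero total probability.
    """
    from .grids import BOUND_REGION, UNBOUND_REGION

    bound = bound if bound is not None else BOUND_REGION
    unbound = unbound if unbound is not None else UNBOUND_REGION
    if g.grid != p.grid:
        raise ValueError("G and P must share one grid")

    def _score(region: RegionSpec) -> float:
        m = region.member_mask(g.grid) & g.mask & p.mask
        total = p.values[m].sum()
        if not m.any() or total <= 0:
            raise ValueError("region unsampled")
        return float((g.values[m] * p.values[m]).sum() / total)

    return ScoreSet(g_bound=_score(bound), g_unbound=_score(unbound))


_AXIS_PAIRS = {(1, 2), (2, 3), (1, 3)}


def project(
    g: FreeEnergyField,
    p: ProbabilityField,
    keep_axes: tuple[int, int],
    thermo: Thermo | None = None,
) -> tuple[FreeEnergyField, ProbabilityField]:
    """Marginalize a 3-D landscape onto two axes (1-based pair).

    The projected G(a, b) is the P-weighted mean of G over the dropped
    axis; the projected P(a, b) is recomputed from the projected G by
    Boltzmann normalization. 2-D bins whose column carries zero summed
    probability are unmasked.
    """
    if tuple(keep_axes) not in _AXIS_PAIRS:
        raise ValueError("keep_axes must be one of (1,2), (2,3), (1,3)")
    if g.grid != p.grid or g.grid.ndim != 3:
        raise ValueError("expected matching 3-D fields")
    keep0 = (keep_axes[0] - 1, keep_axes[1] - 1)
    drop = ({0, 1, 2} - set(keep0)).pop()

    pv = np.where(p.mask, p.values, 0.0)
    gv = np.where(g.mask & p.mask, g.values, 0.0)
    psum = pv.sum(axis=drop)
    gp = (gv * pv).sum(axis=drop)
    mask2 = psum > 0
    if not mask2.any():
        raise ValueError("projection has no sampled bins")
    g2 = np.zeros_like(psum)
    g2[mask2] = gp[mask2] / psum[mask2]
    # keep0 is sorted for the valid pairs, so no transpose is needed
    grid2 = g.grid.dropped(keep0)
    g2_field = FreeEnergyField.from_values(grid2, g2, mask2)
    p2_field = probability_from_free_energy(g2_field, thermo)
    return g2_field, p2_field


def convergence_series(
    checkpoints: CheckpointSeries,
) -> list[tuple[float, float]]:
    """Squared-error L between consecutive checkpointed probability fields.

    L(tau, tau - dtau) = sum_bins (P(.; tau) - P(.; tau - dtau))^2, with
    unmasked bins counted as P = 0. Works identically for 3-D fields and
    2-D projections. Returns n_checkpoints - 1 pairs (tau, L).
    """
    if len(checkpoints) < 2:
        raise ValueError("need at least two checkpoints")
    out = []
    for (t0, f0), (t1, f1) in zip(
        zip(checkpoints.taus, checkpoints.fields),
        zip(checkpoints.taus[1:], checkpoints.fields[1:]),
    ):
        a = np.where(f0.mask, f0.values, 0.0)
        b = np.where(f1.mask, f1.values, 0.0)
        out.append((t1, float(((b - a) ** 2).sum())))
    return out


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test.

    Returns (t, p) with Welch–Satterthwaite degrees of freedom. Raises for
    samples of fewer than two values or when both samples are constant.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
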