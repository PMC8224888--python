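"""Ground-truth free-energy oracle: dense Boltzmann quadrature per bin.

For an analytic potential U (in kT) the exact bin free energy is

    G_bin = -ln  (1/V_bin) ∫_bin exp(-U) dV,    min-shifted to 0,

evaluated here with a tensor-product midpoint rule at n_sub points per
axis per bin (default 10, i.e. 1000 quadrature points per bin). This is
the independent reference against which the ABF engine's recovered
landscapes and the Metropolis histograms are validated.
"""

from __future__ import annotations

import numpy as np

from .grids import FreeEnergyField, GridSpec, RegionSpec
from .landscape import ScoreSet, binding_scores, probability_from_free_energy
from .potentials import TripletPotential, WallParams
from .thermo import Thermo

__all__ = ["reference_free_energy", "reference_binding_score"]


def reference_free_energy(
    potential: TripletPotential,
    walls: WallParams | None = None,
    grid: GridSpec | None = None,
    thermo: Thermo | None = None,
    n_sub: int = 10,
) -> FreeEnergyField:
    """Exact (quadrature) bin free energies of a toy potential, in kT.

    The walls argument is accepted for interface symmetry with the
    samplers; on the default grid (inside the walls) it contributes
    nothing. Potentials are expressed directly in kT, so the Boltzmann
    factor is exp(-U) independent of the thermo argument.
    """
    from .grids import default_grid

    grid = grid or default_grid()
    walls = walls or WallParams()
    nb = grid.shape
    # midpoint sub-grid along each axis
    axes = [
        grid.lower[a] + (np.arange(nb[a] * n_sub) + 0.5) * (grid.width / n_sub)
        for a in range(grid.ndim)
    ]
    # common exponent offset: potential at bin centers (cheap coarse scan)
    C1, C2, C3 = np.meshgrid(*(grid.centers(a) for a in range(3)),
                             indexing="ij")
    u0 = float(potential.energy(np.stack([C1, C2, C3], axis=-1)).min())
    # evaluate one slab of bins along axis 0 at a time to bound memory
    bin_mean = np.empty(nb)
    for i in range(nb[0]):
        D1, D2, D3 = np.meshgrid(
            axes[0][i * n_sub:(i + 1) * n_sub], axes[1], axes[2],
            indexing="ij",
        )
        pts = np.stack([D1, D2, D3], axis=-1)
        u = potential.energy(pts) + walls.energy_force(pts)[0]
        w = np.exp(-(u - u0))
        w = w.reshape(n_sub, nb[1], n_sub, nb[2], n_sub)
        bin_mean[i] = w.mean(axis=(0, 2, 4))
    g = -np.log(bin_mean)
    return FreeEnergyField.from_values(grid, g)


def reference_binding_score(
    potential: TripletPotential,
    walls: WallParams | None = None,
    grid: GridSpec | None = None,
    bound: RegionSpec | None = None,
    unbound: RegionSpec | None = None,
    thermo: Thermo | None = None,
    n_sub: int = 10,
) -> ScoreSet:
    """Binding scores of the exact quadrature landscape."""
    g = reference_free_energy(potential, walls, grid, thermo, n_sub)
    p = probability_from_free_energy(g, thermo)
    return binding_scores(g, p, bound, unbound)
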