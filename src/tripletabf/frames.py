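"""Toy structure-frame generation from reaction-coordinate trajectories.

Builds a six-residue pseudo-structure — three codon bases on one strand,
three paired anticodon bases on the other, each base reduced to its
Watson-Crick donor/acceptor atoms — and, for every strided trajectory
point, places the anticodon bases so that the three centroid-to-centroid
base-pair distances equal the recorded (d1, d2, d3) exactly. The codon
side stays fixed; optional Gaussian positional jitter is applied to the
anticodon atoms only, emulating thermal disorder around the recorded
coordinates.
"""

from __future__ import annotations

import numpy as np

from .structure import COMPLEMENT, PAIR_ATOMS, AtomMeta, FrameEnsemble

__all__ = ["build_template", "generate_frames"]

#: centroid spacing between consecutive codon bases along x, Å
_BASE_SPACING = 8.0


def _base_offsets(n_atoms: int) -> np.ndarray:
    """Zero-sum in-plane atom offsets about a base centroid (Å)."""
    if n_atoms == 2:
        return np.array([[0.6, 0.0, 0.0], [-0.6, 0.0, 0.0]])
    angles = np.deg2rad([90.0, 210.0, 330.0])
    off = 0.7 * np.stack(
        [np.cos(angles), np.zeros(3), np.sin(angles)], axis=1
    )
    return off - off.mean(axis=0)  # exactly zero-sum


def build_template(codon: str = "AUG") -> tuple[AtomMeta, np.ndarray]:
    """Atom annotation and codon-side coordinates for a codon string.

    Codon base i (i = 0, 1, 2) is centred at (8 i, 0, 0); the paired
    anticodon base carries the complementary residue and its own
    donor/acceptor atom set, initially at distance 0 offset along +y
    (coordinates filled in per frame by :func:`generate_frames`).
    """
    codon = codon.upper().replace("T", "U")
    if len(codon) != 3 or any(b not in PAIR_ATOMS for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    names, res_names, res_ids, chain_ids, coords = [], [], [], [], []
    for chain, bases in (("C", codon), ("A", [COMPLEMENT[b] for b in codon])):
        for i, base in enumerate(bases):
            atom_names = PAIR_ATOMS[base]
            off = _base_offsets(len(atom_names))
            centroid = np.array([_BASE_SPACING * i, 0.0, 0.0])
            for an, o in zip(atom_names, off):
                names.append(an)
                res_names.append(base)
                res_ids.append(i + 1)
                chain_ids.append(chain)
                coords.append(centroid + o)
    meta = AtomMeta(
        names=tuple(names),
        res_names=tuple(res_names),
        res_ids=tuple(res_ids),
        chain_ids=tuple(chain_ids),
    )
    return meta, np.asarray(coords)


def generate_frames(
    trajectory: np.ndarray,
    stride: int = 1,
    codon: str = "AUG",
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> FrameEnsemble:
    """Toy atomic frames whose base-pair distances match the trajectory.

    Parameters
    ----------
    trajectory : ndarray
        Rows (step, d1, d2, d3) as produced by the samplers; every
        ``stride``-th row becomes one frame (the analogue of saving
        snapshots at a fixed time interval).
    jitter_sigma : float
        Standard deviation (Å) of isotropic Gaussian noise added to each
        anticodon atom coordinate after exact placement.
    """
    traj = np.asarray(trajectory, dtype=float)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride >= len(traj):
        raise ValueError("stride must be smaller than the trajectory length")
    rows = traj[::stride]
    meta, base_coords = build_template(codon)
    chain = np.asarray(meta.chain_ids)
    res_id = np.asarray(meta.res_ids)
    anticodon = chain == "A"

    rng = np.random.default_rng(seed)
    n_frames = len(rows)
    coords = np.broadcast_to(
        base_coords, (n_frames,) + base_coords.shape
    ).copy()
    for pos in range(1, 4):
        sel = anticodon & (res_id == pos)
        coords[:, sel, 1] += rows[:, pos][:, None]
    if jitter_sigma > 0:
        coords[:, anticodon, :] += rng.normal(
            0.0, jitter_sigma, size=coords[:, anticodon, :].shape
        )
    return FrameEnsemble(
        meta=meta,
        coords=coords,
        rcs=rows[:, 1:4].copy(),
        times=rows[:, 0].astype(int),
    )
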