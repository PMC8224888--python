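"""Bin-conditioned structure averaging and PDB I/O.

A "typical" bound or unbound structure is reconstructed by averaging, atom
by atom, all trajectory snapshots whose reaction coordinates fall inside a
chosen bin:

    keep the frame iff  c_i - w/2 <= d_i < c_i + w/2  for i = 1, 2, 3,

then take the per-atom arithmetic mean of coordinates over the kept
frames, with no prior superposition (the simulated system is positionally
restrained, so the global frame is fixed).

The codon-anticodon distance d_i of a frame is recomputed from geometry as
the distance between the centroid of the codon base's Watson-Crick
hydrogen-bond donor/acceptor atoms and the centroid of the paired
anticodon base's set:

    A: N1, N6    U: N3, O4    G: N1, N2, O6    C: N3, N4, O2

File I/O uses biotite; frames travel as multi-model PDB, averaged
structures as single-model PDB with the contributing frame count stored in
the B-factor column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "PAIR_ATOMS",
    "COMPLEMENT",
    "AtomMeta",
    "Frame",
    "FrameEnsemble",
    "BinSelector",
    "read_frames",
    "write_frames",
    "select_frames",
    "average_structure",
    "write_structure",
    "selection_report",
]

#: Watson-Crick hydrogen-bond donor/acceptor atoms per base.
PAIR_ATOMS = {
    "A": ("N1", "N6"),
    "U": ("N3", "O4"),
    "G": ("N1", "N2", "O6"),
    "C": ("N3", "N4", "O2"),
}

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class AtomMeta:
    """Shared per-atom annotation for all frames of one ensemble."""

    names: tuple[str, ...]
    res_names: tuple[str, ...]
    res_ids: tuple[int, ...]
    chain_ids: tuple[str, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class Frame:
    """One snapshot: coordinates plus its reaction-coordinate triple."""

    meta: AtomMeta
    coords: np.ndarray  # (n_atoms, 3), Å
    rc: np.ndarray      # (3,), Å
    time: int = 0
    n_averaged: int = 1


@dataclass
class FrameEnsemble:
    """Time-stamped frames with identical atom ordering."""

    meta: AtomMeta
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    rcs: np.ndarray     # (n_frames, 3)
    times: np.ndarray   # (n_frames,)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.meta, self.coords[i], self.rcs[i],
                     int(self.times[i]))

    def subset(self, keep: np.ndarray) -> "FrameEnsemble":
        keep = np.asarray(keep)
        return FrameEnsemble(self.meta, self.coords[keep],
                             self.rcs[keep], self.times[keep])


@dataclass(frozen=True)
class BinSelector:
    """A reaction-coordinate bin: center (Å per axis) and width (Å)."""

    center: tuple[float, float, float] = (4.5, 4.5, 4.5)
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        object.__setattr__(
            self, "center", tuple(float(c) for c in self.center)
        )

    def contains(self, rc) -> np.ndarray:
        """Half-open membership test, vectorized over leading dims."""
        rc = np.asarray(rc, dtype=float)
        c = np.asarray(self.center)
        h = self.width / 2.0
        return np.all((rc >= c - h) & (rc < c + h), axis=-1)


def compute_rc(
    meta: AtomMeta,
    coords: np.ndarray,
    codon_chain: str = "C",
    anticodon_chain: str = "A",
) -> np.ndarray:
    """Centroid-to-centroid base-pair distances from coordinates.

    For each of the three positions, takes the centroid of the codon
    base's donor/acceptor atom set and of the paired anticodon base's
    set; works on a single frame (n_atoms, 3) or a stack (F, n_atoms, 3).
    """
    chain = np.asarray(meta.chain_ids)
    res_id = np.asarray(meta.res_ids)
    res_name = np.asarray(meta.res_names)
    name = np.asarray(meta.names)
    single = coords.ndim == 2
    xyz = coords[None] if single else coords
    out = np.empty((xyz.shape[0], 3))
    for pos in range(1, 4):
        centroids = []
        for ch in (codon_chain, anticodon_chain):
            sel = (chain == ch) & (res_id == pos)
            if not sel.any():
                raise ValueError(f"no atoms for chain {ch} residue {pos}")
            base = res_name[sel][0]
            ref = np.isin(name, PAIR_ATOMS[base]) & sel
            if not ref.any():
                raise ValueError(
                    f"no donor/acceptor atoms for {base}{pos} in chain {ch}"
                )
            centroids.append(xyz[:, ref].mean(axis=1))
        out[:, pos - 1] = np.linalg.norm(centroids[0] - centroids[1], axis=-1)
    return out[0] if single else out


def _meta_from_atom_array(atoms) -> AtomMeta:
    return AtomMeta(
        names=tuple(atoms.atom_name),
        res_names=tuple(atoms.res_name),
        res_ids=tuple(int(r) for r in atoms.res_id),
        chain_ids=tuple(atoms.chain_id),
    )


def read_frames(path) -> FrameEnsemble:
    """Read a multi-model PDB; rc is recomputed from the geometry."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    meta = _meta_from_atom_array(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    rcs = compute_rc(meta, coords)
    times = np.arange(len(coords))
    return FrameEnsemble(meta=meta, coords=coords, rcs=rcs, times=times)


def _to_atom_array(meta: AtomMeta, coords: np.ndarray,
                   b_factor: float = 0.0) -> bst.AtomArray:
    n = meta.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(meta.names)
    arr.res_name = np.asarray(meta.res_names)
    arr.res_id = np.asarray(meta.res_ids)
    arr.chain_id = np.asarray(meta.chain_ids)
    arr.element = np.asarray([n_[0] for n_ in meta.names])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.add_annotation("occupancy", dtype=float)
    arr.occupancy = np.ones(n)
    arr.add_annotation("b_factor", dtype=float)
    arr.b_factor = np.full(n, float(b_factor))
    return arr


def write_frames(ensemble: FrameEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB."""
    arrays = [
        _to_atom_array(ensemble.meta, ensemble.coords[i])
        for i in range(len(ensemble))
    ]
    pdb = PDBFile()
    pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


def select_frames(ensemble: FrameEnsemble, sel: BinSelector) -> FrameEnsemble:
    """Frames whose rc lies in the selector bin (may be empty)."""
    return ensemble.subset(sel.contains(ensemble.rcs))


def average_structure(ensemble: FrameEnsemble, sel: BinSelector) -> Frame:
    """Per-atom mean structure over the frames selected by ``sel``.

    No superposition is applied before averaging. The returned frame's rc
    is recomputed from the averaged coordinates. Raises if the bin holds
    no frames.
    """
    chosen = select_frames(ensemble, sel)
    if len(chosen) == 0:
        raise ValueError("bin unpopulated")
    mean = chosen.coords.mean(axis=0)
    rc = compute_rc(ensemble.meta, mean)
    return Frame(meta=ensemble.meta, coords=mean, rc=rc,
                 time=int(chosen.times[0]), n_averaged=len(chosen))


def write_structure(frame: Frame, path) -> None:
    """Single-model PDB; B-factor carries the contributing frame count."""
    arr = _to_atom_array(frame.meta, frame.coords,
                         b_factor=float(frame.n_averaged))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def selection_report(ensemble: FrameEnsemble, sel: BinSelector):
    """Per-frame TSV-ready table: index, d1, d2, d3, selected flag."""
    import pandas as pd

    flags = sel.contains(ensemble.rcs)
    return pd.DataFrame(
        {
            "frame": np.arange(len(ensemble)),
            "d1": ensemble.rcs[:, 0],
            "d2": ensemble.rcs[:, 1],
            "d3": ensemble.rcs[:, 2],
            "selected": flags.astype(int),
        }
    )
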