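"""Trajectory container, atom selections, and text-format trajectory I/O.

A trajectory is an ordered stack of frames of labelled 3D coordinates (Å)
with a fixed time step (ns).  Two plain-text dialects are supported:
multi-model PDB (MODEL/ENDMDL) via biotite, and a whitespace coordinate
table of ``n_frames`` blocks of ``n_atoms`` rows x 3 columns.  No binary
formats are read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = ["AtomLabel", "Trajectory", "read_pdb_trajectory", "write_pdb_trajectory",
           "read_coordinate_table", "write_coordinate_table"]

#: atom names making up the protein backbone selection
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_RESID_RANGE_RE = re.compile(r"^resid\s+(\d+)\s*[-:]\s*(\d+)$")


@dataclass(frozen=True)
class AtomLabel:
    """Residue index (1-based) plus atom name, e.g. ``(12, 'CA')``."""

    resid: int
    name: str


@dataclass
class Trajectory:
    """Ordered frames of labelled coordinates.

    Parameters
    ----------
    atom_labels : sequence of AtomLabel
        One label per atom; identical ordering in every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Positions in Å.
    dt : float
        Time between frames in ns (> 0).
    """

    atom_labels: list[AtomLabel]
    coords: np.ndarray
    dt: float = 0.1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atom_labels):
            raise ValueError("atom_labels length does not match coordinate atoms")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> list[int]:
        """Distinct residue indices in order of first appearance."""
        seen: dict[int, None] = {}
        for lab in self.atom_labels:
            seen.setdefault(lab.resid, None)
        return list(seen)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def mask(self, selection: Union[str, Sequence[bool], np.ndarray, None] = None) -> np.ndarray:
        """Resolve a selection into a boolean atom mask.

        Accepted selections: ``None``/``"all"``, ``"backbone"`` (N/CA/C/O),
        ``"heavy"`` (names not starting with H), ``"ca"``, ``"resid A-B"``
        (1-based inclusive residue range), or an explicit boolean array.
        """
        if selection is None:
            return np.ones(self.n_atoms, dtype=bool)
        if isinstance(selection, (list, tuple, np.ndarray)):
            m = np.asarray(selection, dtype=bool)
            if m.shape != (self.n_atoms,):
                raise ValueError("boolean mask has wrong length")
            return m
        sel = selection.strip().lower()
        if sel == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if sel == "backbone":
            return np.array([lab.name.upper() in BACKBONE_NAMES for lab in self.atom_labels])
        if sel == "heavy":
            return np.array([not lab.name.upper().startswith("H") for lab in self.atom_labels])
        if sel == "ca":
            return np.array([lab.name.upper() == "CA" for lab in self.atom_labels])
        m = _RESID_RANGE_RE.match(sel)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            return np.array([lo <= lab.resid <= hi for lab in self.atom_labels])
        raise ValueError(f"unknown selection: {selection!r}")

    def slice_frames(self, start: int, stop: int | None = None) -> "Trajectory":
        return Trajectory(self.atom_labels, self.coords[start:stop].copy(), self.dt)


def read_pdb_trajectory(path: Union[str, Path], dt: float = 0.1) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL, ATOM/HETATM records)."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(f)  # AtomArrayStack: (models, atoms)
    if stack.stack_depth() < 1:
        raise ValueError(f"no models in {path}")
    labels = [AtomLabel(int(r), str(n)) for r, n in zip(stack.res_id, stack.atom_name)]
    return Trajectory(labels, np.asarray(stack.coord, dtype=float), dt)


def write_pdb_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    stack.res_id = np.array([lab.resid for lab in traj.atom_labels])
    stack.atom_name = np.array([lab.name for lab in traj.atom_labels])
    stack.res_name = np.array(["ALA"] * n)
    stack.chain_id = np.array(["A"] * n)
    stack.element = np.array([lab.name[0] for lab in traj.atom_labels])
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))


def read_coordinate_table(
    path: Union[str, Path],
    n_atoms: int,
    dt: float = 0.1,
    atom_labels: Sequence[AtomLabel] | None = None,
) -> Trajectory:
    """Read a plain numeric table of frame blocks (n_atoms rows x 3 columns).

    When ``atom_labels`` is omitted, one CA atom per residue is assumed
    (residues numbered from 1).
    """
    data = np.loadtxt(path, dtype=float)
    data = np.atleast_2d(data)
    if data.shape[1] != 3:
        raise ValueError("coordinate table must have exactly 3 columns")
    if data.shape[0] % n_atoms != 0:
        raise ValueError(f"row count {data.shape[0]} not a multiple of n_atoms={n_atoms}")
    coords = data.reshape(-1, n_atoms, 3)
    if atom_labels is None:
        atom_labels = [AtomLabel(i + 1, "CA") for i in range(n_atoms)]
    return Trajectory(list(atom_labels), coords, dt)


def write_coordinate_table(traj: Trajectory, path: Union[str, Path]) -> None:
    flat = traj.coords.reshape(-1, 3)
    np.savetxt(path, flat, fmt="%.6f")
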