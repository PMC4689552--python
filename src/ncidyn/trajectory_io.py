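"""Reading topologies and trajectories; window/stride selection.

File parsing is delegated to MDAnalysis (PDB, GRO, XTC, DCD,
multi-model PDB).  Everything downstream works in nm and ps; MDAnalysis
reports Å, so coordinates are converted at this boundary.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .topology_model import (
    AtomRecord,
    ResidueRecord,
    Topology,
    assign_donor_hydrogens,
    classify_atom_role,
    classify_residue,
)

__all__ = ["Frame", "Trajectory", "read_topology", "read_trajectory", "select_window"]

ANGSTROM_PER_NM = 10.0


@dataclass
class Frame:
    """One time-stamped coordinate set, lengths in nm."""

    time: float  # ps
    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray | None = None  # orthorhombic edge lengths (3,) nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive edge lengths")


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    source: str = "<memory>"

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.coordinates.shape != (self.topology.n_atoms, 3):
                raise ValueError(
                    f"frame has {f.coordinates.shape[0]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _guess_element(name: str) -> str:
    """Element symbol from a PDB atom name (protein/water context).

    Names beginning with a digit ("1HG1") are hydrogens; otherwise the
    first alphabetic character decides.  Good enough for the C/N/O/S/H
    vocabulary of standard residues and water.
    """
    stripped = name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit():
        return "H"
    return stripped[0].upper()


def _universe_to_topology(universe) -> Topology:
    residues: list[ResidueRecord] = []
    resindex_map: dict[int, int] = {}
    protein_by_chain: dict[str, list[int]] = {}
    for i, res in enumerate(universe.residues):
        name = str(res.resname).strip().upper()
        chain = str(getattr(res, "segid", "") or "A").strip() or "A"
        rec = ResidueRecord(
            index=i,
            name=name,
            chain_id=chain,
            sequence_number=int(res.resid),
            res_class=classify_residue(name),
            is_terminal=False,
        )
        residues.append(rec)
        resindex_map[res.resindex] = i
        if rec.is_protein:
            protein_by_chain.setdefault(chain, []).append(i)
    # mark chain-terminal protein residues
    terminal = {idx for ids in protein_by_chain.values() for idx in (ids[0], ids[-1])}
    residues = [
        ResidueRecord(
            r.index, r.name, r.chain_id, r.sequence_number, r.res_class,
            is_terminal=r.index in terminal,
        )
        for r in residues
    ]

    atoms: list[AtomRecord] = []
    for j, atom in enumerate(universe.atoms):
        name = str(atom.name).strip().upper()
        ri = resindex_map[atom.resindex]
        atoms.append(
            AtomRecord(
                index=j,
                name=name,
                element=_guess_element(name),
                residue_index=ri,
                role=classify_atom_role(name, residues[ri].name),
            )
        )

    coords = np.asarray(universe.atoms.positions, dtype=float) / ANGSTROM_PER_NM
    topo = Topology(
        atoms=atoms,
        residues=residues,
        donor_hydrogens=assign_donor_hydrogens(atoms, coords),
        reference_coordinates=coords,
    )
    topo.validate()
    return topo


def read_topology(path: str, format: str | None = None) -> Topology:
    """Read a PDB or GRO file into a Topology (coordinates in nm)."""
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty topology file: {path}")
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unknown topology format {fmt!r} (expected pdb or gro)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(path, topology_format=fmt, format=fmt)
    return _universe_to_topology(universe)


def _box_from_dimensions(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if dims.size < 3 or np.any(dims[:3] <= 0):
        return None
    return dims[:3] / ANGSTROM_PER_NM


def read_trajectory(
    path: str, topology: Topology, format: str | None = None, topology_path: str | None = None
) -> Trajectory:
    """Read XTC/DCD/multi-model-PDB coordinates against an existing Topology.

    XTC and DCD carry no atom naming, so the original topology file must
    be supplied via ``topology_path`` (a multi-model PDB is self-contained).
    """
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt not in ("xtc", "dcd", "pdb"):
        raise ValueError(f"unknown trajectory format {fmt!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            universe = mda.Universe(path)
        else:
            if topology_path is None:
                raise ValueError(f"{fmt} trajectories need topology_path")
            universe = mda.Universe(topology_path, path)
    if len(universe.atoms) != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {topology.n_atoms}, "
            f"trajectory has {len(universe.atoms)}"
        )
    frames: list[Frame] = []
    last_time = -np.inf
    for ts in universe.trajectory:
        t = float(ts.time)
        if t <= last_time:  # some writers store zero/constant times
            t = last_time + 1.0
        last_time = t
        frames.append(
            Frame(
                time=t,
                coordinates=np.asarray(ts.positions, dtype=float) / ANGSTROM_PER_NM,
                box=_box_from_dimensions(ts.dimensions),
            )
        )
    return Trajectory(topology=topology, frames=frames, source=path)


def select_window(
    trajectory: Trajectory,
    begin_ps: float = 10000.0,
    end_ps: float = 40000.0,
    stride: int = 1,
) -> Trajectory:
    """Restrict to frames with begin ≤ t ≤ end (inclusive), keeping every
    ``stride``-th surviving frame."""
    if begin_ps >= end_ps:
        raise ValueError("begin_ps must be < end_ps")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    kept = [f for f in trajectory.frames if begin_ps <= f.time <= end_ps]
    kept = kept[::stride]
    if not kept:
        raise ValueError("window contains no frames")
    return Trajectory(
        topology=trajectory.topology,
        frames=kept,
        source=f"{trajectory.source}[{begin_ps}:{end_ps}:{stride}]",
    )
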