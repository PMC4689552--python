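"""Synthetic toy topologies and trajectories with fully known contact structure.

The generator builds a protein-like topology (standard PDB atom naming,
donor hydrogens in place, waters appended) whose residues sit on a wide
grid, far beyond every detection cutoff.  Scripted contact schedules
then move one "mobile" atom per schedule into exact on-geometry in the
scheduled frames and to a far-off position otherwise, on top of seeded
sub-margin positional noise.  Because the noise bound (0.02 nm per
atom) is strictly below half the 0.05 nm margins separating on- and
off-geometry from the criteria, detector outcomes are noise-invariant
and the ground-truth manifest is exact, not statistical.

Every generated trajectory is verified frame by frame at generation
time: the detectors must find exactly the scheduled contacts, nothing
else.  A schedule that would produce a side contact (e.g. an acceptor
that is itself a donor, which would create a reverse hydrogen bond) is
rejected with an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contact_dynamics import lifetime_class
from .interaction_detectors import (
    ContactKey,
    ContactKind,
    detect_hbonds_frame,
    detect_hydrophobic_frame,
    detect_saltbridges_frame,
)
from .topology_model import (
    AtomRecord,
    AtomRole,
    ParticipantSets,
    ResClass,
    ResidueRecord,
    Topology,
    assign_donor_hydrogens,
    build_participant_sets,
    classify_atom_role,
    classify_residue,
)
from .trajectory_io import Frame, Trajectory

__all__ = [
    "ContactSchedule",
    "SyntheticSpec",
    "GroundTruth",
    "make_toy_topology",
    "make_scripted_trajectory",
    "make_hb_geometry_frame",
    "hb_probe_system",
    "make_condition_pair",
    "expected_condition_diff",
    "write_topology_pdb",
    "write_multimodel_pdb",
    "write_dcd",
]

# --------------------------------------------------------------------------
# residue templates: atom name -> (element, local offset in nm)
# Hydrogens sit ~0.1 nm from their parent heavy atom and > 0.12 nm from
# every other N/O of the residue, so proximity-based donor attachment
# recovers the intended bonding.

_BACKBONE = [
    ("N", "N", (0.00, 0.00, 0.0)),
    ("H", "H", (0.00, -0.10, 0.0)),
    ("CA", "C", (0.15, 0.00, 0.0)),
    ("C", "C", (0.29, 0.06, 0.0)),
    ("O", "O", (0.29, 0.19, 0.0)),
]

_SIDECHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0.15, 0.14, 0.0))],
    "VAL": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG1", "C", (0.07, 0.26, 0.0)),
        ("CG2", "C", (0.23, 0.26, 0.0)),
    ],
    "LEU": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD1", "C", (0.07, 0.40, 0.0)),
        ("CD2", "C", (0.23, 0.40, 0.0)),
    ],
    "ILE": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG1", "C", (0.07, 0.26, 0.0)),
        ("CG2", "C", (0.23, 0.26, 0.0)),
        ("CD1", "C", (0.07, 0.40, 0.0)),
    ],
    "PRO": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.08, 0.25, 0.0)),
        ("CD", "C", (0.00, 0.14, 0.0)),
    ],
    "PHE": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD1", "C", (0.05, 0.36, 0.0)),
        ("CD2", "C", (0.25, 0.36, 0.0)),
        ("CE1", "C", (0.05, 0.50, 0.0)),
        ("CE2", "C", (0.25, 0.50, 0.0)),
        ("CZ", "C", (0.15, 0.58, 0.0)),
    ],
    "MET": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("SD", "S", (0.15, 0.43, 0.0)),
        ("CE", "C", (0.15, 0.57, 0.0)),
    ],
    "TRP": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD1", "C", (0.04, 0.36, 0.0)),
        ("CD2", "C", (0.26, 0.36, 0.0)),
        ("NE1", "N", (0.08, 0.48, 0.0)),
        ("HE1", "H", (0.02, 0.56, 0.0)),
        ("CE2", "C", (0.21, 0.48, 0.0)),
        ("CE3", "C", (0.38, 0.36, 0.0)),
        ("CZ2", "C", (0.26, 0.60, 0.0)),
        ("CZ3", "C", (0.44, 0.48, 0.0)),
        ("CH2", "C", (0.37, 0.58, 0.0)),
    ],
    "SER": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("OG", "O", (0.15, 0.28, 0.0)),
        ("HG", "H", (0.15, 0.38, 0.0)),
    ],
    "THR": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("OG1", "O", (0.06, 0.25, 0.0)),
        ("HG1", "H", (0.00, 0.33, 0.0)),
        ("CG2", "C", (0.25, 0.25, 0.0)),
    ],
    "CYS": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("SG", "S", (0.15, 0.30, 0.0)),
    ],
    "TYR": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD1", "C", (0.05, 0.36, 0.0)),
        ("CD2", "C", (0.25, 0.36, 0.0)),
        ("CE1", "C", (0.05, 0.50, 0.0)),
        ("CE2", "C", (0.25, 0.50, 0.0)),
        ("CZ", "C", (0.15, 0.58, 0.0)),
        ("OH", "O", (0.15, 0.72, 0.0)),
        ("HH", "H", (0.15, 0.82, 0.0)),
    ],
    "ASN": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("OD1", "O", (0.03, 0.36, 0.0)),
        ("ND2", "N", (0.27, 0.36, 0.0)),
        ("HD21", "H", (0.22, 0.445, 0.0)),
        ("HD22", "H", (0.35, 0.42, 0.0)),
    ],
    "GLN": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD", "C", (0.15, 0.42, 0.0)),
        ("OE1", "O", (0.03, 0.50, 0.0)),
        ("NE2", "N", (0.27, 0.50, 0.0)),
        ("HE21", "H", (0.22, 0.585, 0.0)),
        ("HE22", "H", (0.35, 0.56, 0.0)),
    ],
    "ASP": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("OD1", "O", (0.03, 0.36, 0.0)),
        ("OD2", "O", (0.27, 0.36, 0.0)),
    ],
    "GLU": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD", "C", (0.15, 0.42, 0.0)),
        ("OE1", "O", (0.03, 0.50, 0.0)),
        ("OE2", "O", (0.27, 0.50, 0.0)),
    ],
    "LYS": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD", "C", (0.15, 0.42, 0.0)),
        ("CE", "C", (0.15, 0.56, 0.0)),
        ("NZ", "N", (0.15, 0.70, 0.0)),
        ("HZ1", "H", (0.15, 0.80, 0.0)),
        ("HZ2", "H", (0.06, 0.745, 0.0)),
        ("HZ3", "H", (0.24, 0.745, 0.0)),
    ],
    "ARG": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("CD", "C", (0.15, 0.42, 0.0)),
        ("NE", "N", (0.15, 0.56, 0.0)),
        ("HE", "H", (0.25, 0.56, 0.0)),
        ("CZ", "C", (0.15, 0.70, 0.0)),
        ("NH1", "N", (0.03, 0.78, 0.0)),
        ("NH2", "N", (0.27, 0.78, 0.0)),
        ("HH11", "H", (-0.02, 0.865, 0.0)),
        ("HH12", "H", (-0.07, 0.74, 0.0)),
        ("HH21", "H", (0.32, 0.865, 0.0)),
        ("HH22", "H", (0.37, 0.74, 0.0)),
    ],
    "HIS": [
        ("CB", "C", (0.15, 0.14, 0.0)),
        ("CG", "C", (0.15, 0.28, 0.0)),
        ("ND1", "N", (0.03, 0.36, 0.0)),
        ("CD2", "C", (0.27, 0.36, 0.0)),
        ("CE1", "C", (0.07, 0.49, 0.0)),
        ("NE2", "N", (0.21, 0.49, 0.0)),
        ("HE2", "H", (0.26, 0.575, 0.0)),
    ],
}

_WATER = [
    ("OW", "O", (0.00, 0.00, 0.0)),
    ("HW1", "H", (0.08, 0.06, 0.0)),
    ("HW2", "H", (-0.08, 0.06, 0.0)),
]

# residue-grid geometry: clusters extend ~0.9 nm in +y and ~0.45 nm in x,
# so these spacings keep all inter-residue atom distances >= ~1.0 nm at home.
_GRID_DX, _GRID_DY, _GRID_DZ = 1.5, 2.2, 2.0
_GRID_COLS, _GRID_ROWS = 8, 8


@dataclass(frozen=True)
class ContactSchedule:
    """One scripted interaction.

    ``anchor`` and ``mobile`` are (residue_index, atom_name) pairs; the
    mobile atom is the one displaced between on- and off-geometry.  For
    SB the anchor is the negative and the mobile the positive atom; for
    HB the anchor is the donor and the mobile the acceptor; for HP the
    pair is symmetric.  ``pattern`` is either an explicit boolean frame
    mask or a target existence percentage.
    """

    kind: ContactKind
    anchor: tuple[int, str]
    mobile: tuple[int, str]
    pattern: float | tuple[bool, ...] = 50.0
    on_distance: float | None = None  # nm; default 0.05 inside the cutoff
    off_distance: float = 0.8  # nm
    hb_angle: float = 155.0  # deg, only for HB
    hydrogen: str | None = None  # donor hydrogen name; default first attached

    def resolved_on_distance(self) -> float:
        if self.on_distance is not None:
            return self.on_distance
        return {ContactKind.SB: 0.35, ContactKind.HB: 0.30, ContactKind.HP: 0.35}[self.kind]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic condition."""

    residue_sequence: Sequence[str]
    n_waters: int = 3
    n_frames: int = 100
    frame_spacing_ps: float = 2.0
    schedules: Sequence[ContactSchedule] = ()
    noise_amplitude: float = 0.02  # nm, max per-atom displacement
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.residue_sequence:
            raise ValueError("residue sequence must be non-empty")
        if self.noise_amplitude >= 0.025:
            raise ValueError("noise amplitude must stay below half the 0.05 nm margin")


@dataclass
class ScheduledContact:
    """Ground-truth record of one scheduled unique contact."""

    key: ContactKey
    mask: np.ndarray
    categories: tuple[str, ...] = ()

    @property
    def percent(self) -> float:
        return 100.0 * float(self.mask.sum()) / len(self.mask)


@dataclass
class GroundTruth:
    """The generator's manifest: what the pipeline must recover, exactly."""

    contacts: list[ScheduledContact]
    n_frames: int
    seed: int

    def _kept(self, kind: ContactKind, threshold: float | None) -> list[ScheduledContact]:
        thr = -1.0 if threshold is None else threshold
        return [c for c in self.contacts if c.key.kind is kind and c.percent > thr + 1e-9]

    def expected_unique(self, kind: ContactKind, threshold: float | None = None) -> int:
        return len(self._kept(kind, threshold))

    def expected_time_averaged(self, kind: ContactKind, threshold: float | None = None) -> float:
        return float(
            sum(c.mask.sum() for c in self._kept(kind, threshold)) / self.n_frames
        )

    def expected_lifetime_counts(
        self, kind: ContactKind, threshold: float | None = None
    ) -> dict[str, int]:
        out = {"short": 0, "substantial": 0, "long": 0}
        for c in self._kept(kind, threshold):
            out[lifetime_class(c.percent).value] += 1
        return out

    def expected_deciles(self, kind: ContactKind, threshold: float | None = None) -> np.ndarray:
        bins = np.zeros(10, dtype=int)
        for c in self._kept(kind, threshold):
            bins[min(int(np.ceil((c.percent - 1e-9) / 10.0)) - 1, 9)] += 1
        return bins

    def expected_hb_category_unique(self, threshold: float | None = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self._kept(ContactKind.HB, threshold):
            for cat in c.categories:
                out[cat] = out.get(cat, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "seed": self.seed,
            "contacts": [
                {
                    "kind": c.key.kind.value,
                    "atoms": list(c.key.atoms),
                    "percent": c.percent,
                    "lifetime_class": lifetime_class(c.percent).value,
                    "categories": list(c.categories),
                }
                for c in self.contacts
            ],
        }


def make_toy_topology(spec: SyntheticSpec) -> Topology:
    """Build the home-position topology for a spec.

    Residues sit on a wide grid, each with standard PDB atom names and
    hydrogens on donor heavy atoms; waters are appended after the
    protein chain.
    """
    atoms: list[AtomRecord] = []
    residues: list[ResidueRecord] = []
    coords: list[tuple[float, float, float]] = []

    def grid_origin(i: int) -> np.ndarray:
        col = i % _GRID_COLS
        row = (i // _GRID_COLS) % _GRID_ROWS
        layer = i // (_GRID_COLS * _GRID_ROWS)
        return np.array([col * _GRID_DX, row * _GRID_DY, layer * _GRID_DZ])

    seq = [r.strip().upper() for r in spec.residue_sequence]
    for name in seq:
        if name not in _SIDECHAINS:
            raise ValueError(f"unknown residue {name!r} in synthetic sequence")

    n_prot = len(seq)
    for ri, name in enumerate(seq):
        residues.append(
            ResidueRecord(
                index=ri,
                name=name,
                chain_id="A",
                sequence_number=ri + 1,
                res_class=classify_residue(name),
                is_terminal=ri in (0, n_prot - 1),
            )
        )
        origin = grid_origin(ri)
        template = [a for a in _BACKBONE if not (name == "PRO" and a[0] == "H")]
        for atom_name, element, offset in template + _SIDECHAINS[name]:
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=atom_name,
                    element=element,
                    residue_index=ri,
                    role=classify_atom_role(atom_name, name),
                )
            )
            coords.append(tuple(origin + np.array(offset)))
    for wi in range(spec.n_waters):
        ri = n_prot + wi
        residues.append(
            ResidueRecord(
                index=ri,
                name="SOL",
                chain_id="W",
                sequence_number=ri + 1,
                res_class=ResClass.OTHER,
            )
        )
        origin = grid_origin(ri)
        for atom_name, element, offset in _WATER:
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=atom_name,
                    element=element,
                    residue_index=ri,
                    role=AtomRole.WATER,
                )
            )
            coords.append(tuple(origin + np.array(offset)))

    ref = np.array(coords)
    topo = Topology(
        atoms=atoms,
        residues=residues,
        donor_hydrogens=assign_donor_hydrogens(atoms, ref),
        reference_coordinates=ref,
    )
    topo.validate()
    return topo


def _atom_index(topology: Topology, residue_index: int, atom_name: str) -> int:
    for a in topology.atoms:
        if a.residue_index == residue_index and a.name == atom_name.upper():
            return a.index
    raise ValueError(f"atom {atom_name!r} not found in residue {residue_index}")


def _approach_direction(topology: Topology, anchor_idx: int, mobile_idx: int) -> np.ndarray:
    """Unit vector along which the mobile atom approaches its anchor.

    An inverse-cube repulsion from every nearby atom pushes the
    direction away from the anchor's own cluster, with a small
    out-of-plane tilt as tie-break, so the placed mobile atom clears all
    non-scheduled atoms.
    """
    coords = topology.reference_coordinates
    anchor = coords[anchor_idx]
    delta = anchor - coords
    dist = np.linalg.norm(delta, axis=1)
    near = (dist > 1e-9) & (dist < 1.0)
    near[mobile_idx] = False
    rep = np.zeros(3)
    if near.any():
        rep = (delta[near] / dist[near, None] ** 3).sum(axis=0)
    norm = np.linalg.norm(rep)
    rep = rep / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    u = rep + np.array([0.0, 0.0, 0.3])
    return u / np.linalg.norm(u)


def _resolve_mask(pattern: float | tuple[bool, ...], n_frames: int) -> np.ndarray:
    if isinstance(pattern, (tuple, list, np.ndarray)):
        mask = np.asarray(pattern, dtype=bool)
        if mask.shape != (n_frames,):
            raise ValueError("explicit mask length must equal n_frames")
        return mask
    percent = float(pattern)
    if not 0 <= percent <= 100:
        raise ValueError("target percentage must lie in [0, 100]")
    k = int(round(percent * n_frames / 100.0))
    mask = np.zeros(n_frames, dtype=bool)
    if k > 0:
        mask[(np.arange(k) * n_frames) // k] = True
    return mask


def _hb_categories(key: ContactKey, topology: Topology) -> tuple[str, ...]:
    """Generator-side category labels, derived from the topology records."""
    donor, _, acceptor = key.atoms
    rd, ra = topology.residue_of(donor), topology.residue_of(acceptor)
    ad, aa = topology.atoms[donor], topology.atoms[acceptor]
    if rd.is_water and ra.is_water:
        return ()
    if rd.is_water or ra.is_water:
        prot_atom, prot_res = (aa, ra) if rd.is_water else (ad, rd)
        cats = ["protein_water",
                "mainchain_water" if prot_atom.role is AtomRole.MAINCHAIN else "sidechain_water"]
        cls = {ResClass.POLAR: "polar_water", ResClass.CHARGED: "charge_water",
               ResClass.HYDROPHOBIC: "hydrophobic_water"}.get(prot_res.res_class)
        if cls:
            cats.append(cls)
        return tuple(cats)
    cats = ["IP"]
    if ad.role is AtomRole.MAINCHAIN and aa.role is AtomRole.MAINCHAIN:
        cats.append("MM")
    elif ad.role is AtomRole.SIDECHAIN and aa.role is AtomRole.SIDECHAIN:
        cats.append("SS")
    else:
        cats.append("MS")
    if rd.res_class is ra.res_class:
        cls = {ResClass.POLAR: "PP", ResClass.CHARGED: "CC",
               ResClass.HYDROPHOBIC: "HH"}.get(rd.res_class)
        if cls:
            cats.append(cls)
    return tuple(cats)


@dataclass
class _ResolvedSchedule:
    schedule: ContactSchedule
    key: ContactKey
    anchor_idx: int
    mobile_idx: int
    hydrogen_idx: int | None
    mask: np.ndarray
    direction: np.ndarray


def _resolve_schedules(
    topology: Topology, spec: SyntheticSpec, participants: ParticipantSets
) -> list[_ResolvedSchedule]:
    resolved: list[_ResolvedSchedule] = []
    used_atoms: set[int] = set()
    for sched in spec.schedules:
        anchor_idx = _atom_index(topology, *sched.anchor)
        mobile_idx = _atom_index(topology, *sched.mobile)
        h_idx: int | None = None
        if sched.kind is ContactKind.HB:
            hydrogens = topology.donor_hydrogens.get(anchor_idx, [])
            if not hydrogens:
                raise ValueError(f"HB schedule anchor {sched.anchor} is not a donor")
            if sched.hydrogen is not None:
                h_idx = _atom_index(topology, sched.anchor[0], sched.hydrogen)
                if h_idx not in hydrogens:
                    raise ValueError(f"{sched.hydrogen} is not attached to donor {sched.anchor}")
            else:
                h_idx = hydrogens[0]
            if topology.donor_hydrogens.get(mobile_idx):
                raise ValueError(
                    f"HB schedule acceptor {sched.mobile} is itself a donor; the reverse "
                    "bond would create an unscheduled contact — pick a hydrogen-free acceptor"
                )
            key = ContactKey(ContactKind.HB, (anchor_idx, h_idx, mobile_idx))
            if mobile_idx not in participants.hb_acceptors:
                raise ValueError(f"{sched.mobile} is not an HB acceptor")
        elif sched.kind is ContactKind.SB:
            if anchor_idx not in participants.sb_negative:
                raise ValueError(f"SB anchor {sched.anchor} is not a negative charge center")
            if mobile_idx not in participants.sb_positive:
                raise ValueError(f"SB mobile {sched.mobile} is not a positive charge center")
            key = ContactKey(ContactKind.SB, (anchor_idx, mobile_idx))
        elif sched.kind is ContactKind.HP:
            for idx, which in ((anchor_idx, sched.anchor), (mobile_idx, sched.mobile)):
                if idx not in participants.hydrophobic_carbons:
                    raise ValueError(f"{which} is not a hydrophobic carbon")
            key = ContactKey.hydrophobic(anchor_idx, mobile_idx)
        else:  # pragma: no cover
            raise ValueError(f"unknown schedule kind {sched.kind}")

        touched = {anchor_idx, mobile_idx} | ({h_idx} if h_idx is not None else set())
        if touched & used_atoms:
            raise ValueError(
                f"schedules share atoms {sorted(touched & used_atoms)} with "
                "potentially incompatible geometry"
            )
        used_atoms |= touched
        resolved.append(
            _ResolvedSchedule(
                schedule=sched,
                key=key,
                anchor_idx=anchor_idx,
                mobile_idx=mobile_idx,
                hydrogen_idx=h_idx,
                mask=_resolve_mask(sched.pattern, spec.n_frames),
                direction=_approach_direction(topology, anchor_idx, mobile_idx),
            )
        )
    _check_clearances(resolved, topology, participants, spec)
    return resolved


def _nominal_positions(rs: _ResolvedSchedule, topology: Topology) -> list[np.ndarray]:
    """Noise-free on- and off-positions of a schedule's mobile atom."""
    home = topology.reference_coordinates
    anchor = home[rs.anchor_idx]
    if rs.schedule.kind is ContactKind.HB:
        on = _place_hb_acceptor(
            anchor, home[rs.hydrogen_idx], rs.schedule.resolved_on_distance(),
            rs.schedule.hb_angle, rs.direction,
        )
    else:
        on = anchor + rs.schedule.resolved_on_distance() * rs.direction
    off = anchor + rs.schedule.off_distance * rs.direction
    return [on, off]


def _check_clearances(
    resolved: list[_ResolvedSchedule],
    topology: Topology,
    participants: ParticipantSets,
    spec: SyntheticSpec,
) -> None:
    """Nominal mobile positions must clear every non-partner participant
    atom by more than the largest cutoff plus the worst-case noise."""
    heavy = sorted(
        (participants.sb_negative | participants.sb_positive | participants.hb_donors
         | participants.hb_acceptors | participants.hydrophobic_carbons)
    )
    home = topology.reference_coordinates
    clearance = 0.4 + 3.0 * spec.noise_amplitude

    def could_interact(m: int, j: int) -> bool:
        # Pairs a detector could register.  Schedule mobiles travel
        # without their hydrogens, so a mobile can never act as donor;
        # only static donors (hydrogens in place) threaten an accidental
        # hydrogen bond.
        if m in participants.hydrophobic_carbons and j in participants.hydrophobic_carbons:
            return True
        if (m in participants.sb_positive and j in participants.sb_negative) or (
            m in participants.sb_negative and j in participants.sb_positive
        ):
            return True
        return j in participants.hb_donors and m in participants.hb_acceptors

    placements = {rs.mobile_idx: _nominal_positions(rs, topology) for rs in resolved}
    for rs in resolved:
        for pos in placements[rs.mobile_idx]:
            for j in heavy:
                if j in (rs.anchor_idx, rs.mobile_idx):
                    continue
                if not could_interact(rs.mobile_idx, j):
                    continue
                for q in placements.get(j, [home[j]]):
                    if np.linalg.norm(pos - q) < clearance:
                        raise ValueError(
                            f"schedule for atoms {rs.key.atoms} places its mobile atom "
                            f"within {clearance:.2f} nm of atom {j}; move the schedule "
                            "to a less crowded pair"
                        )


def _place_hb_acceptor(
    d: np.ndarray, h: np.ndarray, distance: float, angle_deg: float, tilt: np.ndarray
) -> np.ndarray:
    """Acceptor position giving exact |D-A| = distance and D-H-A angle."""
    theta = np.radians(angle_deg)
    dh = d - h
    ldh = np.linalg.norm(dh)
    d_hat = dh / ldh
    perp = tilt - np.dot(tilt, d_hat) * d_hat
    norm = np.linalg.norm(perp)
    if norm < 1e-9:
        perp = np.array([1.0, 0.0, 0.0]) - d_hat[0] * d_hat
        norm = np.linalg.norm(perp)
    perp /= norm
    # law of cosines for |H-A| given |D-H|, |D-A| and the angle at H
    disc = ldh**2 * np.cos(theta) ** 2 - ldh**2 + distance**2
    if disc < 0:
        raise ValueError(
            f"infeasible H-bond geometry: d={distance} nm, angle={angle_deg} deg"
        )
    r = ldh * np.cos(theta) + np.sqrt(disc)
    if r <= 0:
        raise ValueError(
            f"infeasible H-bond geometry: d={distance} nm, angle={angle_deg} deg"
        )
    w = np.cos(theta) * d_hat + np.sin(theta) * perp
    return h + r * w


def _verify_frame(
    frame: Frame,
    topology: Topology,
    participants: ParticipantSets,
    expected: dict[ContactKind, set[ContactKey]],
) -> None:
    found = {
        ContactKind.SB: detect_saltbridges_frame(frame, topology, participants).contacts,
        ContactKind.HB: detect_hbonds_frame(frame, topology, participants).contacts,
        ContactKind.HP: detect_hydrophobic_frame(frame, topology, participants).contacts,
    }
    for kind in ContactKind:
        if found[kind] != expected[kind]:
            extra = found[kind] - expected[kind]
            missing = expected[kind] - found[kind]
            raise ValueError(
                f"schedule verification failed at t={frame.time} ps for {kind.value}: "
                f"unscheduled={sorted(k.atoms for k in extra)}, "
                f"missing={sorted(k.atoms for k in missing)}"
            )


def make_scripted_trajectory(
    spec: SyntheticSpec, topology: Topology | None = None, verify: bool = True
) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory realizing the spec's contact schedules.

    Noise is applied to all atoms first; scheduled mobile atoms are then
    placed exactly relative to the noisy anchors, so realized geometries
    meet the criteria exactly in on-frames and miss them by a wide
    margin in off-frames.  Hydrogens never travel with a mobile atom;
    donor bookkeeping stays anchored to the home topology.

    With verify=True every frame is checked to contain exactly the
    scheduled contacts and nothing else.
    """
    topo = topology if topology is not None else make_toy_topology(spec)
    participants = build_participant_sets(topo)
    resolved = _resolve_schedules(topo, spec, participants)
    rng = np.random.default_rng(spec.seed)
    home = topo.reference_coordinates

    frames: list[Frame] = []
    for t in range(spec.n_frames):
        # isotropic jitter with per-atom displacement <= noise_amplitude
        direction = rng.normal(size=home.shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        magnitude = rng.uniform(0.0, spec.noise_amplitude, size=(home.shape[0], 1))
        coords = home + direction * magnitude
        for rs in resolved:
            anchor = coords[rs.anchor_idx]
            if rs.mask[t]:
                d_on = rs.schedule.resolved_on_distance()
                if rs.schedule.kind is ContactKind.HB:
                    coords[rs.mobile_idx] = _place_hb_acceptor(
                        anchor, coords[rs.hydrogen_idx], d_on,
                        rs.schedule.hb_angle, rs.direction,
                    )
                else:
                    coords[rs.mobile_idx] = anchor + d_on * rs.direction
            else:
                coords[rs.mobile_idx] = anchor + rs.schedule.off_distance * rs.direction
        frames.append(Frame(time=t * spec.frame_spacing_ps, coordinates=coords))
        if verify:
            expected = {k: set() for k in ContactKind}
            for rs in resolved:
                if rs.mask[t]:
                    expected[rs.key.kind].add(rs.key)
            _verify_frame(frames[-1], topo, participants, expected)

    contacts = [
        ScheduledContact(
            key=rs.key,
            mask=rs.mask,
            categories=_hb_categories(rs.key, topo) if rs.key.kind is ContactKind.HB else (),
        )
        for rs in resolved
    ]
    truth = GroundTruth(contacts=contacts, n_frames=spec.n_frames, seed=spec.seed)
    return (
        Trajectory(topology=topo, frames=frames, source=f"synthetic(seed={spec.seed})"),
        truth,
    )


def make_hb_geometry_frame(d_nm: float, angle_deg: float) -> Frame:
    """Three-atom frame (donor, hydrogen, acceptor) with |D-A| = d_nm and
    an exact D-H-A angle; H sits 0.1 nm from D."""
    if d_nm <= 0.1:
        raise ValueError("donor-acceptor distance must exceed the 0.1 nm D-H bond")
    if not 0 < angle_deg <= 180:
        raise ValueError("angle must lie in (0, 180]")
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([0.1, 0.0, 0.0])
    a = _place_hb_acceptor(d, h, d_nm, angle_deg, np.array([0.0, 1.0, 0.0]))
    return Frame(time=0.0, coordinates=np.array([d, h, a]))


def hb_probe_system() -> tuple[Topology, ParticipantSets]:
    """Minimal donor/hydrogen/acceptor topology matching make_hb_geometry_frame.

    Atom 0 is a Ser Oγ donor with its hydrogen (atom 1); atom 2 is a
    backbone carbonyl O acceptor in a different residue.
    """
    residues = [
        ResidueRecord(0, "SER", "A", 1, classify_residue("SER")),
        ResidueRecord(1, "GLY", "A", 2, classify_residue("GLY")),
    ]
    atoms = [
        AtomRecord(0, "OG", "O", 0, AtomRole.SIDECHAIN),
        AtomRecord(1, "HG", "H", 0, AtomRole.SIDECHAIN),
        AtomRecord(2, "O", "O", 1, AtomRole.MAINCHAIN),
    ]
    topo = Topology(atoms=atoms, residues=residues, donor_hydrogens={0: [1]})
    participants = ParticipantSets(
        sb_negative=frozenset(),
        sb_positive=frozenset(),
        hb_donors=frozenset({0}),
        hb_acceptors=frozenset({0, 2}),
        hydrophobic_carbons=frozenset(),
    )
    return topo, participants


def make_condition_pair(
    spec_a: SyntheticSpec, spec_b: SyntheticSpec, verify: bool = True
) -> tuple[tuple[Trajectory, GroundTruth], tuple[Trajectory, GroundTruth]]:
    """Generate two conditions over the same topology (e.g. two temperatures)."""
    if list(spec_a.residue_sequence) != list(spec_b.residue_sequence) or (
        spec_a.n_waters != spec_b.n_waters
    ):
        raise ValueError("condition pair must share one topology")
    topo = make_toy_topology(spec_a)
    pair_a = make_scripted_trajectory(spec_a, topology=topo, verify=verify)
    pair_b = make_scripted_trajectory(spec_b, topology=topo, verify=verify)
    return pair_a, pair_b


def expected_condition_diff(
    gt_a: GroundTruth, gt_b: GroundTruth, threshold: float | None = None
) -> dict:
    """Manifest of expected B - A differences per kind."""
    out: dict = {}
    for kind in ContactKind:
        la = gt_a.expected_lifetime_counts(kind, threshold)
        lb = gt_b.expected_lifetime_counts(kind, threshold)
        out[kind.value] = {
            "d_unique": gt_b.expected_unique(kind, threshold)
            - gt_a.expected_unique(kind, threshold),
            "d_time_averaged": gt_b.expected_time_averaged(kind, threshold)
            - gt_a.expected_time_averaged(kind, threshold),
            "d_lifetime": {c: lb[c] - la[c] for c in la},
            "d_deciles": (
                gt_b.expected_deciles(kind, threshold) - gt_a.expected_deciles(kind, threshold)
            ).tolist(),
        }
    return out


#: residue sequence of the example study: every residue class, His, waters.
EXAMPLE_SEQUENCE = (
    "ASP", "LYS", "SER", "GLY", "LEU", "VAL", "ARG",
    "GLU", "HIS", "TRP", "ASN", "GLN", "TYR", "THR",
)


def example_thermal_pair_specs(
    n_frames: int = 200, seed: int = 0
) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Specs for a two-condition study emulating a cold/hot comparison.

    Condition B (the "hot" condition) gains a unique salt bridge and a
    unique hydrophobic contact, loses a protein-water hydrogen bond,
    shifts long-lived contacts toward shorter occupancies, and places
    contacts exactly on the 5 %, 10 % and 90 % reporting boundaries so
    the filter and lifetime-class edges are all exercised.
    """
    sb, hb, hp = ContactKind.SB, ContactKind.HB, ContactKind.HP
    cold = SyntheticSpec(
        residue_sequence=EXAMPLE_SEQUENCE, n_waters=3, n_frames=n_frames, seed=seed,
        schedules=(
            ContactSchedule(sb, anchor=(0, "OD1"), mobile=(1, "NZ"), pattern=95.0),
            ContactSchedule(sb, anchor=(0, "OD2"), mobile=(6, "NH1"), pattern=95.0),
            ContactSchedule(sb, anchor=(7, "OE1"), mobile=(6, "NH2"), pattern=95.0),
            ContactSchedule(hb, anchor=(4, "N"), mobile=(5, "O"), pattern=90.0),  # MM, HH
            ContactSchedule(hb, anchor=(2, "OG"), mobile=(10, "OD1"), pattern=10.0),  # SS, PP
            ContactSchedule(hb, anchor=(12, "OH"), mobile=(3, "O"), pattern=37.0),  # MS
            ContactSchedule(hb, anchor=(13, "OG1"), mobile=(11, "OE1"), pattern=60.0),  # SS, PP
            ContactSchedule(hb, anchor=(10, "N"), mobile=(11, "O"), pattern=5.0),  # MM, PP
            ContactSchedule(hb, anchor=(1, "N"), mobile=(7, "O"), pattern=4.0),  # MM, CC
            ContactSchedule(hb, anchor=(14, "OW"), mobile=(1, "O"), pattern=50.0),  # water
            ContactSchedule(hb, anchor=(15, "OW"), mobile=(8, "ND1"), pattern=20.0),  # water
            ContactSchedule(hb, anchor=(16, "OW"), mobile=(9, "O"), pattern=100.0),  # water
            ContactSchedule(hp, anchor=(4, "CD1"), mobile=(5, "CG1"), pattern=91.0),
            ContactSchedule(hp, anchor=(6, "CZ"), mobile=(9, "CB"), pattern=50.0),
            ContactSchedule(hp, anchor=(7, "CD"), mobile=(13, "CG2"), pattern=5.0),
            ContactSchedule(hp, anchor=(8, "CD2"), mobile=(11, "CB"), pattern=2.0),
        ),
    )
    hot = SyntheticSpec(
        residue_sequence=EXAMPLE_SEQUENCE, n_waters=3, n_frames=n_frames, seed=seed + 1,
        schedules=(
            ContactSchedule(sb, anchor=(0, "OD1"), mobile=(1, "NZ"), pattern=50.0),
            ContactSchedule(sb, anchor=(0, "OD2"), mobile=(6, "NH1"), pattern=95.0),
            ContactSchedule(sb, anchor=(7, "OE1"), mobile=(6, "NH2"), pattern=8.0),
            ContactSchedule(sb, anchor=(7, "OE2"), mobile=(6, "NE"), pattern=50.0),  # gained
            ContactSchedule(hb, anchor=(4, "N"), mobile=(5, "O"), pattern=95.0),
            ContactSchedule(hb, anchor=(2, "OG"), mobile=(10, "OD1"), pattern=40.0),
            ContactSchedule(hb, anchor=(12, "OH"), mobile=(3, "O"), pattern=37.0),
            # the Thr-Gln bond is lost; a His-Ser bond is gained
            ContactSchedule(hb, anchor=(8, "NE2"), mobile=(2, "O"), pattern=75.0),  # MS
            ContactSchedule(hb, anchor=(10, "N"), mobile=(11, "O"), pattern=5.0),
            ContactSchedule(hb, anchor=(1, "N"), mobile=(7, "O"), pattern=12.0),
            ContactSchedule(hb, anchor=(14, "OW"), mobile=(1, "O"), pattern=30.0),
            ContactSchedule(hb, anchor=(15, "OW"), mobile=(8, "ND1"), pattern=20.0),
            # the Trp backbone-water bond is lost at the hot condition
            ContactSchedule(hp, anchor=(4, "CD1"), mobile=(5, "CG1"), pattern=50.0),
            ContactSchedule(hp, anchor=(6, "CZ"), mobile=(9, "CB"), pattern=50.0),
            ContactSchedule(hp, anchor=(7, "CD"), mobile=(13, "CG2"), pattern=5.0),
            ContactSchedule(hp, anchor=(8, "CD2"), mobile=(11, "CB"), pattern=20.0),
            ContactSchedule(hp, anchor=(0, "CG"), mobile=(8, "CB"), pattern=65.0),  # gained
        ),
    )
    return cold, hot


# --------------------------------------------------------------------------
# writers

def _pdb_atom_line(serial: int, atom: AtomRecord, res: ResidueRecord, xyz_nm) -> str:
    x, y, z = (float(v) * 10.0 for v in xyz_nm)  # nm -> Å
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s}{res.name[:3]:>4s} {res.chain_id[:1]}"
        f"{res.sequence_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {atom.element:>2s}"
    )


def write_topology_pdb(topology: Topology, path: str) -> None:
    """Write the home-position reference structure as a PDB file."""
    if topology.reference_coordinates is None:
        raise ValueError("topology has no reference coordinates")
    lines = []
    for a in topology.atoms:
        res = topology.residues[a.residue_index]
        lines.append(_pdb_atom_line(a.index + 1, a, res, topology.reference_coordinates[a.index]))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_multimodel_pdb(trajectory: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB."""
    topo = trajectory.topology
    lines = []
    for m, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for a in topo.atoms:
            res = topo.residues[a.residue_index]
            lines.append(_pdb_atom_line(a.index + 1, a, res, frame.coordinates[a.index]))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_dcd(trajectory: Trajectory, path: str) -> None:
    """Write a trajectory as a (binary) DCD file via MDAnalysis."""
    import MDAnalysis as mda

    n = trajectory.topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(path, n_atoms=n) as writer:
        for frame in trajectory.frames:
            u.atoms.positions = frame.coordinates * 10.0  # nm -> Å
            writer.write(u.atoms)


def write_manifest(truth: GroundTruth, path: str) -> None:
    """Dump the ground-truth manifest as JSON (or YAML by extension)."""
    data = truth.to_dict()
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
    else:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
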