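"""Atom/residue data model and participant-set construction.

The detectors operate on plain atom indices; this module supplies the
static context they need: which residue class each residue belongs to,
which atoms are mainchain vs sidechain vs water, which atoms can take
part in salt bridges, hydrogen bonds and hydrophobic contacts, and
which hydrogens hang off which donor heavy atoms.

Residue classes follow the three printed lists used throughout the
analysis: charged (Arg, Lys, Asp, Glu), polar (Gln, Asn, Ser, Thr, Tyr,
Cys) and hydrophobic (Ala, Ile, Leu, Phe, Val, Pro, Gly, Met, Trp).
Histidine appears in none of them and is classified OTHER; it is also
excluded from salt-bridge participant sets, as are the backbone
carboxylate/ammonium groups of chain-terminal residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRole",
    "ResClass",
    "AtomRecord",
    "ResidueRecord",
    "Topology",
    "ParticipantSets",
    "classify_residue",
    "classify_atom_role",
    "build_participant_sets",
    "assign_donor_hydrogens",
    "GREEK_TO_PDB",
]


class AtomRole(Enum):
    MAINCHAIN = "mainchain"
    SIDECHAIN = "sidechain"
    WATER = "water"
    OTHER = "other"


class ResClass(Enum):
    CHARGED = "charged"
    POLAR = "polar"
    HYDROPHOBIC = "hydrophobic"
    OTHER = "other"


CHARGED_RESIDUES = frozenset({"ARG", "LYS", "ASP", "GLU"})
POLAR_RESIDUES = frozenset({"GLN", "ASN", "SER", "THR", "TYR", "CYS"})
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "ILE", "LEU", "PHE", "VAL", "PRO", "GLY", "MET", "TRP"}
)
WATER_RESIDUES = frozenset({"HOH", "SOL", "WAT", "TIP4", "TIP3", "TIP", "SPC"})

#: All residue names treated as protein content.
PROTEIN_RESIDUES = (
    CHARGED_RESIDUES | POLAR_RESIDUES | HYDROPHOBIC_RESIDUES | frozenset({"HIS"})
)

# Backbone atom names, including common hydrogen-naming variants.
MAINCHAIN_ATOM_NAMES = frozenset(
    {
        "N", "CA", "C", "O", "OXT", "OT1", "OT2",
        "H", "H1", "H2", "H3", "HN", "HA", "HA1", "HA2", "HA3",
    }
)

# Salt-bridge participant atoms (sidechain charge centers).
SB_NEGATIVE_ATOMS: Mapping[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}
SB_POSITIVE_ATOMS: Mapping[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
}

#: Carbon names participating in hydrophobic contacts.
HYDROPHOBIC_CARBON_NAMES = frozenset(
    {
        "C", "CA", "CB", "CD", "CD1", "CD2", "CE", "CE1", "CE2", "CE3",
        "CG", "CG1", "CG2", "CZ", "CZ2", "CZ3", "CH2",
    }
)

#: Greek-letter atom spellings -> standard PDB names.
GREEK_TO_PDB: Mapping[str, str] = {
    "Cα": "CA", "Cβ": "CB", "Cγ": "CG", "Cγ1": "CG1", "Cγ2": "CG2",
    "Cδ": "CD", "Cδ1": "CD1", "Cδ2": "CD2",
    "Cε": "CE", "Cε1": "CE1", "Cε2": "CE2", "Cε3": "CE3",
    "Cζ": "CZ", "Cζ2": "CZ2", "Cζ3": "CZ3", "Cη2": "CH2",
    "Oδ1": "OD1", "Oδ2": "OD2", "Oε1": "OE1", "Oε2": "OE2",
    "Nδ1": "ND1", "Nε": "NE", "Nε2": "NE2",
    "Nη1": "NH1", "Nη2": "NH2", "Nζ": "NZ",
}

#: Maximum donor-hydrogen distance (nm) for proximity-based attachment.
DONOR_H_MAX_DIST = 0.12


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, naming and structural role."""

    index: int
    name: str
    element: str
    residue_index: int
    role: AtomRole


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with its class assignment and terminal flag."""

    index: int
    name: str
    chain_id: str
    sequence_number: int
    res_class: ResClass
    is_terminal: bool = False

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESIDUES

    @property
    def is_protein(self) -> bool:
        return self.name in PROTEIN_RESIDUES


@dataclass
class Topology:
    """Static frame of reference for all detectors.

    Coordinates are *not* stored here beyond a single reference frame
    (needed for proximity-based hydrogen attachment); trajectories carry
    their own coordinates.  All lengths are nm.
    """

    atoms: list[AtomRecord]
    residues: list[ResidueRecord]
    donor_hydrogens: dict[int, list[int]] = field(default_factory=dict)
    reference_coordinates: np.ndarray | None = None
    length_unit: str = "nm"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_of(self, atom_index: int) -> ResidueRecord:
        return self.residues[self.atoms[atom_index].residue_index]

    def protein_residue_indices(self) -> list[int]:
        return [r.index for r in self.residues if r.is_protein]

    def ca_indices(self) -> list[int]:
        """Indices of Cα atoms of protein residues, in residue order."""
        out = []
        for a in self.atoms:
            if a.name == "CA" and self.residues[a.residue_index].is_protein:
                out.append(a.index)
        return out

    def validate(self) -> None:
        """Raise ValueError on violation of the structural invariants."""
        n_res = len(self.residues)
        for a in self.atoms:
            if not (0 <= a.residue_index < n_res):
                raise ValueError(
                    f"atom {a.index} residue_index {a.residue_index} out of bounds"
                )
        if self.reference_coordinates is not None:
            coords = self.reference_coordinates
            for donor, hydrogens in self.donor_hydrogens.items():
                for h in hydrogens:
                    d = float(np.linalg.norm(coords[donor] - coords[h]))
                    if d > DONOR_H_MAX_DIST + 1e-9:
                        raise ValueError(
                            f"hydrogen {h} is {d:.3f} nm from donor {donor} "
                            f"(> {DONOR_H_MAX_DIST} nm)"
                        )


@dataclass(frozen=True)
class ParticipantSets:
    """Atom-index sets consumed by the per-frame detectors."""

    sb_negative: frozenset[int]
    sb_positive: frozenset[int]
    hb_donors: frozenset[int]
    hb_acceptors: frozenset[int]
    hydrophobic_carbons: frozenset[int]


def classify_residue(name: str) -> ResClass:
    """Classify a 3-letter residue code into its residue class.

    Names outside the three lists (His, waters, ligands, unknown codes)
    map to OTHER; unknown codes additionally log a warning.
    """
    code = name.strip().upper()
    if code in CHARGED_RESIDUES:
        return ResClass.CHARGED
    if code in POLAR_RESIDUES:
        return ResClass.POLAR
    if code in HYDROPHOBIC_RESIDUES:
        return ResClass.HYDROPHOBIC
    if code not in PROTEIN_RESIDUES and code not in WATER_RESIDUES:
        logger.warning("unknown residue code %r classified as OTHER", name)
    return ResClass.OTHER


def classify_atom_role(atom_name: str, residue_name: str) -> AtomRole:
    """MAINCHAIN for backbone names, WATER for water residues, else SIDECHAIN."""
    if not atom_name or not residue_name:
        raise ValueError("atom and residue names must be non-empty")
    res = residue_name.strip().upper()
    if res in WATER_RESIDUES:
        return AtomRole.WATER
    if res not in PROTEIN_RESIDUES:
        return AtomRole.OTHER
    if atom_name.strip().upper() in MAINCHAIN_ATOM_NAMES:
        return AtomRole.MAINCHAIN
    return AtomRole.SIDECHAIN


def assign_donor_hydrogens(
    atoms: Sequence[AtomRecord],
    coordinates: np.ndarray,
    max_dist: float = DONOR_H_MAX_DIST,
) -> dict[int, list[int]]:
    """Attach each hydrogen to its nearest N/O within ``max_dist`` nm.

    Used when the input file carries no bond records.  Hydrogens with no
    N/O inside the cutoff (e.g. aliphatic H) are left unattached.
    """
    from scipy.spatial import cKDTree

    heavy = [a.index for a in atoms if a.element in ("N", "O")]
    hydrogens = [a.index for a in atoms if a.element == "H"]
    mapping: dict[int, list[int]] = {}
    if not heavy or not hydrogens:
        return mapping
    tree = cKDTree(coordinates[heavy])
    dists, nearest = tree.query(coordinates[hydrogens], k=1)
    for h, d, j in zip(hydrogens, dists, nearest):
        if d <= max_dist:
            mapping.setdefault(heavy[j], []).append(h)
    return mapping


def _terminal_excluded_atoms(topology: Topology) -> set[int]:
    """Backbone atoms of terminal groups excluded from salt bridges.

    The exclusion targets the terminal *groups*: the backbone
    carboxylate (C/O/OXT of a chain's last residue) and the backbone
    ammonium (N and its hydrogens of the first residue).  Sidechain
    charge centers of terminal residues remain eligible.
    """
    excluded: set[int] = set()
    by_chain: dict[str, list[ResidueRecord]] = {}
    for r in topology.residues:
        if r.is_protein:
            by_chain.setdefault(r.chain_id, []).append(r)
    for residues in by_chain.values():
        first, last = residues[0].index, residues[-1].index
        for a in topology.atoms:
            if a.residue_index == first and a.name in ("N", "H", "H1", "H2", "H3"):
                excluded.add(a.index)
            if a.residue_index == last and a.name in ("C", "O", "OXT", "OT1", "OT2"):
                excluded.add(a.index)
    return excluded


def build_participant_sets(topology: Topology) -> ParticipantSets:
    """Construct the detector participant sets from a topology.

    Salt-bridge sets contain the sidechain charge-center atoms of
    Asp/Glu (negative) and Arg/Lys (positive); His and terminal
    backbone groups are excluded.  H-bond donors are N/O atoms with at
    least one attached hydrogen; acceptors are all N/O atoms (protein
    and water).  Hydrophobic carbons are the named carbon set over all
    protein residues.
    """
    if not any(r.is_protein for r in topology.residues):
        raise ValueError("no protein content in topology")

    terminal_excluded = _terminal_excluded_atoms(topology)
    sb_neg: set[int] = set()
    sb_pos: set[int] = set()
    hb_donors: set[int] = set()
    hb_acceptors: set[int] = set()
    hydrophobic: set[int] = set()

    for a in topology.atoms:
        res = topology.residues[a.residue_index]
        name = a.name.upper()
        if res.is_protein and a.index not in terminal_excluded:
            if name in SB_NEGATIVE_ATOMS.get(res.name, ()):
                sb_neg.add(a.index)
            if name in SB_POSITIVE_ATOMS.get(res.name, ()):
                sb_pos.add(a.index)
        if res.is_protein and a.element == "C" and name in HYDROPHOBIC_CARBON_NAMES:
            hydrophobic.add(a.index)
        if a.element in ("N", "O") and (res.is_protein or res.is_water):
            hb_acceptors.add(a.index)
            if topology.donor_hydrogens.get(a.index):
                hb_donors.add(a.index)

    return ParticipantSets(
        sb_negative=frozenset(sb_neg),
        sb_positive=frozenset(sb_pos),
        hb_donors=frozenset(hb_donors),
        hb_acceptors=frozenset(hb_acceptors),
        hydrophobic_carbons=frozenset(hydrophobic),
    )
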