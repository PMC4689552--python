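"""Per-frame geometric detection of salt bridges, H-bonds and hydrophobic contacts.

Criteria (all cutoffs inclusive):

* salt bridge — carboxylate O (Asp/Glu) to charged N (Arg/Lys) within 0.4 nm;
* hydrogen bond — donor-acceptor distance ≤ 0.35 nm and donor-hydrogen-
  acceptor angle ≥ 120°; a bond through a different hydrogen between the
  same donor and acceptor is a distinct contact;
* hydrophobic contact — listed carbon names within 0.4 nm, canonically
  ordered so each pair appears once.

Candidate pairs come from a KD-tree; tests hold the detectors to exact
agreement with an all-pairs brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .topology_model import ParticipantSets, Topology
from .trajectory_io import Frame

__all__ = [
    "ContactKind",
    "ContactKey",
    "FrameContacts",
    "pair_distance",
    "detect_hbonds_frame",
    "detect_saltbridges_frame",
    "detect_hydrophobic_frame",
]

# Absorbs float noise at the printed cutoffs: 0.35 nm exactly is in,
# 0.351 nm is out; 120.0 deg exactly is in, 119.9 deg is out.
EDGE_TOL = 1e-9

HB_D_MAX = 0.35  # nm, donor-acceptor
HB_ANGLE_MIN = 120.0  # deg, donor-hydrogen-acceptor
SB_D_MAX = 0.4  # nm
HP_D_MAX = 0.4  # nm


class ContactKind(Enum):
    SB = "SB"
    HB = "HB"
    HP = "HP"


@dataclass(frozen=True, order=True)
class ContactKey:
    """Typed identity of one interaction.

    atoms is (negative, positive) for SB, (donor, hydrogen, acceptor)
    for HB, and the canonically ordered carbon pair (i < j) for HP.
    """

    kind: ContactKind
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        n = {ContactKind.SB: 2, ContactKind.HB: 3, ContactKind.HP: 2}[self.kind]
        if len(self.atoms) != n:
            raise ValueError(f"{self.kind.value} key needs {n} atoms")
        if self.kind is ContactKind.HP and self.atoms[0] >= self.atoms[1]:
            raise ValueError("HP key must be canonically ordered (i < j)")

    @staticmethod
    def hydrophobic(i: int, j: int) -> "ContactKey":
        if i == j:
            raise ValueError("hydrophobic contact needs two distinct atoms")
        return ContactKey(ContactKind.HP, (min(i, j), max(i, j)))


@dataclass
class FrameContacts:
    """Contacts present in one frame (set semantics)."""

    time: float
    contacts: set[ContactKey] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.contacts)


def pair_distance(
    frame: Frame, i: int, j: int, use_min_image: bool = False
) -> float:
    """Euclidean distance between atoms i and j in nm, optionally under
    the minimum-image convention for an orthorhombic box."""
    if i == j:
        raise ValueError("i and j must differ")
    delta = frame.coordinates[i] - frame.coordinates[j]
    if use_min_image:
        if frame.box is None:
            raise ValueError("minimum image requested but frame has no box")
        delta = delta - frame.box * np.round(delta / frame.box)
    return float(np.linalg.norm(delta))


def _pairs_within(
    coords: np.ndarray,
    set_a: np.ndarray,
    set_b: np.ndarray,
    cutoff: float,
    box: np.ndarray | None,
) -> list[tuple[int, int]]:
    """(a, b) index pairs with |r_a - r_b| ≤ cutoff (+EDGE_TOL).

    Under a box the KD-tree uses periodic wrapping; without one it works
    on raw coordinates.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        return []
    if box is not None:
        pa = np.mod(coords[set_a], box)
        pb = np.mod(coords[set_b], box)
        tree = cKDTree(pb, boxsize=box)
    else:
        pa, pb = coords[set_a], coords[set_b]
        tree = cKDTree(pb)
    out: list[tuple[int, int]] = []
    for ia, neighbors in enumerate(tree.query_ball_point(pa, cutoff + EDGE_TOL)):
        a = int(set_a[ia])
        for ib in neighbors:
            out.append((a, int(set_b[ib])))
    return out


def detect_saltbridges_frame(
    frame: Frame,
    topology: Topology,
    participants: ParticipantSets,
    d_max: float = SB_D_MAX,
    use_min_image: bool = False,
) -> FrameContacts:
    """Salt bridges: every negative x positive atom pair within d_max."""
    box = frame.box if use_min_image else None
    neg = np.fromiter(sorted(participants.sb_negative), dtype=int)
    pos = np.fromiter(sorted(participants.sb_positive), dtype=int)
    contacts = {
        ContactKey(ContactKind.SB, (a, b))
        for a, b in _pairs_within(frame.coordinates, neg, pos, d_max, box)
    }
    return FrameContacts(time=frame.time, contacts=contacts)


def _dha_angle_deg(
    d: np.ndarray, h: np.ndarray, a: np.ndarray, box: np.ndarray | None
) -> float:
    v1 = d - h
    v2 = a - h
    if box is not None:
        v1 = v1 - box * np.round(v1 / box)
        v2 = v2 - box * np.round(v2 / box)
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_hbonds_frame(
    frame: Frame,
    topology: Topology,
    participants: ParticipantSets,
    d_max: float = HB_D_MAX,
    angle_min: float = HB_ANGLE_MIN,
    use_min_image: bool = False,
) -> FrameContacts:
    """Hydrogen bonds: (donor, hydrogen, acceptor) triples passing the
    distance and angle criteria.  Intra-residue donor-acceptor pairs are
    excluded; sequence-adjacent residues are retained."""
    box = frame.box if use_min_image else None
    coords = frame.coordinates
    donors = np.fromiter(sorted(participants.hb_donors), dtype=int)
    acceptors = np.fromiter(sorted(participants.hb_acceptors), dtype=int)
    res_of = {a.index: a.residue_index for a in topology.atoms}
    contacts: set[ContactKey] = set()
    for d_idx, a_idx in _pairs_within(coords, donors, acceptors, d_max, box):
        if d_idx == a_idx or res_of[d_idx] == res_of[a_idx]:
            continue
        for h_idx in topology.donor_hydrogens.get(d_idx, ()):
            angle = _dha_angle_deg(coords[d_idx], coords[h_idx], coords[a_idx], box)
            if angle >= angle_min - EDGE_TOL:
                contacts.add(ContactKey(ContactKind.HB, (d_idx, h_idx, a_idx)))
    return FrameContacts(time=frame.time, contacts=contacts)


def detect_hydrophobic_frame(
    frame: Frame,
    topology: Topology,
    participants: ParticipantSets,
    d_max: float = HP_D_MAX,
    min_res_separation: int = 1,
    use_min_image: bool = False,
) -> FrameContacts:
    """Hydrophobic contacts: canonical pairs of listed carbons within
    d_max, residues at least min_res_separation apart in sequence."""
    box = frame.box if use_min_image else None
    carbons = np.fromiter(sorted(participants.hydrophobic_carbons), dtype=int)
    res_of = {a.index: a.residue_index for a in topology.atoms}
    contacts: set[ContactKey] = set()
    for i, j in _pairs_within(frame.coordinates, carbons, carbons, d_max, box):
        if i >= j:
            continue
        if abs(res_of[i] - res_of[j]) < min_res_separation:
            continue
        contacts.add(ContactKey.hydrophobic(i, j))
    return FrameContacts(time=frame.time, contacts=contacts)
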