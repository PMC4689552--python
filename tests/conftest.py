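import numpy as np
import pytest

from ncidyn.interaction_detectors import ContactKind
from ncidyn.synthetic_data import ContactSchedule, SyntheticSpec, make_toy_topology
from ncidyn.topology_model import (
    AtomRecord,
    AtomRole,
    ResidueRecord,
    Topology,
    build_participant_sets,
    classify_residue,
)
from ncidyn.trajectory_io import Frame, Trajectory

#: one residue of every class plus His and waters
STANDARD_SEQUENCE = (
    "ASP", "LYS", "SER", "GLY", "LEU", "VAL", "ARG",
    "GLU", "HIS", "TRP", "ASN", "GLN", "TYR", "THR",
)


@pytest.fixture(scope="session")
def toy_spec():
    return SyntheticSpec(residue_sequence=STANDARD_SEQUENCE, n_waters=3, n_frames=50, seed=7)


@pytest.fixture(scope="session")
def toy_topology(toy_spec):
    return make_toy_topology(toy_spec)


@pytest.fixture(scope="session")
def toy_participants(toy_topology):
    return build_participant_sets(toy_topology)


@pytest.fixture(scope="session")
def standard_schedules():
    """Schedules covering all three kinds and several occupancy levels."""
    return (
        ContactSchedule(ContactKind.SB, anchor=(0, "OD1"), mobile=(1, "NZ"), pattern=40.0),
        ContactSchedule(ContactKind.HB, anchor=(2, "OG"), mobile=(7, "OE1"), pattern=92.0),
        ContactSchedule(ContactKind.HP, anchor=(4, "CD1"), mobile=(5, "CG1"), pattern=10.0),
    )


def random_frame(topology, seed, spread=1.8, box=None):
    """Random coordinates dense enough to produce many contacts."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, spread, size=(topology.n_atoms, 3))
    return Frame(time=float(seed), coordinates=coords, box=box)


def ca_chain_topology(n_residues):
    """Minimal Cα-only protein topology for structural-metric tests."""
    residues = [
        ResidueRecord(i, "GLY", "A", i + 1, classify_residue("GLY")) for i in range(n_residues)
    ]
    atoms = [AtomRecord(i, "CA", "C", i, AtomRole.MAINCHAIN) for i in range(n_residues)]
    return Topology(atoms=atoms, residues=residues)


def ca_trajectory(coord_stack, dt=2.0):
    """Trajectory over a Cα-only topology from an (n_frames, n_res, 3) stack."""
    coord_stack = np.asarray(coord_stack, dtype=float)
    topo = ca_chain_topology(coord_stack.shape[1])
    frames = [Frame(time=i * dt, coordinates=c) for i, c in enumerate(coord_stack)]
    return Trajectory(topology=topo, frames=frames)
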