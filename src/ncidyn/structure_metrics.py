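"""Structural metrics: superposition, RMSD, RMSF, Cα-Cα distance maps, SASA.

Internal computation stays in nm; RMSD/RMSF are reported in Å and SASA
in nm², matching the mixed reporting convention of thermal-stability
comparisons in this domain.

SASA uses the Shrake-Rupley algorithm: each atom's sphere (van der
Waals radius + probe radius, default 0.14 nm) is sampled with a
Fibonacci point set (default 960 points) and a point counts as
accessible when no neighbouring sphere covers it.  Water is excluded
both as surface and as occluder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .topology_model import ResClass, Topology
from .trajectory_io import Frame, Trajectory

__all__ = [
    "DistanceMatrix",
    "SASAResult",
    "kabsch_superpose",
    "rmsd_ca",
    "rmsf_ca",
    "ca_distance_matrix",
    "matrix_difference",
    "shrake_rupley_sasa",
    "sasa_by_class",
    "sasa_trajectory_by_class",
    "crystal_ca_rmsd",
]

NM_TO_ANGSTROM = 10.0

#: Bondi van der Waals radii, nm.
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

PROBE_RADIUS_NM = 0.14
N_SPHERE_POINTS = 960


@dataclass
class DistanceMatrix:
    """Residue-residue Cα distance matrix (nm), symmetric, zero diagonal."""

    labels: list[int]  # residue indices
    values: np.ndarray  # (N, N) nm
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")


@dataclass
class SASAResult:
    """Per-atom and per-residue accessible areas for one frame, nm²."""

    atom_areas: np.ndarray
    residue_areas: dict[int, float] = field(default_factory=dict)
    class_totals: dict[str, float] = field(default_factory=dict)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of mobile onto reference.

    Returns (rotation, translation, fitted) with fitted = mobile @ R.T + t.
    The rotation is always proper (det = +1); reflections are never fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, s, vt = np.linalg.svd(h)
    # rank < 2 means the point set is collinear/degenerate
    if np.sum(s > 1e-12 * max(s[0], 1e-300)) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_c - rotation @ mob_c
    fitted = mobile @ rotation.T + translation
    return rotation, translation, fitted


def _ca_coords(topology: Topology, coords: np.ndarray) -> np.ndarray:
    idx = topology.ca_indices()
    if not idx:
        raise ValueError("no protein Cα atoms in topology")
    return coords[idx]


def rmsd_ca(
    frame: Frame, reference: Frame, topology: Topology, fit: bool = True
) -> float:
    """Cα RMSD of a frame against a reference, in Å.

    With fit=True (the MD convention) the frame is first superposed onto
    the reference over the same Cα selection.
    """
    x = _ca_coords(topology, frame.coordinates)
    ref = _ca_coords(topology, reference.coordinates)
    if x.shape != ref.shape:
        raise ValueError("Cα selections differ between frame and reference")
    if fit:
        _, _, x = kabsch_superpose(x, ref)
    return float(np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1)))) * NM_TO_ANGSTROM


def rmsf_ca(
    trajectory: Trajectory, reference_mode: str = "initial", fit: bool = True
) -> np.ndarray:
    """Per-residue Cα RMSF over time, in Å.

    Frames are superposed to the reference (first frame, or the mean
    structure after a first-frame alignment pass) and the fluctuation is
    the square root of the time-mean squared displacement per Cα.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if reference_mode not in ("initial", "mean"):
        raise ValueError("reference_mode must be 'initial' or 'mean'")
    topo = trajectory.topology
    stack = np.array([_ca_coords(topo, f.coordinates) for f in trajectory.frames])
    ref = stack[0]
    if fit:
        stack = np.array([kabsch_superpose(x, ref)[2] for x in stack])
    if reference_mode == "mean":
        ref = stack.mean(axis=0)
    sq = np.sum((stack - ref) ** 2, axis=2)  # (n_frames, n_res)
    return np.sqrt(sq.mean(axis=0)) * NM_TO_ANGSTROM


def ca_distance_matrix(trajectory: Trajectory) -> DistanceMatrix:
    """Time-averaged Cα-Cα distance matrix over the analysis window (nm)."""
    topo = trajectory.topology
    idx = topo.ca_indices()
    if not idx:
        raise ValueError("no protein Cα atoms in topology")
    acc = np.zeros((len(idx), len(idx)))
    for f in trajectory.frames:
        ca = f.coordinates[idx]
        acc += cdist(ca, ca)
    acc /= trajectory.n_frames
    labels = [topo.atoms[i].residue_index for i in idx]
    return DistanceMatrix(labels=labels, values=acc, provenance=trajectory.source)


def matrix_difference(
    a: DistanceMatrix, b: DistanceMatrix, flag_threshold: float = 1.0
) -> tuple[DistanceMatrix, list[tuple[int, int, float]]]:
    """Elementwise A - B plus the list of cells with |Δ| ≥ flag_threshold.

    Flags are reported once per unordered residue pair (upper triangle).
    """
    if a.labels != b.labels:
        raise ValueError("distance matrices have different residue labels")
    diff = a.values - b.values
    flags = [
        (a.labels[i], a.labels[j], float(diff[i, j]))
        for i, j in zip(*np.nonzero(np.triu(np.abs(diff) >= flag_threshold, k=1)))
    ]
    out = DistanceMatrix(
        labels=list(a.labels), values=diff, provenance=f"({a.provenance})-({b.provenance})"
    )
    return out, flags


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    frame: Frame,
    topology: Topology,
    probe: float = PROBE_RADIUS_NM,
    n_points: int = N_SPHERE_POINTS,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area per atom (nm²).

    Non-water, non-virtual atoms participate both as surface and as
    occluders; atoms of unknown element raise unless they are water or
    virtual sites (which are skipped).
    """
    sphere = _fibonacci_sphere(n_points)
    water = {r.index for r in topology.residues if r.is_water}
    active: list[int] = []
    radii: list[float] = []
    for a in topology.atoms:
        if a.residue_index in water:
            continue
        r = VDW_RADII_NM.get(a.element)
        if r is None:
            raise ValueError(f"no van der Waals radius for element {a.element!r} (atom {a.name})")
        active.append(a.index)
        radii.append(r + probe)
    if not active:
        raise ValueError("no non-water atoms for SASA")
    coords = frame.coordinates[active]
    radii_arr = np.array(radii)
    tree = cKDTree(coords)
    max_r = radii_arr.max()
    atom_areas = np.zeros(topology.n_atoms)
    for k, (center, rad) in enumerate(zip(coords, radii_arr)):
        points = center + rad * sphere
        neighbors = [n for n in tree.query_ball_point(center, rad + max_r) if n != k]
        accessible = np.ones(n_points, dtype=bool)
        for n in neighbors:
            d2 = np.sum((points - coords[n]) ** 2, axis=1)
            accessible &= d2 > radii_arr[n] ** 2
            if not accessible.any():
                break
        atom_areas[active[k]] = 4.0 * np.pi * rad * rad * accessible.sum() / n_points

    residue_areas: dict[int, float] = {}
    for a in topology.atoms:
        if atom_areas[a.index] > 0 or a.residue_index not in water:
            residue_areas[a.residue_index] = (
                residue_areas.get(a.residue_index, 0.0) + atom_areas[a.index]
            )
    result = SASAResult(atom_areas=atom_areas, residue_areas=residue_areas)
    result.class_totals = _class_totals(result, topology)
    return result


def _class_totals(sasa: SASAResult, topology: Topology) -> dict[str, float]:
    pho = phil = total = 0.0
    for ri, area in sasa.residue_areas.items():
        res = topology.residues[ri]
        if not res.is_protein:
            continue
        total += area
        if res.res_class is ResClass.HYDROPHOBIC:
            pho += area
        elif res.res_class in (ResClass.CHARGED, ResClass.POLAR):
            phil += area
        # OTHER-class residues (e.g. His) count in total only
    return {"hydrophobic": pho, "hydrophilic": phil, "total": total}


def sasa_by_class(sasa: SASAResult, topology: Topology) -> dict[str, float]:
    """Class totals (nm²): hydrophobic, hydrophilic (charged+polar), total."""
    return _class_totals(sasa, topology)


def sasa_trajectory_by_class(
    trajectory: Trajectory,
    probe: float = PROBE_RADIUS_NM,
    n_points: int = N_SPHERE_POINTS,
) -> dict[str, tuple[float, float]]:
    """Time mean ± SD of the SASA class totals over a trajectory."""
    per_frame = {"hydrophobic": [], "hydrophilic": [], "total": []}
    for f in trajectory.frames:
        totals = shrake_rupley_sasa(f, trajectory.topology, probe, n_points).class_totals
        for k in per_frame:
            per_frame[k].append(totals[k])
    return {
        k: (float(np.mean(v)), float(np.std(v, ddof=0))) for k, v in per_frame.items()
    }


def crystal_ca_rmsd(path_a: str, path_b: str) -> float:
    """Cα RMSD (Å) between two crystal structures after Kabsch superposition.

    Chains are matched by order; residues by sequence number within each
    matched chain, so structures with differing missing-residue sets
    compare over their common ordered set.
    """
    from .trajectory_io import read_topology

    topo_a = read_topology(path_a)
    topo_b = read_topology(path_b)

    def ca_map(topo: Topology) -> dict[tuple[str, int], np.ndarray]:
        out = {}
        for i in topo.ca_indices():
            res = topo.residue_of(i)
            out[(res.chain_id, res.sequence_number)] = topo.reference_coordinates[i]
        return out

    map_a, map_b = ca_map(topo_a), ca_map(topo_b)
    chains_a = sorted({c for c, _ in map_a})
    chains_b = sorted({c for c, _ in map_b})
    xs, ys = [], []
    for ca, cb in zip(chains_a, chains_b):
        seqs = sorted(
            {s for c, s in map_a if c == ca} & {s for c, s in map_b if c == cb}
        )
        xs.extend(map_a[(ca, s)] for s in seqs)
        ys.extend(map_b[(cb, s)] for s in seqs)
    if len(xs) < 3:
        raise ValueError("fewer than 3 matched Cα atoms between the two structures")
    _, _, fitted = kabsch_superpose(np.array(xs), np.array(ys))
    return float(np.sqrt(np.mean(np.sum((fitted - np.array(ys)) ** 2, axis=1)))) * NM_TO_ANGSTROM
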