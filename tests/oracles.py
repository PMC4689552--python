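"""Independent brute-force oracles for the detector tests.

Everything here is written directly from the geometric definitions —
plain loops over all pairs/triples — and deliberately shares no code
with the package's detectors.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TOL = 1e-9


def min_image_distance_27(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum distance over the 27 periodic images of b."""
    best = math.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = np.linalg.norm(a - (b + np.asarray(shift) * box))
        best = min(best, d)
    return best


def _dist(coords, i, j, box):
    if box is None:
        return float(np.linalg.norm(coords[i] - coords[j]))
    return min_image_distance_27(coords[i], coords[j], box)


def brute_saltbridges(coords, negatives, positives, d_max=0.4, box=None):
    """All (neg, pos) pairs within d_max."""
    return {
        (i, j)
        for i in negatives
        for j in positives
        if _dist(coords, i, j, box) <= d_max + TOL
    }


def _angle_deg(d, h, a, box=None):
    v1 = np.asarray(d) - np.asarray(h)
    v2 = np.asarray(a) - np.asarray(h)
    if box is not None:
        v1 = v1 - box * np.round(v1 / box)
        v2 = v2 - box * np.round(v2 / box)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def brute_hbonds(
    coords, donor_hydrogens, acceptors, residue_of,
    d_max=0.35, angle_min=120.0, box=None,
):
    """All (donor, hydrogen, acceptor) triples passing distance + angle,
    excluding intra-residue donor-acceptor pairs."""
    found = set()
    for donor, hydrogens in donor_hydrogens.items():
        for acceptor in acceptors:
            if acceptor == donor or residue_of[acceptor] == residue_of[donor]:
                continue
            if _dist(coords, donor, acceptor, box) > d_max + TOL:
                continue
            for h in hydrogens:
                ang = _angle_deg(coords[donor], coords[h], coords[acceptor], box)
                if ang >= angle_min - TOL:
                    found.add((donor, h, acceptor))
    return found


def brute_hydrophobic(coords, carbons, residue_of, d_max=0.4, min_res_sep=1, box=None):
    """All canonically ordered carbon pairs within d_max, residues at
    least min_res_sep apart."""
    carbons = sorted(carbons)
    found = set()
    for i, j in itertools.combinations(carbons, 2):
        if abs(residue_of[i] - residue_of[j]) < min_res_sep:
            continue
        if _dist(coords, i, j, box) <= d_max + TOL:
            found.add((i, j))
    return found


def isolated_sphere_area(radius: float, probe: float) -> float:
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_areas(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Analytic accessible areas of two intersecting spheres.

    Each sphere of radius R_i = r_i + probe loses the spherical cap cut
    off by the radical plane of the intersection circle.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return isolated_sphere_area(r1, probe), isolated_sphere_area(r2, probe)
    # cap height on sphere 1: h1 = R1 - x where x is the distance from
    # center 1 to the plane of intersection
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    x2 = d - x1
    h1 = R1 - x1
    h2 = R2 - x2
    a1 = 4.0 * math.pi * R1 * R1 - 2.0 * math.pi * R1 * h1
    a2 = 4.0 * math.pi * R2 * R2 - 2.0 * math.pi * R2 * h2
    return a1, a2
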