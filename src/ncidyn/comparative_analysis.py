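"""Category decomposition and two-condition difference tables.

Hydrogen bonds are decomposed the way thermostability comparisons
tabulate them: intra-protein (IP) bonds split by donor/acceptor role
into mainchain-mainchain (MM), mainchain-sidechain (MS, both
directions) and sidechain-sidechain (SS), and by residue class into
polar-polar (PP), charged-charged (CC) and hydrophobic-hydrophobic
(HH).  Bonds with exactly one water partner form the protein-water
family, bucketed by the protein partner's role and class.  MM+MS+SS=IP
and mainchain-water + sidechain-water = protein-water are identities, not
approximations, and are enforced by tests.

Differences between two conditions (e.g. 337 K - 300 K) are computed
from the registries, never from rounded report values, after applying
the same existence filter to both sides.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .contact_dynamics import (
    ContactRegistry,
    LifetimeClass,
    accumulate_registry,
    decile_histogram,
    existence_percentage,
    filter_by_existence,
    lifetime_class,
    lifetime_class_counts,
    time_averaged_count,
)
from .interaction_detectors import (
    ContactKey,
    ContactKind,
    detect_hbonds_frame,
    detect_hydrophobic_frame,
    detect_saltbridges_frame,
)
from .topology_model import AtomRole, ResClass, Topology, build_participant_sets
from .trajectory_io import Trajectory

__all__ = [
    "HB_CATEGORIES",
    "CategoryTable",
    "ConditionSummary",
    "ConditionDiff",
    "decompose_hbond_categories",
    "protein_water_hbonds",
    "summarize_condition",
    "condition_difference",
    "export_report",
]

HB_CATEGORIES = (
    "IP", "MM", "MS", "SS", "PP", "CC", "HH",
    "protein_water", "mainchain_water", "sidechain_water",
    "polar_water", "charge_water", "hydrophobic_water",
)


@dataclass
class CategoryTable:
    """Unique and time-averaged HB counts per category for one condition."""

    unique: dict[str, int] = field(default_factory=lambda: {c: 0 for c in HB_CATEGORIES})
    time_averaged: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in HB_CATEGORIES}
    )


def _hb_categories_of(key: ContactKey, topology: Topology) -> list[str]:
    """Category labels of one HB key (empty for water-water bonds)."""
    donor, _, acceptor = key.atoms
    a_d, a_a = topology.atoms[donor], topology.atoms[acceptor]
    r_d, r_a = topology.residue_of(donor), topology.residue_of(acceptor)
    waters = (r_d.is_water, r_a.is_water)
    if all(waters):
        return []
    if any(waters):
        prot_atom = a_a if waters[0] else a_d
        prot_res = r_a if waters[0] else r_d
        cats = ["protein_water"]
        cats.append(
            "mainchain_water" if prot_atom.role is AtomRole.MAINCHAIN else "sidechain_water"
        )
        class_cat = {
            ResClass.POLAR: "polar_water",
            ResClass.CHARGED: "charge_water",
            ResClass.HYDROPHOBIC: "hydrophobic_water",
        }.get(prot_res.res_class)
        if class_cat:
            cats.append(class_cat)
        return cats
    # both protein
    cats = ["IP"]
    roles = {a_d.role, a_a.role}
    if roles == {AtomRole.MAINCHAIN}:
        cats.append("MM")
    elif roles == {AtomRole.SIDECHAIN}:
        cats.append("SS")
    else:
        cats.append("MS")
    same_class = {
        ResClass.POLAR: "PP",
        ResClass.CHARGED: "CC",
        ResClass.HYDROPHOBIC: "HH",
    }
    if r_d.res_class is r_a.res_class and r_d.res_class in same_class:
        cats.append(same_class[r_d.res_class])
    return cats


def decompose_hbond_categories(registry: ContactRegistry, topology: Topology) -> CategoryTable:
    """Assign every HB in the registry to its categories and tally
    unique and time-averaged counts per category."""
    if registry.kind is not ContactKind.HB:
        raise ValueError("category decomposition applies to HB registries only")
    table = CategoryTable()
    for key, series in registry.series.items():
        frac = series.occurrence_count / registry.n_frames
        for cat in _hb_categories_of(key, topology):
            table.unique[cat] += 1
            table.time_averaged[cat] += frac
    return table


def protein_water_hbonds(registry: ContactRegistry, topology: Topology) -> dict[str, int]:
    """Unique counts of HBs with exactly one water partner, by bucket."""
    table = decompose_hbond_categories(registry, topology)
    return {
        c: table.unique[c]
        for c in (
            "protein_water", "mainchain_water", "sidechain_water",
            "polar_water", "charge_water", "hydrophobic_water",
        )
    }


@dataclass
class ConditionSummary:
    """All per-condition results: one registry per contact kind plus the
    detector parameters they were computed with."""

    name: str
    registries: dict[ContactKind, ContactRegistry]
    topology: Topology
    parameters: dict[str, float | int | str]

    def unique_counts(self) -> dict[str, int]:
        return {k.value: r.unique_count for k, r in self.registries.items()}

    def time_averaged(self) -> dict[str, float]:
        return {k.value: time_averaged_count(r) for k, r in self.registries.items()}

    def lifetime_counts(self) -> dict[str, dict[str, int]]:
        return {
            k.value: {c.value: n for c, n in lifetime_class_counts(r).items()}
            for k, r in self.registries.items()
        }

    def decile_histograms(self) -> dict[str, np.ndarray]:
        return {k.value: decile_histogram(r) for k, r in self.registries.items()}

    def hb_categories(self) -> CategoryTable:
        return decompose_hbond_categories(self.registries[ContactKind.HB], self.topology)


def summarize_condition(
    trajectory: Trajectory,
    name: str,
    hb_d_max: float = 0.35,
    hb_angle_min: float = 120.0,
    sb_d_max: float = 0.4,
    hp_d_max: float = 0.4,
    min_res_separation: int = 1,
    use_min_image: bool = False,
) -> ConditionSummary:
    """Run all three detectors over a trajectory window and fold the
    per-frame streams into kind-homogeneous registries."""
    participants = build_participant_sets(trajectory.topology)
    streams = {k: [] for k in ContactKind}
    for frame in trajectory.frames:
        streams[ContactKind.SB].append(
            detect_saltbridges_frame(frame, trajectory.topology, participants, sb_d_max, use_min_image)
        )
        streams[ContactKind.HB].append(
            detect_hbonds_frame(
                frame, trajectory.topology, participants, hb_d_max, hb_angle_min, use_min_image
            )
        )
        streams[ContactKind.HP].append(
            detect_hydrophobic_frame(
                frame, trajectory.topology, participants, hp_d_max, min_res_separation, use_min_image
            )
        )
    registries = {
        k: accumulate_registry(streams[k], k, window=trajectory.source) for k in ContactKind
    }
    return ConditionSummary(
        name=name,
        registries=registries,
        topology=trajectory.topology,
        parameters={
            "hb_d_max": hb_d_max,
            "hb_angle_min": hb_angle_min,
            "sb_d_max": sb_d_max,
            "hp_d_max": hp_d_max,
            "min_res_separation": min_res_separation,
            "use_min_image": int(use_min_image),
        },
    )


@dataclass
class ConditionDiff:
    """Elementwise condition_B - condition_A differences."""

    name_a: str
    name_b: str
    existence_filter: float | None
    unique: dict[str, int] = field(default_factory=dict)
    time_averaged: dict[str, float] = field(default_factory=dict)
    lifetime: dict[str, dict[str, int]] = field(default_factory=dict)
    deciles: dict[str, np.ndarray] = field(default_factory=dict)
    hb_category_unique: dict[str, int] = field(default_factory=dict)
    hb_category_time_averaged: dict[str, float] = field(default_factory=dict)


def _filtered(summary: ConditionSummary, threshold: float | None) -> ConditionSummary:
    if threshold is None:
        return summary
    return ConditionSummary(
        name=summary.name,
        registries={
            k: filter_by_existence(r, threshold) for k, r in summary.registries.items()
        },
        topology=summary.topology,
        parameters=summary.parameters,
    )


def condition_difference(
    summary_a: ConditionSummary,
    summary_b: ConditionSummary,
    existence_filter: float | None = None,
) -> ConditionDiff:
    """B - A differences of every reported quantity, with the same
    existence filter applied to both sides first.

    The two summaries must have been computed with identical detector
    parameters; a mismatch is an error, not a warning.
    """
    mismatched = [
        k
        for k in set(summary_a.parameters) | set(summary_b.parameters)
        if summary_a.parameters.get(k) != summary_b.parameters.get(k)
    ]
    if mismatched:
        raise ValueError(f"condition parameters differ: {sorted(mismatched)}")
    a = _filtered(summary_a, existence_filter)
    b = _filtered(summary_b, existence_filter)
    diff = ConditionDiff(
        name_a=summary_a.name, name_b=summary_b.name, existence_filter=existence_filter
    )
    ua, ub = a.unique_counts(), b.unique_counts()
    diff.unique = {k: ub[k] - ua[k] for k in ua}
    ta, tb = a.time_averaged(), b.time_averaged()
    diff.time_averaged = {k: tb[k] - ta[k] for k in ta}
    la, lb = a.lifetime_counts(), b.lifetime_counts()
    diff.lifetime = {
        k: {c: lb[k][c] - la[k][c] for c in la[k]} for k in la
    }
    da, db = a.decile_histograms(), b.decile_histograms()
    diff.deciles = {k: db[k] - da[k] for k in da}
    ca, cb = a.hb_categories(), b.hb_categories()
    diff.hb_category_unique = {c: cb.unique[c] - ca.unique[c] for c in HB_CATEGORIES}
    diff.hb_category_time_averaged = {
        c: cb.time_averaged[c] - ca.time_averaged[c] for c in HB_CATEGORIES
    }
    return diff


def _registry_dump(summary: ConditionSummary) -> pd.DataFrame:
    rows = []
    for kind, registry in sorted(summary.registries.items(), key=lambda kv: kv[0].value):
        for key in sorted(registry.series):
            s = registry.series[key]
            p = existence_percentage(s)
            atoms = [summary.topology.atoms[i] for i in key.atoms]
            residues = [summary.topology.residue_of(i) for i in key.atoms]
            rows.append(
                {
                    "kind": kind.value,
                    "donor_res": f"{residues[0].name}{residues[0].sequence_number}",
                    "donor_atom": atoms[0].name,
                    "hydrogen": atoms[1].name if kind is ContactKind.HB else "",
                    "acceptor_res": f"{residues[-1].name}{residues[-1].sequence_number}",
                    "acceptor_atom": atoms[-1].name,
                    "existence_percent": round(p, 6),
                    "lifetime_class": lifetime_class(p).value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "donor_res", "donor_atom", "hydrogen",
            "acceptor_res", "acceptor_atom", "existence_percent", "lifetime_class",
        ],
    )


def export_report(
    summaries: Iterable[ConditionSummary],
    diffs: Iterable[ConditionDiff] = (),
    out_dir: str = "report",
) -> list[str]:
    """Write the CSV report suite (summary, categories, lifetime bins,
    registry dumps, and condition differences) with deterministic ordering."""
    summaries = list(summaries)
    diffs = list(diffs)
    if not summaries:
        raise ValueError("at least one condition summary is required")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _write(df: pd.DataFrame, fname: str) -> None:
        path = os.path.join(out_dir, fname)
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    for s in summaries:
        kinds = sorted(k.value for k in s.registries)
        tavg, uniq, life = s.time_averaged(), s.unique_counts(), s.lifetime_counts()
        _write(
            pd.DataFrame(
                {
                    "kind": kinds,
                    "unique_count": [uniq[k] for k in kinds],
                    "time_averaged": [tavg[k] for k in kinds],
                    "short": [life[k]["short"] for k in kinds],
                    "substantial": [life[k]["substantial"] for k in kinds],
                    "long": [life[k]["long"] for k in kinds],
                }
            ),
            f"summary_{s.name}.csv",
        )
        cat = s.hb_categories()
        _write(
            pd.DataFrame(
                {
                    "category": list(HB_CATEGORIES),
                    "unique_count": [cat.unique[c] for c in HB_CATEGORIES],
                    "time_averaged": [cat.time_averaged[c] for c in HB_CATEGORIES],
                }
            ),
            f"hb_categories_{s.name}.csv",
        )
        deciles = s.decile_histograms()
        _write(
            pd.DataFrame(
                {"bin_upper_percent": list(range(10, 101, 10))}
                | {k: deciles[k].tolist() for k in kinds}
            ),
            f"decile_histogram_{s.name}.csv",
        )
        _write(_registry_dump(s), f"registry_{s.name}.csv")

    for d in diffs:
        tag = f"{d.name_b}_minus_{d.name_a}" + (
            f"_filter_le_{d.existence_filter:g}" if d.existence_filter is not None else ""
        )
        kinds = sorted(d.unique)
        _write(
            pd.DataFrame(
                {
                    "kind": kinds,
                    "d_unique": [d.unique[k] for k in kinds],
                    "d_time_averaged": [d.time_averaged[k] for k in kinds],
                    "d_short": [d.lifetime[k]["short"] for k in kinds],
                    "d_substantial": [d.lifetime[k]["substantial"] for k in kinds],
                    "d_long": [d.lifetime[k]["long"] for k in kinds],
                }
            ),
            f"diff_{tag}.csv",
        )
        _write(
            pd.DataFrame(
                {
                    "category": list(HB_CATEGORIES),
                    "d_unique": [d.hb_category_unique[c] for c in HB_CATEGORIES],
                    "d_time_averaged": [d.hb_category_time_averaged[c] for c in HB_CATEGORIES],
                }
            ),
            f"diff_hb_categories_{tag}.csv",
        )
    return written
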