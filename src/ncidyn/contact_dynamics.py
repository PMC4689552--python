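"""Unique-contact registry and lifetime statistics.

A contact observed in at least one analysis frame becomes a unique
contact; its per-frame presence vector yields an existence percentage
(occupancy), which the lifetime classification partitions into
short-lived (0, 10], substantially-lived (10, 90] and long-lived
(90, 100] percent, and the decile histogram refines into ten 10 % bins.
Bin edges are half-open (a, b] exactly as printed in the source
convention; comparisons carry a 1e-9 guard so exact ratios like 37/100
land in the intended bin even after stride arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .interaction_detectors import ContactKey, ContactKind, FrameContacts

__all__ = [
    "LifetimeClass",
    "ContactTimeSeries",
    "ContactRegistry",
    "accumulate_registry",
    "existence_percentage",
    "lifetime_class",
    "filter_by_existence",
    "time_averaged_count",
    "decile_histogram",
]

EDGE_TOL = 1e-9


class LifetimeClass(Enum):
    SHORT = "short"  # 0 < X <= 10 %
    SUBSTANTIAL = "substantial"  # 10 < X <= 90 %
    LONG = "long"  # 90 < X <= 100 %


@dataclass
class ContactTimeSeries:
    """Presence vector of one unique contact over the analysis window."""

    key: ContactKey
    presence: np.ndarray  # bool, length n_frames
    n_frames: int

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (self.n_frames,):
            raise ValueError("presence length must equal n_frames")
        if not self.presence.any():
            raise ValueError("a registered contact must be present in >= 1 frame")

    @property
    def occurrence_count(self) -> int:
        return int(self.presence.sum())


@dataclass
class ContactRegistry:
    """All unique contacts of one kind in one analysis window."""

    kind: ContactKind
    series: dict[ContactKey, ContactTimeSeries] = field(default_factory=dict)
    n_frames: int = 0
    window: str = ""

    @property
    def unique_count(self) -> int:
        return len(self.series)

    def per_frame_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_frames, dtype=int)
        for s in self.series.values():
            counts += s.presence
        return counts

    def keys(self) -> Iterable[ContactKey]:
        return self.series.keys()

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "kind": s.key.kind.value,
                "atoms": ":".join(map(str, s.key.atoms)),
                "existence_percent": existence_percentage(s),
                "lifetime_class": lifetime_class(existence_percentage(s)).value,
            }
            for s in self.series.values()
        ]
        df = pd.DataFrame(rows, columns=["kind", "atoms", "existence_percent", "lifetime_class"])
        return df.sort_values(["kind", "atoms"], ignore_index=True)


def accumulate_registry(
    frame_contacts: Iterable[FrameContacts], kind: ContactKind, window: str = ""
) -> ContactRegistry:
    """Fold a per-frame contact stream into one registry.

    Contacts never observed are not registered; column sums reconstruct
    the per-frame counts exactly.
    """
    stream = list(frame_contacts)
    n_frames = len(stream)
    if n_frames == 0:
        raise ValueError("empty frame stream")
    first_seen: dict[ContactKey, list[int]] = {}
    for t, fc in enumerate(stream):
        for key in fc.contacts:
            if key.kind is not kind:
                raise ValueError(f"stream contains {key.kind.value} in a {kind.value} registry")
            first_seen.setdefault(key, []).append(t)
    registry = ContactRegistry(kind=kind, n_frames=n_frames, window=window)
    for key in sorted(first_seen):
        presence = np.zeros(n_frames, dtype=bool)
        presence[first_seen[key]] = True
        registry.series[key] = ContactTimeSeries(key=key, presence=presence, n_frames=n_frames)
    return registry


def existence_percentage(series: ContactTimeSeries) -> float:
    """Occupancy: 100 x (frames present) / (frames in window)."""
    if series.n_frames <= 0:
        raise ValueError("n_frames must be positive")
    return 100.0 * series.occurrence_count / series.n_frames


def lifetime_class(percent: float) -> LifetimeClass:
    """Classify an occupancy into short/substantial/long-lived.

    Boundaries are inclusive on the right: exactly 10 % is SHORT,
    exactly 90 % is SUBSTANTIAL, anything above (up to 100 %) is LONG.
    """
    if percent <= 0 or percent > 100 + EDGE_TOL:
        raise ValueError(f"occupancy must lie in (0, 100], got {percent}")
    if percent <= 10 + EDGE_TOL:
        return LifetimeClass.SHORT
    if percent <= 90 + EDGE_TOL:
        return LifetimeClass.SUBSTANTIAL
    return LifetimeClass.LONG


def lifetime_class_counts(registry: ContactRegistry) -> dict[LifetimeClass, int]:
    counts = {c: 0 for c in LifetimeClass}
    for s in registry.series.values():
        counts[lifetime_class(existence_percentage(s))] += 1
    return counts


def filter_by_existence(registry: ContactRegistry, threshold_percent: float) -> ContactRegistry:
    """Drop contacts whose occupancy is <= threshold (keep strictly above).

    Matches the reporting convention "excluding interactions existed for
    less than or equal to N % of the time".
    """
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    kept = {
        key: s
        for key, s in registry.series.items()
        if existence_percentage(s) > threshold_percent + EDGE_TOL
    }
    return ContactRegistry(
        kind=registry.kind, series=kept, n_frames=registry.n_frames, window=registry.window
    )


def time_averaged_count(source: ContactRegistry | Iterable[FrameContacts]) -> float:
    """Mean number of contacts per frame (sum over frames / frame count)."""
    if isinstance(source, ContactRegistry):
        if source.n_frames == 0:
            raise ValueError("registry has no frames")
        return float(source.per_frame_counts().mean())
    stream = list(source)
    if not stream:
        return 0.0
    return float(np.mean([len(fc) for fc in stream]))


def decile_histogram(registry: ContactRegistry) -> np.ndarray:
    """Counts of unique contacts per 10 % occupancy bin (0,10], ..., (90,100]."""
    bins = np.zeros(10, dtype=int)
    for s in registry.series.values():
        p = existence_percentage(s)
        idx = int(np.ceil((p - EDGE_TOL) / 10.0)) - 1
        bins[min(max(idx, 0), 9)] += 1
    return bins
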