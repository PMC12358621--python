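"""Electrode montage, canonical pair enumeration and spatial grouping.

The recording montage is a 2x4 grid: four electrodes per hemisphere along
the anterior-posterior axis (frontal, temporal, parietal, occipital).
Channels are numbered 1-8 in the canonical order

    1 frontal right, 2 temporal right, 3 parietal right, 4 occipital right,
    5 occipital left, 6 parietal left, 7 temporal left, 8 frontal left.

All 28 unordered channel pairs are enumerated lexicographically on
(smaller index, larger index); pair 19 is the occipital interhemispheric
pair (4, 5) and pair 9 the right occipitotemporal pair (2, 4).

Pairs are partitioned into seven spatial groups: H1-H4 are interhemispheric
("horizontal") pairs graded by the anterior-posterior distance between the
two regions (H1 = mirror-symmetric, H4 = maximally diagonal), V1-V3 are
intrahemispheric ("vertical") pairs graded by the same distance. Group
sizes are H1=4, H2=6, H3=4, H4=2, V1=6, V2=4, V3=2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Tuple

import pandas as pd

HEMISPHERES = ("right", "left")
REGIONS = ("frontal", "temporal", "parietal", "occipital")

#: anterior-posterior rank of each region (frontal-most = 1)
REGION_RANK = {"frontal": 1, "temporal": 2, "parietal": 3, "occipital": 4}

GROUP_LABELS = ("H1", "H2", "H3", "H4", "V1", "V2", "V3")
GROUP_SIZES = {"H1": 4, "H2": 6, "H3": 4, "H4": 2, "V1": 6, "V2": 4, "V3": 2}


class MontageError(ValueError):
    """Raised for invalid montages or invalid channel pairs."""


@dataclass(frozen=True)
class Channel:
    index: int  # 1-based
    hemisphere: str
    region: str
    label: str  # e.g. "fr" for frontal right
    position: str = ""  # conventional 10-20-style site name, informational


@dataclass(frozen=True)
class Montage:
    channels: Tuple[Channel, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != 8:
            raise MontageError(f"montage must have 8 channels, got {len(self.channels)}")
        if [c.index for c in self.channels] != list(range(1, 9)):
            raise MontageError("channel indices must be 1..8 in order")
        combos = {(c.hemisphere, c.region) for c in self.channels}
        if len(combos) != 8:
            raise MontageError("each (hemisphere, region) combination must occur exactly once")
        for c in self.channels:
            if c.hemisphere not in HEMISPHERES or c.region not in REGIONS:
                raise MontageError(f"bad channel descriptor: {c}")

    def channel(self, index: int) -> Channel:
        if not 1 <= index <= 8:
            raise MontageError(f"channel index {index} out of range 1..8")
        return self.channels[index - 1]

    @property
    def labels(self) -> List[str]:
        return [c.label for c in self.channels]


def default_montage() -> Montage:
    """The canonical 8-channel montage (right hemisphere front-to-back, then
    left hemisphere back-to-front)."""
    order = [
        ("right", "frontal", "F4"),
        ("right", "temporal", "C4"),
        ("right", "parietal", "P4"),
        ("right", "occipital", "O2"),
        ("left", "occipital", "O1"),
        ("left", "parietal", "P3"),
        ("left", "temporal", "C3"),
        ("left", "frontal", "F3"),
    ]
    channels = tuple(
        Channel(
            index=i + 1,
            hemisphere=hemi,
            region=region,
            label=region[0] + hemi[0],
            position=pos,
        )
        for i, (hemi, region, pos) in enumerate(order)
    )
    return Montage(channels)


@dataclass(frozen=True)
class PairEntry:
    pair_index: int  # 1-based
    channel_a: int
    channel_b: int  # a < b
    abbreviation: str  # e.g. "or/ol"


@dataclass(frozen=True)
class PairTable:
    entries: Tuple[PairEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != 28:
            raise MontageError(f"pair table must have 28 entries, got {len(self.entries)}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, pair_index: int) -> PairEntry:
        return self.entries[pair_index - 1]

    def index_of(self, channel_a: int, channel_b: int) -> int:
        a, b = sorted((channel_a, channel_b))
        for e in self.entries:
            if (e.channel_a, e.channel_b) == (a, b):
                return e.pair_index
        raise MontageError(f"no pair ({channel_a}, {channel_b}) in table")


def build_pair_table(montage: Montage) -> PairTable:
    """Enumerate all 28 unordered channel pairs in lexicographic order.

    The abbreviation joins the two channel labels, e.g. pair (4, 5) ->
    ``"or/ol"`` (occipital right / occipital left).
    """
    entries = []
    for k, (a, b) in enumerate(combinations(range(1, 9), 2), start=1):
        entries.append(
            PairEntry(
                pair_index=k,
                channel_a=a,
                channel_b=b,
                abbreviation=f"{montage.channel(a).label}/{montage.channel(b).label}",
            )
        )
    return PairTable(tuple(entries))


def assign_group(pair: Tuple[int, int], montage: Montage) -> str:
    """Spatial group of a channel pair.

    Interhemispheric pairs map to ``H(1 + d)`` and intrahemispheric pairs to
    ``V(d)`` where ``d`` is the absolute difference of the two regions'
    anterior-posterior ranks (diagonal grade). Symmetric in its arguments.
    """
    a, b = pair
    if a == b:
        raise MontageError(f"pair must join two distinct channels, got ({a}, {b})")
    ca, cb = montage.channel(a), montage.channel(b)
    grade = abs(REGION_RANK[ca.region] - REGION_RANK[cb.region])
    if ca.hemisphere != cb.hemisphere:
        return f"H{1 + grade}"
    return f"V{grade}"


@dataclass(frozen=True)
class GroupScheme:
    assignment: Dict[int, str]  # pair_index -> group label
    group_sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes: Dict[str, int] = {g: 0 for g in GROUP_LABELS}
        for pi, g in self.assignment.items():
            if g not in sizes:
                raise MontageError(f"unknown group label {g!r} for pair {pi}")
            sizes[g] += 1
        if not self.group_sizes:
            object.__setattr__(self, "group_sizes", sizes)
        elif self.group_sizes != sizes:
            raise MontageError("declared group_sizes disagree with assignment")

    def members(self, group: str) -> List[int]:
        return [pi for pi, g in sorted(self.assignment.items()) if g == group]


def build_group_scheme(montage: Montage, pair_table: PairTable | None = None) -> GroupScheme:
    """Partition the 28 pairs into the seven H/V distance groups."""
    table = pair_table if pair_table is not None else build_pair_table(montage)
    assignment = {
        e.pair_index: assign_group((e.channel_a, e.channel_b), montage) for e in table
    }
    scheme = GroupScheme(assignment)
    if scheme.group_sizes != GROUP_SIZES:
        raise MontageError(f"group sizes {scheme.group_sizes} != expected {GROUP_SIZES}")
    return scheme


def montage_table(montage: Montage | None = None) -> pd.DataFrame:
    """Audit table: pair_index, channels, abbreviation and group for all 28 pairs."""
    m = montage if montage is not None else default_montage()
    table = build_pair_table(m)
    scheme = build_group_scheme(m, table)
    return pd.DataFrame(
        {
            "pair_index": [e.pair_index for e in table],
            "channel_a": [e.channel_a for e in table],
            "channel_b": [e.channel_b for e in table],
            "abbreviation": [e.abbreviation for e in table],
            "group": [scheme.assignment[e.pair_index] for e in table],
        }
    )
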