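"""Alignment-based conservation classification on reference coordinates.

Each reference position is placed in one of three categories, mirroring
the standard comparative treatment of retroelement families: conserved
across every element in the alignment (ALL_CONSERVED), conserved only
within a focal subgroup such as one element family (GROUP_CONSERVED),
or VARIABLE. Comparison is case-insensitive, T ≡ U, and a gap in any
relevant sequence fails the corresponding conservation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Category",
    "GroupedAlignment",
    "ConservationTrack",
    "map_columns_to_reference",
    "classify_conservation",
    "summarize_interval",
]

GAP = "-"


class Category(str, Enum):
    ALL_CONSERVED = "ALL_CONSERVED"
    GROUP_CONSERVED = "GROUP_CONSERVED"
    VARIABLE = "VARIABLE"


@dataclass
class GroupedAlignment:
    """Equal-length aligned sequences with per-sequence group labels.

    ``groups`` maps sequence id → group name; ``focal_groups`` names the
    subgroup tested when a position is not conserved across all
    sequences. ``reference_id`` selects the coordinate-bearing sequence.
    """

    sequences: dict[str, str]
    groups: dict[str, str]
    reference_id: str
    focal_groups: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference {self.reference_id!r} absent from alignment")
        missing = set(self.sequences) - set(self.groups)
        if missing:
            raise ValueError(f"sequences without group label: {sorted(missing)[:5]}")
        unknown = set(self.focal_groups) - set(self.groups.values())
        if unknown:
            raise ValueError(f"focal groups not present: {sorted(unknown)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def focal_ids(self) -> list[str]:
        return [sid for sid, g in self.groups.items() if g in self.focal_groups]

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass
class ConservationTrack:
    """Per-reference-position category, positions 1..length."""

    categories: dict[int, Category]

    @property
    def length(self) -> int:
        return len(self.categories)

    def __getitem__(self, pos: int) -> Category:
        return self.categories[pos]


def _norm(res: str) -> str:
    return res.upper().replace("T", "U")


def map_columns_to_reference(
    alignment: GroupedAlignment, reference_id: str | None = None
) -> dict[int, int]:
    """Map alignment columns (1-based) to reference positions (1-based).

    Columns where the reference carries a gap are unmapped.
    """
    ref_id = reference_id or alignment.reference_id
    if ref_id not in alignment.sequences:
        raise ValueError(f"reference {ref_id!r} absent from alignment")
    ref = alignment.sequences[ref_id]
    mapping = {}
    pos = 0
    for col, res in enumerate(ref, start=1):
        if res != GAP:
            pos += 1
            mapping[col] = pos
    return mapping


def classify_conservation(alignment: GroupedAlignment) -> ConservationTrack:
    """Three-category conservation classification per reference position.

    ALL_CONSERVED: one identical non-gap residue across every sequence;
    otherwise GROUP_CONSERVED if identical (non-gap) across the focal
    subgroup; otherwise VARIABLE. Gaps count as mismatches.
    """
    focal = alignment.focal_ids
    if not focal:
        raise ValueError("focal subgroup is empty")
    col_map = map_columns_to_reference(alignment)
    seqs = alignment.sequences
    all_ids = list(seqs)
    categories: dict[int, Category] = {}
    for col, pos in col_map.items():
        residues = {_norm(seqs[sid][col - 1]) for sid in all_ids}
        if GAP not in residues and len(residues) == 1:
            categories[pos] = Category.ALL_CONSERVED
            continue
        focal_res = {_norm(seqs[sid][col - 1]) for sid in focal}
        if GAP not in focal_res and len(focal_res) == 1:
            categories[pos] = Category.GROUP_CONSERVED
        else:
            categories[pos] = Category.VARIABLE
    return ConservationTrack(categories)


def summarize_interval(
    track: ConservationTrack, interval: tuple[int, int]
) -> dict[str, dict[str, float]]:
    """Counts and fractions per category over a 1-based inclusive interval."""
    start, end = interval
    if not (1 <= start <= end <= track.length):
        raise ValueError(f"interval [{start},{end}] outside track 1..{track.length}")
    length = end - start + 1
    counts = {cat: 0 for cat in Category}
    for pos in range(start, end + 1):
        counts[track[pos]] += 1
    return {
        cat.value: {"count": counts[cat], "fraction": counts[cat] / length}
        for cat in Category
    }
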