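"""Structural annotation: loop/stem decomposition, pseudoknot core
extraction, and named functional motif intervals.

Coordinates are 1-based inclusive throughout, matching the convention
used for retroelement RNA motifs (e.g. a primer-binding site written
"nucleotides 95–104" has length 10); BED export converts to 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure import Structure, pairs_cross

__all__ = [
    "Stem",
    "LoopElement",
    "PseudoknotCore",
    "MotifAnnotation",
    "enumerate_elements",
    "pseudoknot_core",
    "annotate_motifs",
    "hairpin_loops",
]


class UnsupportedTopologyError(ValueError):
    """More than one crossing helix family in the structure."""


@dataclass(frozen=True)
class Stem:
    """Maximal run of consecutively stacked pairs."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def five_prime(self) -> tuple[int, int]:
        """(start, end) of the 5' strand."""
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def three_prime(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1])


@dataclass(frozen=True)
class LoopElement:
    """One loop: kind ∈ {hairpin, bulge, internal, multibranch, exterior}."""

    kind: str
    positions: tuple[int, ...]
    closing_pair: tuple[int, int] | None = None


@dataclass(frozen=True)
class PseudoknotCore:
    """S1/L2/S2 decomposition of an H-type pseudoknot.

    S1 is the crossing stem whose 5' strand is 5'-most; S2 the stem it
    crosses. L2 is the interhelical loop between S2's 5' strand and
    S1's 3' strand. L1 and L3 are the long loops bridged by S1 and S2
    respectively.
    """

    S1_pairs: tuple[tuple[int, int], ...]
    S2_pairs: tuple[tuple[int, int], ...]
    L2_positions: tuple[int, ...]
    L1_span: tuple[int, int]
    L3_span: tuple[int, int]
    span_3prime: int

    @property
    def s1_length(self) -> int:
        return len(self.S1_pairs)

    @property
    def s2_length(self) -> int:
        return len(self.S2_pairs)

    @property
    def l2_length(self) -> int:
        return len(self.L2_positions)

    def to_dict(self) -> dict:
        return {
            "S1_pairs": [list(p) for p in self.S1_pairs],
            "S2_pairs": [list(p) for p in self.S2_pairs],
            "S1_length": self.s1_length,
            "S2_length": self.s2_length,
            "L2_positions": list(self.L2_positions),
            "L2_length": self.l2_length,
            "L1_span": list(self.L1_span),
            "L3_span": list(self.L3_span),
            "span_3prime": self.span_3prime,
        }


@dataclass(frozen=True)
class MotifAnnotation:
    """Named 1-based inclusive interval on the reference sequence."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed_fields(self) -> tuple[int, int]:
        """(start, end) under the 0-based half-open convention."""
        return (self.start - 1, self.end)


def _nested_view(structure: Structure) -> tuple[Structure, list]:
    """Split into (nested remainder, crossing stems)."""
    crossing = structure.crossing_pairs()
    if not crossing:
        return structure, []
    stems = structure.stems()
    cross_stems = [s for s in stems if any(p in crossing for p in s)]
    # remove the 3'-most crossing stem(s) until nested; H-type needs one
    for stem in cross_stems:
        rest = structure.remove_pairs(stem)
        if rest.is_nested():
            return rest, [stem]
    raise UnsupportedTopologyError("cannot reduce to nested by removing one stem")


def enumerate_elements(
    structure: Structure, collapse_bulges: bool = False
) -> tuple[list[Stem], list[LoopElement]]:
    """Decompose a structure into stems and loop elements.

    Every unpaired position belongs to exactly one loop element (or the
    exterior loop); stems are maximal stacked runs. With
    ``collapse_bulges`` single-nucleotide bulges do not terminate a
    stem, reproducing the "stem with a bulged nucleotide" reading used
    when describing hairpins like SL1a. Pseudoknotted input is
    decomposed on its nested remainder; the crossing stem is appended
    as a stem with no loop assignment.
    """
    nested, cross_stems = _nested_view(structure)
    n = structure.length
    partner = [0] * (n + 2)
    for i, j in nested.pairs:
        partner[i], partner[j] = j, i
    # positions held by the crossing helix are paired, not loop members
    cross_paired = {p for stem in cross_stems for pair in stem for p in pair}

    stems = [Stem(tuple(s)) for s in nested.stems()]
    if collapse_bulges:
        stems = _collapse_single_bulges(stems)

    loops: list[LoopElement] = []

    def children_of(i: int, j: int):
        kids = []
        k = i + 1
        while k < j:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    todo: list[tuple[int, int]] = [(0, n + 1)]
    while todo:
        i, j = todo.pop()
        kids = children_of(i, j)
        todo.extend(kids)
        unpaired = []
        k = i + 1
        for ck, cl in kids:
            unpaired.extend(range(k, ck))
            k = cl + 1
        unpaired.extend(range(k, j))
        unpaired = [p for p in unpaired if p not in cross_paired]
        if i == 0:
            if unpaired:
                loops.append(LoopElement("exterior", tuple(unpaired)))
            continue
        if not kids:
            loops.append(LoopElement("hairpin", tuple(unpaired), (i, j)))
        elif len(kids) == 1 and unpaired:
            kind = "bulge" if (kids[0][0] == i + 1 or kids[0][1] == j - 1) else "internal"
            loops.append(LoopElement(kind, tuple(unpaired), (i, j)))
        elif len(kids) >= 2:
            loops.append(LoopElement("multibranch", tuple(unpaired), (i, j)))
    for stem in cross_stems:
        stems.append(Stem(tuple(stem)))
    return stems, loops


def _collapse_single_bulges(stems: list[Stem]) -> list[Stem]:
    """Merge stems separated by a single bulged nucleotide."""
    stems = sorted(stems, key=lambda s: s.pairs[0])
    merged: list[list[tuple[int, int]]] = []
    for stem in stems:
        if merged:
            pi, pj = merged[-1][-1]
            ci, cj = stem.pairs[0]
            gap5, gap3 = ci - pi - 1, pj - cj - 1
            if {gap5, gap3} == {0, 1}:
                merged[-1].extend(stem.pairs)
                continue
        merged.append(list(stem.pairs))
    return [Stem(tuple(p)) for p in merged]


def hairpin_loops(structure: Structure) -> list[tuple[LoopElement, Stem]]:
    """Hairpin loops with the stem that closes each (pseudoknots allowed)."""
    stems, loops = enumerate_elements(structure)
    by_closing = {s.pairs[-1]: s for s in stems}
    out = []
    for loop in loops:
        if loop.kind == "hairpin" and loop.closing_pair in by_closing:
            out.append((loop, by_closing[loop.closing_pair]))
    return out


def pseudoknot_core(structure: Structure) -> PseudoknotCore | None:
    """Extract the S1/L2/S2 core of an H-type pseudoknot, if present.

    Returns None for a fully nested structure. S1 is named by 5'-ness
    of its 5' strand. Raises :class:`UnsupportedTopologyError` for
    topologies with more than one crossing helix family.
    """
    crossing = structure.crossing_pairs()
    if not crossing:
        return None
    stems = [tuple(s) for s in structure.stems()]
    cross_stems = [s for s in stems if any(p in crossing for p in s)]
    if len(cross_stems) < 2:
        raise UnsupportedTopologyError("crossing pairs not resolvable into two stems")
    # keep only stems that genuinely cross another crossing stem
    involved = [
        s
        for s in cross_stems
        if any(
            pairs_cross(p, q)
            for other in cross_stems
            if other is not s
            for p in s
            for q in other
        )
    ]
    if len(involved) != 2:
        raise UnsupportedTopologyError(
            f"expected one crossing stem pair, found {len(involved)} stems"
        )
    involved.sort(key=lambda s: s[0][0])
    s1, s2 = involved[0], involved[1]
    if not all(pairs_cross(p, q) for p in s1 for q in s2):
        raise UnsupportedTopologyError("crossing stems are not mutually crossing")

    paired = {p for pr in structure.pairs for p in pr}
    s2_5p_end = s2[-1][0]       # 3' end of S2's 5' strand
    s1_3p_start = s1[-1][1]     # 5' end of S1's 3' strand
    L2 = tuple(
        p for p in range(s2_5p_end + 1, s1_3p_start) if p not in paired
    )
    s1_5p_end = s1[-1][0]
    s2_5p_start = s2[0][0]
    s1_3p_end = s1[0][1]
    s2_3p_start = s2[-1][1]
    return PseudoknotCore(
        S1_pairs=tuple(s1),
        S2_pairs=tuple(s2),
        L2_positions=L2,
        L1_span=(s1_5p_end + 1, s2_5p_start - 1),
        L3_span=(s1_3p_end + 1, s2_3p_start - 1),
        span_3prime=max(p for pr in structure.pairs for p in pr),
    )


def annotate_motifs(
    motifs: dict[str, tuple[int, int]] | list[tuple[str, int, int]],
    sequence_length: int,
) -> list[MotifAnnotation]:
    """Validate and emit named motif intervals.

    ``motifs`` maps name → (start, end), 1-based inclusive. Intervals
    outside 1..sequence_length raise a config error.
    """
    items = motifs.items() if isinstance(motifs, dict) else [(n, (s, e)) for n, s, e in motifs]
    out = []
    for name, (start, end) in items:
        if not (1 <= start <= end <= sequence_length):
            raise ValueError(
                f"motif {name!r} interval [{start},{end}] outside 1..{sequence_length}"
            )
        out.append(MotifAnnotation(name, int(start), int(end)))
    return out
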