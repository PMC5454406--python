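"""Secondary-structure container supporting pseudoknotted pair sets."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Structure", "pairs_cross"]


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True when base pairs p and q interleave (i < k < j < l)."""
    (i, j), (k, l) = sorted((tuple(p), tuple(q)))
    return i < k < j < l


@dataclass(frozen=True)
class Structure:
    """A set of base pairs over a sequence of given length.

    Pairs are 1-based ``(i, j)`` tuples with ``i < j``. Each position
    participates in at most one pair. Crossing (pseudoknotted) pairs are
    permitted; helpers expose the nested/crossing split.
    """

    pairs: frozenset[tuple[int, int]]
    length: int
    _partner: dict = field(init=False, repr=False, compare=False, hash=False)

    def __init__(self, pairs, length: int):
        norm = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        partner: dict[int, int] = {}
        for i, j in norm:
            if i == j:
                raise ValueError(f"self-pair at {i}")
            if not (1 <= i <= length and 1 <= j <= length):
                raise ValueError(f"pair ({i},{j}) outside 1..{length}")
            for p, q in ((i, j), (j, i)):
                if p in partner and partner[p] != q:
                    raise ValueError(f"position {p} pairs twice")
                partner[p] = q
        object.__setattr__(self, "pairs", norm)
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "_partner", partner)

    def partner_of(self, pos: int) -> int | None:
        return self._partner.get(pos)

    @property
    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def crossing_pairs(self) -> set[tuple[int, int]]:
        """All pairs involved in at least one crossing."""
        ps = self.sorted_pairs
        out: set[tuple[int, int]] = set()
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                if pairs_cross(ps[a], ps[b]):
                    out.add(ps[a])
                    out.add(ps[b])
        return out

    def is_nested(self) -> bool:
        return not self.crossing_pairs()

    def stems(self) -> list[list[tuple[int, int]]]:
        """Maximal runs of consecutively stacked pairs, 5'→3' ordered.

        A stem is a maximal set {(i,j), (i+1,j-1), ...}; any bulge or
        internal loop terminates a stem.
        """
        remaining = set(self.pairs)
        out = []
        for i, j in self.sorted_pairs:
            if (i, j) not in remaining or (i - 1, j + 1) in self.pairs:
                continue
            run = []
            k, l = i, j
            while (k, l) in remaining:
                run.append((k, l))
                remaining.discard((k, l))
                k, l = k + 1, l - 1
            out.append(run)
        return out

    def remove_pairs(self, drop) -> "Structure":
        return Structure(self.pairs - set(drop), self.length)

    def union(self, other_pairs) -> "Structure":
        return Structure(self.pairs | set(other_pairs), self.length)
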