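"""Kissing-loop candidate detection and palindrome scanning.

A dimerization-initiation ("kissing") interaction joins the apical,
single-stranded loop nucleotides of two hairpins — on the same molecule
or on two copies of it — through an antiparallel duplex. The scanner
extracts apical motifs (hairpin loop plus the k apical base pairs of the
stem), scores all motif pairs for complementarity, and reports ranked
candidates; a symmetric two-duplex complex is flagged when a motif pair
passes in both orientations across two molecule copies.

Complementarity is strict Watson–Crick by default: the biologically
motivating case is a perfectly complementary 7-mer pair, with G·U wobble
available behind a flag. High loop reactivity (= solvent-accessible,
available for intermolecular pairing) is used to rank candidates, never
to filter them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import Stem, hairpin_loops
from .shape import ReactivityProfile
from .structure import Structure

__all__ = [
    "ApicalMotif",
    "KissingCandidate",
    "apical_motif",
    "duplex_score",
    "scan_kissing_pairs",
    "palindrome_scan",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ApicalMotif:
    """Apical window of one hairpin: loop + k apical base pairs."""

    hairpin_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    loop_positions: tuple[int, ...]
    k: int
    molecule: int = 0

    @property
    def window_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class KissingCandidate:
    """Scored pairing of two apical motifs."""

    motif_a: ApicalMotif
    motif_b: ApicalMotif
    duplex_length: int
    pairing: tuple[tuple[int, int], ...]  # window-local 1-based indices
    wobble_used: bool
    mean_loop_reactivity_a: float | None = None
    mean_loop_reactivity_b: float | None = None
    symmetric: bool = False

    @property
    def rank_reactivity(self) -> float:
        vals = [
            v
            for v in (self.mean_loop_reactivity_a, self.mean_loop_reactivity_b)
            if v is not None
        ]
        return float(np.mean(vals)) if vals else 0.0


def _complementary(a: str, b: str, allow_wobble: bool) -> bool:
    if (a, b) in _WC:
        return True
    return allow_wobble and (a, b) in _WOBBLE


def apical_motif(
    structure: Structure, hairpin: tuple | Stem, k: int = 2, seq: str = "",
    hairpin_id: str = "", molecule: int = 0,
) -> ApicalMotif:
    """Extract the apical window of a hairpin: loop plus ``k`` apical pairs.

    ``hairpin`` is a (loop, stem) tuple from :func:`hairpin_loops` (or a
    Stem whose loop is looked up). The window is contiguous and has
    length loop + 2k; ``k`` may not exceed the stem length.
    """
    if isinstance(hairpin, Stem):
        matches = [h for h in hairpin_loops(structure) if h[1] == hairpin]
        if not matches:
            raise ValueError("stem does not close a hairpin loop")
        loop, stem = matches[0]
    else:
        loop, stem = hairpin
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k > stem.length:
        raise ValueError(f"k={k} exceeds stem length {stem.length}")
    if k == 0:
        start, end = loop.positions[0], loop.positions[-1]
    else:
        apical = stem.pairs[-k:]  # the k innermost (apical) pairs
        start, end = apical[0][0], apical[0][1]
    window_seq = seq[start - 1 : end].upper().replace("T", "U") if seq else ""
    return ApicalMotif(
        hairpin_id=hairpin_id or f"hairpin@{loop.closing_pair}",
        start=start,
        end=end,
        sequence=window_seq,
        loop_positions=loop.positions,
        k=k,
        molecule=molecule,
    )


def duplex_score(
    seq_a: str, seq_b: str, allow_wobble: bool = False
) -> tuple[int, tuple[tuple[int, int], ...]]:
    """Best antiparallel duplex between two motifs.

    Maximizes the longest contiguous run of complementary positions over
    all antiparallel alignments. Returns ``(duplex_length, pairing)``
    where pairing holds (pos_in_a, pos_in_b) 1-based window-local
    indices. Watson–Crick pairs always count; G·U only when
    ``allow_wobble``.
    """
    a = seq_a.upper().replace("T", "U")
    b = seq_b.upper().replace("T", "U")
    if not a or not b:
        raise ValueError("motif sequences must be nonempty")
    la, lb = len(a), len(b)
    best_len, best_map = 0, ()
    # antiparallel: a[i] pairs b[j] with i + j = offset (constant per alignment)
    for off in range(0, la + lb - 1):
        run: list[tuple[int, int]] = []
        cur: list[tuple[int, int]] = []
        for i in range(max(0, off - lb + 1), min(la, off + 1)):
            j = off - i
            if _complementary(a[i], b[j], allow_wobble):
                cur.append((i + 1, j + 1))
                if len(cur) > len(run):
                    run = list(cur)
            else:
                cur = []
        if len(run) > best_len:
            best_len, best_map = len(run), tuple(run)
    return best_len, best_map


def _mean_loop_reactivity(
    motif: ApicalMotif, reactivity: ReactivityProfile | None
) -> float | None:
    if reactivity is None:
        return None
    vals = [reactivity.get(p) for p in motif.loop_positions]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


def extract_apical_motifs(
    structure: Structure, seq: str, k: int = 2, molecule: int = 0
) -> list[ApicalMotif]:
    """All apical motifs of a structure, 5'→3', stems shorter than k use
    their full depth."""
    out = []
    for idx, (loop, stem) in enumerate(hairpin_loops(structure)):
        kk = min(k, stem.length)
        out.append(
            apical_motif(
                structure, (loop, stem), kk, seq,
                hairpin_id=f"mol{molecule}.h{idx}", molecule=molecule,
            )
        )
    return out


def scan_kissing_pairs(
    structures: list[tuple[Structure, str]],
    k: int = 2,
    min_len: int = 6,
    allow_wobble: bool = False,
    reactivity: list[ReactivityProfile | None] | None = None,
) -> list[KissingCandidate]:
    """Scan hairpin pairs for kissing-loop candidates.

    ``structures`` holds one (structure, sequence) tuple for a single
    molecule, or two for an intermolecular scan (pass the same tuple
    twice for two copies of one species). All ordered motif pairs are
    scored; candidates with duplex_length ≥ ``min_len`` are reported,
    ranked by duplex length then mean loop reactivity (reactive loops —
    available for intermolecular pairing — rank first). When two
    molecules are supplied and a motif pair passes in both orientations,
    both candidates are flagged as a symmetric two-duplex complex.
    """
    if not 1 <= len(structures) <= 2:
        raise ValueError("supply one or two (structure, sequence) tuples")
    if reactivity is None:
        reactivity = [None] * len(structures)
    motifs = [
        extract_apical_motifs(st, sq, k, molecule=m)
        for m, (st, sq) in enumerate(structures)
    ]
    candidates: list[KissingCandidate] = []
    seen_pairs: set[tuple[str, str]] = set()
    mol_pairs = [(0, 0)] if len(structures) == 1 else [(0, 1), (1, 0), (0, 0), (1, 1)]
    for ma, mb in mol_pairs:
        for a in motifs[ma]:
            for b in motifs[mb]:
                if ma == mb and a.hairpin_id >= b.hairpin_id:
                    continue  # within one molecule, unordered distinct pairs
                key = (a.hairpin_id, b.hairpin_id)
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                length, pairing = duplex_score(a.sequence, b.sequence, allow_wobble)
                if length < min_len:
                    continue
                candidates.append(
                    KissingCandidate(
                        motif_a=a,
                        motif_b=b,
                        duplex_length=length,
                        pairing=pairing,
                        wobble_used=allow_wobble
                        and any(
                            (a.sequence[i - 1], b.sequence[j - 1]) in _WOBBLE
                            for i, j in pairing
                        ),
                        mean_loop_reactivity_a=_mean_loop_reactivity(a, reactivity[ma]),
                        mean_loop_reactivity_b=_mean_loop_reactivity(b, reactivity[mb]),
                    )
                )
    if len(structures) == 2:
        candidates = _flag_symmetric(candidates)
    candidates.sort(
        key=lambda c: (
            -c.duplex_length,
            -c.rank_reactivity,
            c.motif_a.start,
            c.motif_b.start,
        )
    )
    return candidates


def _hairpin_key(hid: str) -> str:
    """Molecule-independent hairpin identity (index within its molecule)."""
    return hid.split(".", 1)[1] if "." in hid else hid


def _flag_symmetric(candidates: list[KissingCandidate]) -> list[KissingCandidate]:
    cross = {
        (
            _hairpin_key(c.motif_a.hairpin_id),
            _hairpin_key(c.motif_b.hairpin_id),
        )
        for c in candidates
        if c.motif_a.molecule != c.motif_b.molecule
    }
    out = []
    for c in candidates:
        if c.motif_a.molecule != c.motif_b.molecule:
            ka = _hairpin_key(c.motif_a.hairpin_id)
            kb = _hairpin_key(c.motif_b.hairpin_id)
            if (kb, ka) in cross:
                c = KissingCandidate(
                    **{**c.__dict__, "symmetric": True}
                )
        out.append(c)
    return out


def palindrome_scan(seq: str, min_len: int = 4, max_len: int = 30) -> list[tuple[int, int]]:
    """Maximal even-length self-reverse-complementary windows.

    Returns 1-based inclusive (start, end) intervals of length within
    [min_len, max_len] that equal their own reverse complement (strict
    WC) and cannot be symmetrically extended.
    """
    if min_len % 2 != 0 or min_len < 4:
        raise ValueError("min_len must be even and at least 4")
    s = seq.upper().replace("T", "U")
    n = len(s)

    def is_pal(i: int, j: int) -> bool:  # 0-based inclusive window
        while i < j:
            if s[j] != _RC.get(s[i], "?"):
                return False
            i, j = i + 1, j - 1
        return True

    out = []
    for center in range(1, n):  # even palindromes centered between center-1|center
        i, j = center - 1, center
        while i >= 0 and j < n and s[j] == _RC.get(s[i], "?"):
            i, j = i - 1, j + 1
        length = j - i - 1
        if length >= min_len:
            start, end = i + 2, j  # 1-based maximal window
            if length > max_len:
                trim = (length - max_len) // 2
                start, end = start + trim, end - trim
            out.append((start, end))
    return sorted(set(out))
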