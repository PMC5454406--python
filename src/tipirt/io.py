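"""File formats: FASTA, .shape, CT, multi-layer dot-bracket, BED,
alignments, TSV tables.

Sequence and alignment parsing is delegated to Biopython; tabular input
to pandas. The ``.shape`` dialect is two whitespace-separated columns
(1-based index, reactivity) with −999 marking excluded positions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO

from .conservation import GroupedAlignment
from .retrostats import CultureCount
from .shape import MISSING, IntensityTable, ReactivityProfile
from .structure import Structure, pairs_cross

__all__ = [
    "read_fasta",
    "read_shape",
    "write_shape",
    "read_intensity_tables",
    "write_ct",
    "read_ct",
    "to_dot_bracket",
    "from_dot_bracket",
    "write_bed",
    "read_grouped_alignment",
    "read_culture_counts",
]

_BRACKETS = [("(", ")"), ("[", "]"), ("{", "}")]


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as id → RNA sequence (T→U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_shape(path) -> ReactivityProfile:
    values: dict[int, float] = {}
    missing: set[int] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos_s, val_s = line.split()[:2]
        pos, val = int(pos_s), float(val_s)
        if val == MISSING:
            missing.add(pos)
        else:
            values[pos] = val
    return ReactivityProfile(values=values, missing=missing)


def write_shape(profile: ReactivityProfile, path, length: int | None = None) -> None:
    """Write 1..length rows; missing/uncovered positions as −999."""
    positions = set(profile.values) | profile.missing
    top = length or (max(positions) if positions else 0)
    lines = []
    for pos in range(1, top + 1):
        val = profile.values.get(pos, MISSING)
        lines.append(f"{pos}\t{val:.4f}" if val != MISSING else f"{pos}\t{MISSING:.0f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_intensity_tables(path) -> list[IntensityTable]:
    """TSV with columns position, treated, control and optional
    replicate/transcript_id/transcript_offset columns; one table per
    (transcript_id, replicate) combination."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "treated", "control"}
    if not required <= set(df.columns):
        raise ValueError(f"intensity TSV needs columns {sorted(required)}")
    if "transcript_id" not in df.columns:
        df["transcript_id"] = "transcript"
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "transcript_offset" not in df.columns:
        df["transcript_offset"] = 1
    out = []
    for (tid, rep), grp in df.groupby(["transcript_id", "replicate"], sort=True):
        grp = grp.sort_values("position")
        out.append(
            IntensityTable(
                position=grp["position"].to_numpy(),
                treated=grp["treated"].to_numpy(),
                control=grp["control"].to_numpy(),
                transcript_offset=int(grp["transcript_offset"].iloc[0]),
                transcript_id=f"{tid}_rep{rep}",
            )
        )
    return out


def write_ct(structure: Structure, seq: str, path, title: str = "tipirt") -> None:
    partner = {i: 0 for i in range(1, structure.length + 1)}
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i
    lines = [f"{structure.length}\t{title}"]
    for i in range(1, structure.length + 1):
        lines.append(
            f"{i}\t{seq[i - 1]}\t{i - 1}\t{(i + 1) if i < structure.length else 0}"
            f"\t{partner[i]}\t{i}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path) -> tuple[Structure, str]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    seq = []
    pairs = set()
    for ln in lines[1 : n + 1]:
        fields = ln.split()
        i, base, j = int(fields[0]), fields[1], int(fields[4])
        seq.append(base)
        if j > i:
            pairs.add((i, j))
    return Structure(frozenset(pairs), n), "".join(seq)


def to_dot_bracket(structure: Structure) -> str:
    """Multi-layer dot-bracket: nested pairs in '()', each successive
    crossing layer in '[]' then '{}'."""
    layers: list[list[tuple[int, int]]] = []
    for pair in structure.sorted_pairs:
        for layer in layers:
            if not any(pairs_cross(pair, q) for q in layer):
                layer.append(pair)
                break
        else:
            layers.append([pair])
    if len(layers) > len(_BRACKETS):
        raise ValueError("structure needs more than three bracket layers")
    chars = ["."] * structure.length
    for layer, (op, cl) in zip(layers, _BRACKETS):
        for i, j in layer:
            chars[i - 1], chars[j - 1] = op, cl
    return "".join(chars)


def from_dot_bracket(db: str) -> Structure:
    stacks: dict[str, list[int]] = {op: [] for op, _ in _BRACKETS}
    closers = {cl: op for op, cl in _BRACKETS}
    pairs = set()
    for pos, ch in enumerate(db, start=1):
        if ch in stacks:
            stacks[ch].append(pos)
        elif ch in closers:
            op = closers[ch]
            if not stacks[op]:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((stacks[op].pop(), pos))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r}")
    for op, stack in stacks.items():
        if stack:
            raise ValueError(f"unclosed {op!r} at {stack}")
    return Structure(frozenset(pairs), len(db))


def write_bed(intervals, path, chrom: str = "ref") -> None:
    """Write (name, start, end) 1-based inclusive intervals as BED
    (0-based half-open)."""
    lines = [
        f"{chrom}\t{start - 1}\t{end}\t{name}" for name, start, end in intervals
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_grouped_alignment(
    alignment_path,
    manifest_path,
    reference_id: str,
    focal_groups: set[str],
    fmt: str = "fasta",
) -> GroupedAlignment:
    """Aligned FASTA/Clustal plus a TSV manifest (sequence_id, group)."""
    aln = AlignIO.read(str(alignment_path), fmt)
    manifest = pd.read_csv(manifest_path, sep="\t")
    if not {"sequence_id", "group"} <= set(manifest.columns):
        raise ValueError("manifest needs columns sequence_id, group")
    groups = dict(zip(manifest["sequence_id"], manifest["group"]))
    return GroupedAlignment(
        sequences={rec.id: str(rec.seq).upper() for rec in aln},
        groups=groups,
        reference_id=reference_id,
        focal_groups=set(focal_groups),
    )


def read_culture_counts(path) -> dict[str, list[CultureCount]]:
    """TSV with columns strain, his_positive, cfu and optional
    his_fraction/cfu_fraction; returns counts grouped by strain."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "his_positive", "cfu"}
    if not required <= set(df.columns):
        raise ValueError(f"counts TSV needs columns {sorted(required)}")
    out: dict[str, list[CultureCount]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["strain"]), []).append(
            CultureCount(
                his_positive=int(row["his_positive"]),
                cfu=int(row["cfu"]),
                his_fraction=float(row.get("his_fraction", 1.0) or 1.0),
                cfu_fraction=float(row.get("cfu_fraction", 1.0) or 1.0),
            )
        )
    return out
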