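"""Synthetic benchmark generator with known ground truth.

Every input the pipeline consumes can be generated here with planted
truth: a structured RNA whose pair set contains an H-type pseudoknot
and a complementary apical motif pair (a miniature of the Ty1 5'
topology — S1/L1/S2a/L2/S1'/L3/S2' with hairpins carrying the kissing
motifs), replicate probing intensities whose reactivities reflect
pairedness, grouped alignments realizing a per-position conservation
plan exactly, and Poisson colony counts at a chosen true
retrotransposition frequency.

Layout defaults mirror the modeled system at reduced scale: a 7-bp S1,
1-nt interhelical loop, 8-bp S2, and two 5-bp-stem hairpins whose
apical 7-mers are reverse complements. Planted stems are GC-biased and
unpaired filler is drawn from {A, C} (which cannot pair with itself),
so the planted signal is recoverable by design while probing noise and
helix competition remain. All outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conservation import Category, ConservationTrack, GroupedAlignment
from .retrostats import CultureCount
from .shape import IntensityTable
from .structure import Structure

__all__ = [
    "PlantSpec",
    "SyntheticTruth",
    "gen_structured_sequence",
    "simulate_shape",
    "gen_alignment",
    "gen_colony_counts",
]

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


@dataclass(frozen=True)
class PlantSpec:
    """Element lengths for the planted topology (all in nucleotides)."""

    s1_len: int = 7
    s2_len: int = 8
    l2_len: int = 1
    hairpin_stem: int = 5
    loop_a: int = 3          # hairpin A loop; apical motif = loop + 2 pairs
    apical_k: int = 2
    flank: int = 2           # unpaired spacer around each hairpin
    tail: int = 3
    gc_bias: float = 0.7     # P(G or C) per planted stem position

    def __post_init__(self) -> None:
        if self.apical_k > self.hairpin_stem:
            raise ValueError("apical_k cannot exceed hairpin stem length")
        if min(self.s1_len, self.s2_len) < 3:
            raise ValueError("pseudoknot stems must be at least 3 bp")
        if self.l2_len < 1 or self.loop_a < 3:
            raise ValueError("infeasible element lengths")

    @property
    def loop_b(self) -> int:
        return self.loop_a + 2 * self.apical_k


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one generated instance."""

    sequence: str
    structure: Structure
    s1_pairs: tuple[tuple[int, int], ...]
    s2_pairs: tuple[tuple[int, int], ...]
    hairpin_a_window: tuple[int, int]   # apical motif interval, 1-based
    hairpin_b_window: tuple[int, int]
    seed: int
    spec: PlantSpec = field(default=PlantSpec())

    @property
    def pseudoknot_pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.s1_pairs) | frozenset(self.s2_pairs)

    def paired_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.sequence), dtype=bool)
        for i, j in self.structure.pairs:
            mask[i - 1] = mask[j - 1] = True
        return mask


def _rand_stem(rng: np.random.Generator, length: int, gc_bias: float) -> str:
    strong = rng.random(length) < gc_bias
    gc = rng.choice(list("GC"), size=length)
    au = rng.choice(list("AU"), size=length)
    return "".join(g if s else a for s, g, a in zip(strong, gc, au))


def _filler(rng: np.random.Generator, length: int) -> str:
    # A/C cannot pair with each other: keeps planted loops truly unpaired
    return "".join(rng.choice(list("AC"), size=length))


def gen_structured_sequence(
    spec: PlantSpec | None = None, seed: int = 0
) -> SyntheticTruth:
    """Generate a sequence realizing the planted pseudoknot + motif pair.

    Sequence order: S1₅' · [flank · hairpinA · flank] · S2₅' · L2 ·
    S1₃' · [flank · hairpinB · flank] · S2₃' · tail. Hairpin B's loop is
    the reverse complement of hairpin A's apical window, planting the
    kissing motif pair. Identical seeds give identical output.
    """
    spec = spec or PlantSpec()
    rng = np.random.default_rng(seed)

    s1a = _rand_stem(rng, spec.s1_len, spec.gc_bias)
    s2a = _rand_stem(rng, spec.s2_len, spec.gc_bias)
    stem_a5 = _rand_stem(rng, spec.hairpin_stem, spec.gc_bias)
    stem_b5 = _rand_stem(rng, spec.hairpin_stem, spec.gc_bias)
    loop_a = _filler(rng, spec.loop_a)

    window_a_seq = stem_a5[-spec.apical_k:] + loop_a + _revcomp(stem_a5)[: spec.apical_k]
    loop_b = _revcomp(window_a_seq)
    assert len(loop_b) == spec.loop_b

    parts = []
    cursor = 1

    def put(s: str) -> tuple[int, int]:
        nonlocal cursor
        parts.append(s)
        span = (cursor, cursor + len(s) - 1)
        cursor += len(s)
        return span

    sp_s1a = put(s1a)
    put(_filler(rng, spec.flank))
    sp_ha5 = put(stem_a5)
    sp_la = put(loop_a)
    sp_ha3 = put(_revcomp(stem_a5))
    put(_filler(rng, spec.flank))
    sp_s2a = put(s2a)
    put(_filler(rng, spec.l2_len))
    sp_s1b = put(_revcomp(s1a))
    put(_filler(rng, spec.flank))
    sp_hb5 = put(stem_b5)
    sp_lb = put(loop_b)
    sp_hb3 = put(_revcomp(stem_b5))
    put(_filler(rng, spec.flank))
    sp_s2b = put(_revcomp(s2a))
    put(_filler(rng, spec.tail))

    seq = "".join(parts)

    def helix(sp5: tuple[int, int], sp3: tuple[int, int]) -> tuple[tuple[int, int], ...]:
        n = sp5[1] - sp5[0] + 1
        return tuple((sp5[0] + t, sp3[1] - t) for t in range(n))

    s1_pairs = helix(sp_s1a, sp_s1b)
    s2_pairs = helix(sp_s2a, sp_s2b)
    ha_pairs = helix(sp_ha5, sp_ha3)
    hb_pairs = helix(sp_hb5, sp_hb3)

    structure = Structure(
        frozenset(s1_pairs) | frozenset(s2_pairs) | frozenset(ha_pairs) | frozenset(hb_pairs),
        len(seq),
    )
    win_a = (sp_ha5[1] - spec.apical_k + 1, sp_ha3[0] + spec.apical_k - 1)
    win_b = (sp_lb[0], sp_lb[1])
    return SyntheticTruth(
        sequence=seq,
        structure=structure,
        s1_pairs=s1_pairs,
        s2_pairs=s2_pairs,
        hairpin_a_window=win_a,
        hairpin_b_window=win_b,
        seed=seed,
        spec=spec,
    )


def simulate_shape(
    truth: SyntheticTruth,
    paired_mean: float = 0.05,
    unpaired_mean: float = 0.9,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    control_level: float = 50.0,
    signal_scale: float = 100.0,
) -> list[IntensityTable]:
    """Replicate treated/control intensity tables for a planted truth.

    Per position a base reactivity is drawn from a gamma distribution
    with mean ``paired_mean`` (paired) or ``unpaired_mean`` (unpaired);
    replicates multiply it by mean-one lognormal noise with log-sd
    ``noise_sd`` (0 → identical replicates). Intensities are
    control_level (control) and control_level + signal_scale·reactivity
    (treated), which round-trip through the processing chain.
    """
    if paired_mean <= 0 or unpaired_mean <= 0:
        raise ValueError("reactivity means must be positive")
    rng = np.random.default_rng(seed)
    n = len(truth.sequence)
    paired = truth.paired_mask()
    shape_k = 2.0  # gamma shape: skewed-positive, overlapping classes
    base = np.where(
        paired,
        rng.gamma(shape_k, paired_mean / shape_k, size=n),
        rng.gamma(shape_k, unpaired_mean / shape_k, size=n),
    )
    tables = []
    positions = np.arange(1, n + 1)
    for r in range(n_replicates):
        if noise_sd > 0:
            noise = rng.lognormal(-0.5 * noise_sd**2, noise_sd, size=n)
        else:
            noise = np.ones(n)
        react = base * noise
        tables.append(
            IntensityTable(
                position=positions,
                treated=control_level + signal_scale * react,
                control=np.full(n, control_level),
                transcript_id=f"synthetic_rep{r + 1}",
            )
        )
    return tables


def gen_alignment(
    reference: str,
    group_sizes: dict[str, int],
    focal_groups: set[str],
    plan: dict[int, Category] | None = None,
    seed: int = 0,
    reference_group: str | None = None,
) -> tuple[GroupedAlignment, ConservationTrack]:
    """Grouped alignment realizing a per-position conservation plan.

    ``plan`` maps reference position → category (default: all
    ALL_CONSERVED). VARIABLE positions receive ≥ 1 substitution inside
    the focal subgroup; GROUP_CONSERVED positions receive ≥ 1
    substitution in a non-focal sequence only. The planted track is
    returned alongside the alignment and is recovered exactly by
    :func:`tipirt.conservation.classify_conservation`.
    """
    reference = reference.upper().replace("T", "U")
    L = len(reference)
    plan = plan or {}
    for pos, cat in plan.items():
        if not 1 <= pos <= L:
            raise ValueError(f"plan position {pos} outside 1..{L}")
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    groups: dict[str, str] = {}
    for gname, count in group_sizes.items():
        for i in range(count):
            sid = f"{gname}_{i + 1}"
            ids.append(sid)
            groups[sid] = gname
    focal_ids = [s for s in ids if groups[s] in focal_groups]
    nonfocal_ids = [s for s in ids if groups[s] not in focal_groups]
    if not focal_ids:
        raise ValueError("focal subgroup is empty")

    ref_group = reference_group or next(g for g in group_sizes if g in focal_groups)
    reference_id = f"{ref_group}_1"

    seqs = {sid: list(reference) for sid in ids}
    alphabet = "ACGU"
    for pos in range(1, L + 1):
        cat = plan.get(pos, Category.ALL_CONSERVED)
        if cat is Category.ALL_CONSERVED:
            continue
        ref_res = reference[pos - 1]
        alt = rng.choice([c for c in alphabet if c != ref_res])
        if cat is Category.GROUP_CONSERVED:
            if not nonfocal_ids:
                raise ValueError("GROUP_CONSERVED plan requires non-focal sequences")
            target = nonfocal_ids[int(rng.integers(len(nonfocal_ids)))]
        else:  # VARIABLE: substitute inside the focal group, never the reference
            pool = [s for s in focal_ids if s != reference_id]
            if not pool:
                raise ValueError("VARIABLE plan requires a second focal sequence")
            target = pool[int(rng.integers(len(pool)))]
        seqs[target][pos - 1] = str(alt)

    alignment = GroupedAlignment(
        sequences={sid: "".join(s) for sid, s in seqs.items()},
        groups=groups,
        reference_id=reference_id,
        focal_groups=set(focal_groups),
    )
    track = ConservationTrack(
        {pos: plan.get(pos, Category.ALL_CONSERVED) for pos in range(1, L + 1)}
    )
    return alignment, track


def gen_colony_counts(
    true_freq: float,
    cfu_mean: float = 2e6,
    n: int = 7,
    seed: int = 0,
    his_fraction: float = 1.0,
    cfu_fraction: float = 1.0,
) -> list[CultureCount]:
    """Poisson colony counts at a true retrotransposition frequency.

    CFU ~ Poisson(cfu_mean) and His+ ~ Poisson(true_freq × CFU), the
    natural counting model for plated colonies; seven replicate cultures
    by default.
    """
    if true_freq < 0:
        raise ValueError("true frequency must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        cfu = int(rng.poisson(cfu_mean))
        cfu = max(cfu, 1)
        his = int(rng.poisson(true_freq * cfu)) if true_freq > 0 else 0
        out.append(
            CultureCount(
                his_positive=his, cfu=cfu,
                his_fraction=his_fraction, cfu_fraction=cfu_fraction,
            )
        )
    return out
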