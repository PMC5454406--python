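# Methods

This note documents the models and procedures the package implements,
the defaults that matter, and what the synthetic benchmarks do and do
not demonstrate.

## Reactivity processing

Raw per-nucleotide reactivity is the difference of integrated
intensities between the reagent-treated and control (mock-treated)
primer-extension experiments; upstream electropherogram alignment and
peak integration are out of scope, the pipeline starts at per-position
intensities. Negative differences are kept through normalization and
treated as "no data" only when converted to folding restraints.

Normalization follows the boxplot convention: values above the upper
fence Q3 + 1.5·IQR are flagged as outliers (the lower fence is ignored
— only unusually high peaks distort the scale); the scale factor is the
mean of the top ⌈0.10·n⌉ non-outlier values; every value, outliers
included, is divided by it. Quartiles use linear interpolation of order
statistics (the "type 7" convention, numpy's default), which the test
oracle mirrors by direct sorting. Whether the outlier fence should be
anchored at Q3 or the median is ambiguous in the field's verbal
convention; Q3 (standard boxplot semantics) was chosen and is asserted
by tests. After normalization the mean of the selected top set is 1 by
construction, and the whole map is invariant to positive rescaling of
the input.

Replicate agreement is enforced positionwise: the sample standard
deviation (n−1 denominator) of normalized reactivities across
replicates is compared to a threshold, default 0.7 on the normalized
scale; positions above it are masked. Profiles from transcripts placed
on the reference by explicit 1-based offsets are averaged per position
(unweighted mean of available values) into the composite profile;
offsets are always explicit inputs, never guessed. Excluded positions
serialize as −999 in `.shape` output.

## Pseudo-free-energy restraints

Reactivity enters folding as ΔG(i) = m·ln(S(i)+1) + b, charged each
time nucleotide i participates in a helix stack, so nucleotides inside
a helix (flanked by two stacks) are charged twice — the convention of
the established restrained-folding framework. Defaults m = 1.8,
b = −0.6 kcal/mol come from that framework's literature; the source
study does not print its own values, so exact energetic agreement with
any particular published run is not claimed, and both parameters are
config keys (`shape.m`, `shape.b`). A switch (`shape.double_charge`)
selects a single-charge convention in which each stack charges only its
inner pair, leaving every stacked nucleotide charged at most once.
Missing and negative reactivities contribute zero.

## Energy model and folding

The nearest-neighbor model is deliberately simplified and bundled as an
editable config, because the scientific claims supported here are about
topology (which helices exist and whether they cross), not absolute
energies:

- stack energy between adjacent pairs = −(s₁+s₂)/2 with per-pair
  strengths s(GC) = 3.3, s(AU) = 2.2, s(GU) = 1.4 kcal/mol;
- loop penalties grow logarithmically: hairpin 5.6 + 1.1·ln(L/3),
  bulge 3.8 + 1.1·ln L, internal 4.1 + 1.1·ln(L/2), total unpaired
  length capped at 30 for two-loops;
- affine multibranch cost 3.4 + 0.4 per branch (closing pair included)
  + 0.1 per unpaired nucleotide;
- minimum hairpin loop 3; only AU/GC/GU pairs form; N never pairs.

`mfe_fold` is a Zuker-style dynamic program over nested structures,
exact under this model (verified against exhaustive enumeration for
short sequences). Ties are broken toward fewer pairs via an energy
perturbation of 10⁻⁶ kcal/mol per pair — negligible against the
parameter scale but deterministic — then by a fixed traceback order, so
identical inputs always give identical structures.

`shapeknots_fold` adds pseudoknot discovery in the spirit of
heuristic-candidate algorithms: maximal complementary helices of ≥ 3 bp
are ranked by stacking + SHAPE energy; each of the top `max_candidates`
(default 10) is forced in turn, its positions barred from a nested
refold of the remainder, and the union is scored. A crossing union is
scored as the nested remainder plus the crossing helix's bare stack
energy plus a pseudoknot initiation penalty (default 3.5 kcal/mol,
configurable); a union that turns out nested is scored as an ordinary
nested structure. The minimum over the nested MFE and all candidates is
returned, so the result is never worse than the nested fold. The search
is restricted to H-type topologies (one crossing helix family);
kissing-hairpin and more deeply knotted topologies are out of scope,
and the annotator raises on them rather than guessing.

## Annotation conventions

Coordinates are 1-based inclusive everywhere in memory and in reports
("nucleotides 155–168" style); BED export converts to 0-based
half-open. A stem is a maximal run of consecutively stacked pairs; by
default any bulge terminates a stem, and a "collapse single bulges"
view merges stems separated by one bulged nucleotide, matching how
hairpins with a single bulge are usually described. In the pseudoknot
core, S1 is the crossing stem whose 5′ strand is 5′-most; L2 is the
unpaired stretch between the end of S2's 5′ strand and the start of
S1's 3′ strand; L1 and L3 are the intervals bridged by S1 and S2.

## Kissing-loop scanning

An apical motif is the hairpin loop plus the k innermost stem pairs
(default k = 2; a 3-nt loop with k = 2 gives a 7-nt window). Duplex
scoring maximizes the longest contiguous complementary run over all
antiparallel alignments; strict Watson–Crick by default — "perfect
complementarity" in the motivating biology is WC — with G·U behind a
flag. Candidates need a duplex of at least `min_len` (default 6) and
are ranked by duplex length, then by mean loop reactivity: a reactive
(solvent-accessible) loop is *available* for intermolecular pairing, so
reactivity supports a candidate but never gates one, since no
principled cutoff exists. When two molecule copies are scanned and a
motif pair passes in both orientations, both candidates are flagged as
a symmetric complex (two kissing duplexes). Palindrome scanning reports
maximal even-length windows equal to their own reverse complement.
Conservation may be attached as an optional annotation; it never
filters candidates.

## Conservation classification

Each reference position is ALL_CONSERVED when every aligned sequence
carries the same non-gap residue, else GROUP_CONSERVED when the focal
subgroup does, else VARIABLE. Comparisons are case-insensitive with
T ≡ U. A gap anywhere in the tested set fails the corresponding test —
"conserved" is read strictly; whether gapped columns should instead be
ignored is genuinely ambiguous, and the strict reading is the
conservative one. Columns where the reference is gapped carry no
reference coordinate and are skipped. Alignment computation itself
(e.g. Clustal) is upstream of this package.

## Retrotransposition statistics

Per-culture frequency is (His+/fraction plated)/(CFU/fraction plated).
Replicates are summarized by the median (midpoint convention for even
n) with the exact sign-test order-statistic interval: the largest k
with 1 − 2·P(Bin(n,½) ≤ k−1) ≥ 0.95 gives (x₍k₎, x₍n+1−k₎). For n = 7
that is k = 1, i.e. the full range at 98.4 % coverage — the standard
distribution-free interval at this sample size; the summary records
which method produced it since verbal reports of "95 % CI" rarely say.
For n < 6 no symmetric order-statistic interval reaches 95 %; the full
range is returned with a warning. Percent-of-reference is
100·(mutant median)/(reference median). A recombination-background
subtraction is deliberately not applied by default.

## Synthetic data: what it emulates, what it does not

The generator's default instance is a 72-nt miniature of the modeled
topology: S1 (7 bp) and S2 (8 bp) crossing around a 1-nt interhelical
loop, one hairpin in L1 whose apical window (3-nt loop + 2 pairs,
7 nt) is reverse-complementary to the 7-nt loop of a hairpin in L3 —
the planted kissing pair. Planted stems are GC-biased (P(G/C) = 0.7
per position) and unpaired filler is drawn from {A, C}, an alphabet
that cannot pair with itself, so the planted signal is recoverable by
design while register competition from stem/filler interactions and
probing noise remain.

Simulated probing draws a per-position base reactivity from a gamma
distribution (shape 2) with mean 0.05 at paired and 0.9 at unpaired
positions — overlapping but separable classes — and multiplies by
mean-one lognormal replicate noise (log-sd default 0.2, three
replicates); intensities are emitted as control 50 / treated
50 + 100·reactivity so they round-trip the processing chain. Alignments
realize a per-position category plan exactly (variable positions get a
focal-group substitution, group-conserved positions a non-focal one),
and colony counts are Poisson: CFU ~ Poisson(2×10⁶), His+ ~
Poisson(frequency × CFU), seven cultures — plain counting statistics.

Passing the planted-recovery benchmarks therefore shows that the
algorithm chain is internally correct and that the pseudoknot heuristic
finds crossing helices when probing data is informative at this scale.
It does not show that the energy model ranks structures the way real
RNA does, that recovery holds at full transcript length (hundreds of
nucleotides with many competing helices), or anything about real
electrophoresis artifacts (signal decay, primer stalls), none of which
are simulated.

## Problem sizes

The exhaustive-enumeration oracle runs on 200 random sequences of 8–18
nt, where complete enumeration of nested structures is tractable;
planted-recovery uses 50 seeded 72-nt instances; conservation recovery
100 seeded alignments of 13 sequences × 50 positions; CI coverage
10,000 Monte-Carlo draws at n = 7. These sizes make the whole suite run
in well under a minute per property while keeping each check
statistically meaningful.

## Known limitations

- The energy model is not Turner-accurate; absolute energies are not
  comparable to standard folding packages, only topologies are.
- Pseudoknot search covers H-type only, and only helices present as
  maximal complementary runs among the top-ranked candidates.
- The crossing helix is scored without loop-geometry terms beyond a
  flat initiation penalty; pseudoknot loop-length effects are ignored.
- Conservation treats all sequences as independent; no phylogenetic
  weighting.
- Composite merging averages whatever overlaps; it does not model
  inter-transcript scale differences beyond each transcript's own
  normalization.
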