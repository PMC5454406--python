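"""Nearest-neighbor MFE folding with SHAPE restraints and an H-type
pseudoknot discovery heuristic.

The model is a deliberately simplified nearest-neighbor scheme: stacking
energies derived from per-pair strengths (GC > AU > GU), logarithmic
loop penalties, an affine multibranch term, and a fixed initiation
penalty for introducing one crossing helix. It is bundled as an editable
config because the scientific claims this package supports are about
structural topology (which helices form, whether they cross), not about
absolute free energies.

``mfe_fold`` is a Zuker-style dynamic program over nested structures;
``shapeknots_fold`` layers a pseudoknot search on top of it: candidate
helices (maximal complementary runs of ≥ 3 bp, ranked by stacking +
SHAPE energy) are each forced in turn, the remaining sequence is
refolded around them, and the best-scoring structure — never worse than
the nested MFE — is returned.

SHAPE reactivities enter as pseudo-energies dG(i) = m·ln(S+1) + b
charged once per helix stack a nucleotide participates in, so reactive
(flexible) nucleotides resist pairing.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .restraints import RestraintParams, pseudo_energy_array
from .shape import ReactivityProfile
from .structure import Structure

__all__ = ["EnergyModel", "mfe_fold", "energy_of", "shapeknots_fold", "enumerate_helices"]

INF = math.inf
#: deterministic tie-break: among equal-energy structures prefer fewer pairs
PAIR_EPS = 1e-6

_CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


@dataclass
class EnergyModel:
    """Simplified nearest-neighbor parameters (kcal/mol).

    pair_strength: per-pair stability; the energy of stacking pair p on
        pair q is −(strength(p) + strength(q)) / 2.
    Loop penalties grow logarithmically from a base cost:
        hairpin(L)  = hairpin_base  + slope·ln(L / min_hairpin)
        bulge(L)    = bulge_base    + slope·ln(L)
        internal(L) = internal_base + slope·ln(L / 2)
    multibranch: affine offset + per-branch + per-unpaired costs.
    pk_init_penalty: charged once for the crossing helix of a pseudoknot.
    """

    pair_strength: dict = field(
        default_factory=lambda: {
            "GC": 3.3, "CG": 3.3, "AU": 2.2, "UA": 2.2, "GU": 1.4, "UG": 1.4,
        }
    )
    hairpin_base: float = 5.6
    bulge_base: float = 3.8
    internal_base: float = 4.1
    loop_log_slope: float = 1.1
    multibranch_offset: float = 3.4
    multibranch_branch: float = 0.4
    multibranch_unpaired: float = 0.1
    pk_init_penalty: float = 3.5
    min_hairpin: int = 3
    max_internal: int = 30

    def can_pair(self, a: str, b: str) -> bool:
        return (a + b) in self.pair_strength and (a + b) in _CANONICAL

    def stack_energy(self, outer: str, inner: str) -> float:
        """Energy of stacking pair ``inner`` directly inside ``outer``."""
        return -0.5 * (self.pair_strength[outer] + self.pair_strength[inner])

    def hairpin_penalty(self, L: int) -> float:
        if L < self.min_hairpin:
            raise ValueError(f"hairpin loop of {L} < min {self.min_hairpin}")
        return self.hairpin_base + self.loop_log_slope * math.log(L / self.min_hairpin)

    def bulge_penalty(self, L: int) -> float:
        return self.bulge_base + self.loop_log_slope * math.log(L)

    def internal_penalty(self, L: int) -> float:
        return self.internal_base + self.loop_log_slope * math.log(L / 2.0)

    def multibranch_penalty(self, n_branches: int, n_unpaired: int) -> float:
        # n_branches counts interior helices; the closing pair adds one more
        return (
            self.multibranch_offset
            + self.multibranch_branch * (n_branches + 1)
            + self.multibranch_unpaired * n_unpaired
        )


def _clean_seq(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def _shape_vector(
    seq_len: int,
    shape: ReactivityProfile | np.ndarray | None,
    params: RestraintParams,
) -> np.ndarray:
    """Per-nucleotide pseudo-energies (0-based), zeros when no data."""
    if shape is None:
        return np.zeros(seq_len)
    if isinstance(shape, ReactivityProfile):
        react = shape.to_array(seq_len)
    else:
        react = np.asarray(shape, dtype=float)
        if react.shape[0] != seq_len:
            raise ValueError("reactivity vector length != sequence length")
    return pseudo_energy_array(react, params)


def _stack_shape_charge(dg: np.ndarray, i: int, j: int, params: RestraintParams) -> float:
    """SHAPE charge for the stack of pair (i,j) on (i+1,j-1), 0-based.

    double_charge=True charges all four nucleotides per stack (so
    helix-interior nucleotides, flanked by two stacks, pay twice);
    False charges only the inner pair, once per nucleotide overall.
    """
    if params.double_charge:
        return dg[i] + dg[j] + dg[i + 1] + dg[j - 1]
    return dg[i + 1] + dg[j - 1]


# ---------------------------------------------------------------------------
# scoring an explicit structure


def energy_of(
    structure: Structure,
    seq: str,
    model: EnergyModel | None = None,
    shape=None,
    params: RestraintParams | None = None,
) -> float:
    """Free energy (kcal/mol) of an explicit structure under the model.

    Nested structures are scored by loop decomposition. A pseudoknotted
    structure is scored as: nested remainder + crossing helix scored as
    bare stacks + ``pk_init_penalty``; when more than one crossing stem
    could be "the" pseudoknot helix, the minimum-energy assignment is
    used.
    """
    model = model or EnergyModel()
    params = params or RestraintParams()
    seq = _clean_seq(seq)
    if structure.length != len(seq):
        raise ValueError("structure length does not match sequence")
    for i, j in structure.pairs:
        if not model.can_pair(seq[i - 1], seq[j - 1]):
            raise ValueError(f"illegal pair ({i},{j}): {seq[i-1]}-{seq[j-1]}")
        if j - i <= model.min_hairpin:
            raise ValueError(f"pair ({i},{j}) violates minimum hairpin length")
    dg = _shape_vector(len(seq), shape, params)

    crossing = structure.crossing_pairs()
    if not crossing:
        return _nested_energy(structure, seq, model, dg, params)

    # try removing each crossing stem; keep assignments that leave the
    # rest nested, score the removed helix as bare stacks + pk penalty
    candidates = []
    cross_stems = [s for s in structure.stems() if any(p in crossing for p in s)]
    for stem in cross_stems:
        rest = structure.remove_pairs(stem)
        if not rest.is_nested():
            continue
        e = (
            _nested_energy(rest, seq, model, dg, params)
            + _helix_energy(stem, seq, model, dg, params)
            + model.pk_init_penalty
        )
        candidates.append(e)
    if not candidates:
        raise ValueError("unsupported topology: more than one crossing helix family")
    return min(candidates)


def _helix_energy(stem, seq: str, model: EnergyModel, dg, params) -> float:
    """Stacking + SHAPE energy of a stand-alone helix (no loop terms)."""
    e = 0.0
    for (i, j), (k, l) in zip(stem, stem[1:]):
        assert (k, l) == (i + 1, j - 1)
        e += model.stack_energy(seq[i - 1] + seq[j - 1], seq[k - 1] + seq[l - 1])
        e += _stack_shape_charge(dg, i - 1, j - 1, params)
    return e


def _nested_energy(structure: Structure, seq, model, dg, params) -> float:
    n = len(seq)
    partner = [0] * (n + 2)
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i

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

    total = 0.0
    # stack of closing pairs to score; virtual exterior pair (0, n+1)
    todo = [(0, n + 1)]
    while todo:
        i, j = todo.pop()
        kids = children_of(i, j)
        todo.extend(kids)
        if i == 0:  # exterior loop: no penalty
            continue
        if not kids:
            total += model.hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                total += model.stack_energy(seq[i - 1] + seq[j - 1], seq[k - 1] + seq[l - 1])
                total += _stack_shape_charge(dg, i - 1, j - 1, params)
            elif u1 == 0 or u2 == 0:
                total += model.bulge_penalty(u1 + u2)
            else:
                total += model.internal_penalty(u1 + u2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += model.multibranch_penalty(len(kids), unpaired)
    return total


# ---------------------------------------------------------------------------
# nested MFE dynamic program


def mfe_fold(
    seq: str,
    model: EnergyModel | None = None,
    shape=None,
    params: RestraintParams | None = None,
    banned: set[int] | None = None,
) -> Structure:
    """Minimum-free-energy nested structure (Zuker-style DP).

    ``banned`` is an optional set of 1-based positions prohibited from
    pairing (used by the pseudoknot search). Ties are broken toward
    fewer pairs, then by a fixed deterministic traceback order.
    """
    model = model or EnergyModel()
    params = params or RestraintParams()
    seq = _clean_seq(seq)
    n = len(seq)
    if n == 0:
        return Structure(frozenset(), 0)
    dg = _shape_vector(n, shape, params)
    banned0 = {b - 1 for b in (banned or set())}

    minh = model.min_hairpin
    maxi = model.max_internal
    mb_b = model.multibranch_branch
    mb_c = model.multibranch_unpaired
    mb_close = model.multibranch_offset + model.multibranch_branch

    # pairability and per-5'-end partner lists
    can = model.can_pair
    pairable = [[False] * n for _ in range(n)]
    partners: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        if i in banned0:
            continue
        for j in range(i + minh + 1, n):
            if j in banned0:
                continue
            if can(seq[i], seq[j]):
                pairable[i][j] = True
                partners[i].append(j)

    # precompute loop penalty tables
    hp = [INF] * (n + 1)
    for L in range(minh, n + 1):
        hp[L] = model.hairpin_penalty(L)
    bulge = [INF] * (maxi + 1)
    intl = [INF] * (maxi + 1)
    for L in range(1, maxi + 1):
        bulge[L] = model.bulge_penalty(L)
        if L >= 2:
            intl[L] = model.internal_penalty(L)

    # stack energy incl. SHAPE for pair (i,j) stacked on (i+1,j-1)
    def stack_e(i: int, j: int) -> float:
        return model.stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1]) + (
            _stack_shape_charge(dg, i, j, params)
        )

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]

    for d in range(minh + 1, n):
        for i in range(n - d):
            j = i + d
            Vi = INF
            if pairable[i][j]:
                Vi = hp[d - 1] + PAIR_EPS
                # stacks, bulges, internal loops (u1 + u2 ≤ max_internal)
                kmax = min(i + maxi + 1, j - minh - 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    row = partners[k]
                    lmin = max(k + minh + 1, j - 1 - (maxi - u1))
                    for idx in range(bisect_left(row, lmin), len(row)):
                        l = row[idx]
                        if l >= j:
                            break
                        v = V[k][l]
                        if v == INF:
                            continue
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            e = v + stack_e(i, j) + PAIR_EPS
                        elif u1 == 0 or u2 == 0:
                            e = v + bulge[u1 + u2] + PAIR_EPS
                        else:
                            e = v + intl[u1 + u2] + PAIR_EPS
                        if e < Vi:
                            Vi = e
                # multibranch closure: ≥ 2 branches inside
                row_wm = WM[i + 1]
                base = mb_close + PAIR_EPS
                for k in range(i + 2, j - 1):
                    a = row_wm[k]
                    if a == INF:
                        continue
                    b = WM[k + 1][j - 1]
                    if b == INF:
                        continue
                    e = base + a + b
                    if e < Vi:
                        Vi = e
                V[i][j] = Vi
            # WM: segment of a multibranch loop holding ≥ 1 branch
            best = Vi + mb_b if Vi != INF else INF
            a = WM[i + 1][j] if i + 1 <= j else INF
            if a != INF and a + mb_c < best:
                best = a + mb_c
            a = WM[i][j - 1] if j - 1 >= i else INF
            if a != INF and a + mb_c < best:
                best = a + mb_c
            row_wm = WM[i]
            for k in range(i, j):
                a = row_wm[k]
                if a == INF:
                    continue
                b = WM[k + 1][j]
                if b == INF:
                    continue
                if a + b < best:
                    best = a + b
            WM[i][j] = best

    # exterior loop
    W = [0.0] * (n + 1)  # W[t] = best over prefix seq[0:t]
    for t in range(1, n + 1):
        j = t - 1
        best = W[t - 1]
        for k in range(0, j - minh):
            v = V[k][j]
            if v == INF:
                continue
            e = W[k] + v
            if e < best:
                best = e
        W[t] = best

    pairs = _traceback(n, V, WM, W, pairable, partners, minh, maxi, hp, bulge, intl,
                       stack_e, mb_close, mb_b, mb_c)
    return Structure(frozenset((i + 1, j + 1) for i, j in pairs), n)


def _traceback(n, V, WM, W, pairable, partners, minh, maxi, hp, bulge, intl,
               stack_e, mb_close, mb_b, mb_c):
    EPS = 1e-9
    pairs: list[tuple[int, int]] = []
    stack: list[tuple] = [("W", n)]
    while stack:
        task = stack.pop()
        kind = task[0]
        if kind == "W":
            t = task[1]
            if t == 0:
                continue
            j = t - 1
            if abs(W[t] - W[t - 1]) <= EPS:
                stack.append(("W", t - 1))
                continue
            done = False
            for k in range(0, j - minh):
                v = V[k][j]
                if v != INF and abs(W[t] - (W[k] + v)) <= EPS:
                    stack.append(("W", k))
                    stack.append(("V", k, j))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError("exterior traceback failed")
        elif kind == "V":
            _, i, j = task
            pairs.append((i, j))
            target = V[i][j]
            if abs(target - (hp[j - i - 1] + PAIR_EPS)) <= EPS:
                continue
            done = False
            kmax = min(i + maxi + 1, j - minh - 1)
            for k in range(i + 1, kmax + 1):
                u1 = k - i - 1
                for l in partners[k]:
                    if l >= j:
                        break
                    v = V[k][l]
                    if v == INF:
                        continue
                    u2 = j - l - 1
                    if u1 + u2 > maxi:
                        continue
                    if u1 == 0 and u2 == 0:
                        e = v + stack_e(i, j) + PAIR_EPS
                    elif u1 == 0 or u2 == 0:
                        e = v + bulge[u1 + u2] + PAIR_EPS
                    else:
                        e = v + intl[u1 + u2] + PAIR_EPS
                    if abs(target - e) <= EPS:
                        stack.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 2, j - 1):
                a, b = WM[i + 1][k], WM[k + 1][j - 1]
                if a != INF and b != INF and abs(target - (mb_close + PAIR_EPS + a + b)) <= EPS:
                    stack.append(("WM", i + 1, k))
                    stack.append(("WM", k + 1, j - 1))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError(f"V traceback failed at ({i},{j})")
        else:  # WM
            _, i, j = task
            target = WM[i][j]
            if V[i][j] != INF and abs(target - (V[i][j] + mb_b)) <= EPS:
                stack.append(("V", i, j))
                continue
            if i + 1 <= j and WM[i + 1][j] != INF and abs(target - (WM[i + 1][j] + mb_c)) <= EPS:
                stack.append(("WM", i + 1, j))
                continue
            if j - 1 >= i and WM[i][j - 1] != INF and abs(target - (WM[i][j - 1] + mb_c)) <= EPS:
                stack.append(("WM", i, j - 1))
                continue
            done = False
            for k in range(i, j):
                a, b = WM[i][k], WM[k + 1][j]
                if a != INF and b != INF and abs(target - (a + b)) <= EPS:
                    stack.append(("WM", i, k))
                    stack.append(("WM", k + 1, j))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError(f"WM traceback failed at ({i},{j})")
    return pairs


# ---------------------------------------------------------------------------
# pseudoknot heuristic


def enumerate_helices(
    seq: str, model: EnergyModel | None = None, min_len: int = 3,
    shape=None, params: RestraintParams | None = None,
) -> list[tuple[float, list[tuple[int, int]]]]:
    """Maximal complementary helices of ≥ ``min_len`` bp, ranked by energy.

    Returns (energy, pairs) tuples sorted most stable first; pairs are
    1-based. Energy is the stand-alone stacking + SHAPE score.
    """
    model = model or EnergyModel()
    params = params or RestraintParams()
    seq = _clean_seq(seq)
    n = len(seq)
    dg = _shape_vector(n, shape, params)
    minh = model.min_hairpin
    out = []
    for i in range(1, n + 1):
        for j in range(i + minh + 1, n + 1):
            if not model.can_pair(seq[i - 1], seq[j - 1]):
                continue
            # only start at outer-maximal pairs
            if i > 1 and j < n and model.can_pair(seq[i - 2], seq[j]):
                continue
            run = []
            k, l = i, j
            while l - k > minh and model.can_pair(seq[k - 1], seq[l - 1]):
                run.append((k, l))
                k, l = k + 1, l - 1
            if len(run) >= min_len:
                e = _helix_energy(run, seq, model, dg, params)
                out.append((e, run))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def shapeknots_fold(
    seq: str,
    shape=None,
    model: EnergyModel | None = None,
    params: RestraintParams | None = None,
    max_candidates: int = 10,
) -> Structure:
    """Fold allowing at most one crossing (pseudoknot) helix.

    The nested MFE is computed first; then each of the ``max_candidates``
    most stable candidate helices is forced in turn (its positions
    barred from the nested refold), charged ``pk_init_penalty``, and the
    overall minimum-energy structure is returned. The result is never
    worse than the nested MFE.
    """
    model = model or EnergyModel()
    params = params or RestraintParams()
    seq = _clean_seq(seq)
    nested = mfe_fold(seq, model, shape, params)
    best = nested
    best_e = energy_of(nested, seq, model, shape, params)
    best_np = len(nested.pairs)
    for _helix_e, helix in enumerate_helices(seq, model, 3, shape, params)[:max_candidates]:
        banned = {p for pair in helix for p in pair}
        rest = mfe_fold(seq, model, shape, params, banned=banned)
        cand = rest.union(helix)
        # scored by the same function that scores the nested fold: a
        # crossing union pays bare-stack helix energy + pk_init_penalty,
        # a non-crossing union is scored as an ordinary nested structure
        total = energy_of(cand, seq, model, shape, params)
        n_pairs = len(cand.pairs)
        if total < best_e - 1e-9 or (abs(total - best_e) <= 1e-9 and n_pairs < best_np):
            best, best_e, best_np = cand, total, n_pairs
    return best
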