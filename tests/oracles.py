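"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithmic paths: quantiles
by hand interpolation over a sorted copy, structure enumeration by
recursion, duplex search by exhaustive offset/run checking.
"""

from __future__ import annotations

import math
from functools import lru_cache

_CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}
_WC = {"AU", "UA", "GC", "CG"}
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def quantile_type7(sorted_vals: list[float], q: float) -> float:
    """Linear interpolation of order statistics (the common default)."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def boxplot_normalize_oracle(values: list[float]) -> tuple[list[float], float]:
    """Direct-sorting reimplementation of top-10% boxplot normalization."""
    s = sorted(values)
    q1 = quantile_type7(s, 0.25)
    q3 = quantile_type7(s, 0.75)
    fence = q3 + 1.5 * (q3 - q1)
    keep = [v for v in s if v <= fence]
    n_top = math.ceil(0.10 * len(keep))
    scale = sum(keep[-n_top:]) / n_top
    return [v / scale for v in values], scale


def sample_sd(values: list[float]) -> float:
    """Direct n−1 sample standard deviation."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def enumerate_nested_structures(seq: str, min_hairpin: int = 3, banned=frozenset()):
    """All legal nested pair sets (0-based pairs) for a sequence.

    ``banned`` holds 1-based positions prohibited from pairing.
    """
    n = len(seq)

    def pairable(i: int, j: int) -> bool:
        if (i + 1) in banned or (j + 1) in banned:
            return False
        return seq[i] + seq[j] in _CANONICAL

    @lru_cache(maxsize=None)
    def structs(i: int, j: int):
        if j - i < min_hairpin + 1:
            return (frozenset(),)
        out = list(structs(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if pairable(i, k):
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.append(left | right | {(i, k)})
        return tuple(out)

    if n == 0:
        return (frozenset(),)
    result = structs(0, n - 1)
    structs.cache_clear()
    return result


def duplex_score_oracle(a: str, b: str, allow_wobble: bool = False) -> int:
    """Longest contiguous complementary run over every antiparallel offset."""
    ok = _CANONICAL if allow_wobble else _WC
    best = 0
    for off in range(len(a) + len(b) - 1):
        run = 0
        for i in range(len(a)):
            j = off - i
            if 0 <= j < len(b) and a[i] + b[j] in ok:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def palindrome_windows_oracle(seq: str, min_len: int) -> set[tuple[int, int]]:
    """All maximal even self-reverse-complement windows (1-based)."""

    def is_pal(i: int, j: int) -> bool:  # 0-based inclusive
        return all(seq[j - t] == _RC.get(seq[i + t], "?") for t in range(j - i + 1))

    hits = set()
    n = len(seq)
    for i in range(n):
        for j in range(i + min_len - 1, n, 1):
            if (j - i + 1) % 2 == 0 and is_pal(i, j):
                extendable = i > 0 and j < n - 1 and is_pal(i - 1, j + 1)
                if not extendable:
                    hits.add((i + 1, j + 1))
    # drop windows strictly inside a longer reported window with same center
    return hits
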