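"""Retrotransposition-frequency statistics.

A reporter assay yields, per replicate culture, a count of selectable
colonies (His+ prototrophs, each marking one retrotransposition event)
and a total colony-forming-unit (CFU) count from a plated dilution. The
per-culture frequency is (His+ / fraction plated) over (CFU / fraction
plated); replicate medians are summarized with a distribution-free 95 %
confidence interval built from order statistics (the sign-test
interval), the standard choice for a median of seven replicates when no
distributional form is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CultureCount", "FrequencySummary", "frequency", "median_ci",
           "percent_of_reference", "summarize_counts"]


@dataclass(frozen=True)
class CultureCount:
    """Colony counts for one culture.

    ``his_fraction``/``cfu_fraction`` are the fractions of the culture
    plated for each count (dilution scaling).
    """

    his_positive: int
    cfu: int
    his_fraction: float = 1.0
    cfu_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.his_positive < 0 or self.cfu < 0:
            raise ValueError("counts must be nonnegative")
        if not (0 < self.his_fraction <= 1 and 0 < self.cfu_fraction <= 1):
            raise ValueError("plated fractions must lie in (0, 1]")


@dataclass(frozen=True)
class FrequencySummary:
    """Replicate frequencies with median and order-statistic 95 % CI."""

    frequencies: tuple[float, ...]
    median: float
    ci_lower: float
    ci_upper: float
    level: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.median <= self.ci_upper):
            raise ValueError("CI does not bracket the median")


def frequency(culture: CultureCount) -> float:
    """Per-culture retrotransposition frequency.

    (His+ scaled to the whole culture) / (CFU scaled to the whole
    culture) = (his/his_fraction) / (cfu/cfu_fraction).
    """
    if culture.cfu == 0:
        raise ValueError("cannot compute frequency with zero CFU")
    return (culture.his_positive / culture.his_fraction) / (
        culture.cfu / culture.cfu_fraction
    )


def sign_test_order_index(n: int, level: float = 0.95) -> int | None:
    """Largest k such that (x(k), x(n+1−k)) has sign-test coverage ≥ level.

    Coverage of the symmetric order-statistic interval for the median is
    1 − 2·P(Bin(n, ½) ≤ k−1). Returns None when even k = 1 fails.
    """
    best = None
    for k in range(1, n // 2 + 1):
        coverage = 1.0 - 2.0 * stats.binom.cdf(k - 1, n, 0.5)
        if coverage >= level:
            best = k
        else:
            break
    return best


def median_ci(frequencies, level: float = 0.95) -> FrequencySummary:
    """Median with distribution-free order-statistic confidence interval.

    The interval is (x(k), x(n+1−k)) with k the largest order index
    whose sign-test coverage reaches ``level`` (k = 1 at n = 7, giving
    the full range x(1)..x(7) at 98.4 % coverage). For n too small to
    reach the level, the full range is returned with a warning.
    """
    freqs = tuple(float(f) for f in frequencies)
    n = len(freqs)
    if n < 1:
        raise ValueError("need at least one replicate")
    ordered = sorted(freqs)
    med = float(np.median(ordered))
    k = sign_test_order_index(n, level)
    if k is None:
        warnings.warn(
            f"n={n} cannot reach {level:.0%} coverage; CI degenerates to full range",
            stacklevel=2,
        )
        k = 1 if n >= 2 else None
    if k is None:  # n == 1
        lo = hi = ordered[0]
    else:
        lo, hi = ordered[k - 1], ordered[n - k]
    return FrequencySummary(
        frequencies=freqs, median=med, ci_lower=lo, ci_upper=hi, level=level, n=n
    )


def percent_of_reference(
    mutant: FrequencySummary, reference: FrequencySummary
) -> float:
    """Mutant median as a percentage of the reference (wild-type) median."""
    if reference.median <= 0:
        raise ValueError("reference median must be positive")
    return 100.0 * mutant.median / reference.median


def summarize_counts(cultures, level: float = 0.95) -> FrequencySummary:
    """Frequencies + median CI for a list of :class:`CultureCount`."""
    return median_ci([frequency(c) for c in cultures], level=level)
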