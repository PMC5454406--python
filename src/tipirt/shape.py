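"""Chemical-probing (SHAPE) reactivity processing.

Turns raw per-nucleotide treated/control intensities from replicate
probing experiments into a single composite, normalized reactivity
profile over reference coordinates.

The processing chain mirrors standard SHAPE practice:

1. raw reactivity = treated − control intensity, per position;
2. boxplot ("2–8 %"-style) normalization: high outliers above
   Q3 + 1.5·IQR are excluded, the profile is divided by the mean of the
   top 10 % most reactive remaining positions;
3. positions whose normalized reactivity varies across replicates with a
   sample standard deviation above a threshold (default 0.7) are masked;
4. replicate/transcript profiles are averaged position-wise onto
   reference coordinates to form a composite profile.

Missing positions are encoded as −999 in ``.shape`` files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -999.0

__all__ = [
    "IntensityTable",
    "ReactivityProfile",
    "compute_raw_reactivity",
    "boxplot_normalize",
    "filter_by_sd",
    "composite_merge",
]


class DegenerateInputError(ValueError):
    """Raised when normalization cannot define a positive scale factor."""


@dataclass
class IntensityTable:
    """Per-nucleotide probing intensities for one transcript replicate.

    Positions are 1-based on the transcript; ``transcript_offset`` places
    transcript nucleotide 1 on the reference (1-based).
    """

    position: np.ndarray
    treated: np.ndarray
    control: np.ndarray
    transcript_offset: int = 1
    transcript_id: str = "transcript"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=int)
        self.treated = np.asarray(self.treated, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if not (len(self.position) == len(self.treated) == len(self.control)):
            raise ValueError("position/treated/control lengths differ")
        if len(np.unique(self.position)) != len(self.position):
            raise ValueError("duplicate positions in intensity table")
        if np.any(self.treated < 0) or np.any(self.control < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class ReactivityProfile:
    """Normalized reactivities keyed by 1-based position.

    ``missing`` holds positions excluded by QC; excluded positions carry
    no value. ``scale_factor`` is the divisor used during normalization
    and ``n_replicates`` the per-position count of contributing
    replicates.
    """

    values: dict[int, float] = field(default_factory=dict)
    missing: set[int] = field(default_factory=set)
    scale_factor: float = 1.0
    n_replicates: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        overlap = self.missing & set(self.values)
        if overlap:
            raise ValueError(f"positions both missing and valued: {sorted(overlap)[:5]}")

    def get(self, pos: int) -> float | None:
        """Reactivity at ``pos`` or None when missing/uncovered."""
        return self.values.get(pos)

    def to_array(self, length: int) -> np.ndarray:
        """Dense 1..length array with NaN at missing/uncovered positions."""
        arr = np.full(length, np.nan)
        for pos, val in self.values.items():
            if 1 <= pos <= length:
                arr[pos - 1] = val
        return arr


def compute_raw_reactivity(treated, control) -> np.ndarray:
    """Elementwise treated − control intensity.

    Negative differences are retained; downstream restraint code treats
    negative reactivities as absent.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError(
            f"treated and control differ in length ({treated.shape} vs {control.shape})"
        )
    if np.any(treated < 0) or np.any(control < 0):
        raise ValueError("intensities must be nonnegative")
    return treated - control


def boxplot_normalize(raw) -> tuple[np.ndarray, float]:
    """Normalize reactivities by the mean of the top 10 % non-outlier values.

    High outliers — values above Q3 + 1.5·IQR (quartiles by linear
    interpolation of order statistics) — are excluded from scale-factor
    estimation only. The scale factor is the mean of the top
    ceil(0.10·n_remaining) non-outlier values; every value, outliers
    included, is divided by it.

    Returns ``(normalized, scale_factor)``.
    """
    raw = np.asarray(raw, dtype=float)
    finite = raw[np.isfinite(raw)]
    if finite.size < 10:
        raise ValueError("need at least 10 finite values to normalize")
    q1, q3 = np.quantile(finite, [0.25, 0.75])  # linear interpolation (type 7)
    fence = q3 + 1.5 * (q3 - q1)
    keep = finite[finite <= fence]
    if keep.size == 0:
        raise DegenerateInputError("all values are boxplot outliers")
    n_top = int(np.ceil(0.10 * keep.size))
    top = np.sort(keep)[-n_top:]
    scale = float(np.mean(top))
    if scale <= 0:
        raise DegenerateInputError(
            f"scale factor {scale} is not positive (flat or nonreactive profile)"
        )
    return raw / scale, scale


def filter_by_sd(profiles, threshold: float = 0.7) -> np.ndarray:
    """Mask positions whose replicate SD exceeds ``threshold``.

    ``profiles`` is a (n_replicates, n_positions) array of normalized
    reactivities sharing positions. Returns a boolean exclusion mask
    (True = excluded). Sample SD uses the n−1 denominator.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2:
        raise ValueError("profiles must be a 2-D replicate × position array")
    if arr.shape[0] < 2:
        warnings.warn("single replicate: SD filter is a no-op", stacklevel=2)
        return np.zeros(arr.shape[1], dtype=bool)
    sd = np.std(arr, axis=0, ddof=1)
    return sd > threshold


def composite_merge(
    profiles: list[ReactivityProfile],
    offsets: list[int] | None = None,
) -> ReactivityProfile:
    """Average overlapping transcript profiles onto reference coordinates.

    Each profile's positions are shifted by its 1-based transcript offset
    (position p maps to reference p + offset − 1). Per reference
    position, the unweighted mean of all available (non-excluded) values
    is taken; positions masked in every covering profile are reported as
    missing, positions covered by no transcript are absent entirely.
    """
    if offsets is None:
        offsets = [1] * len(profiles)
    if len(offsets) != len(profiles):
        raise ValueError("one offset per profile required")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    masked: set[int] = set()
    for prof, off in zip(profiles, offsets):
        for pos, val in prof.values.items():
            ref = pos + off - 1
            sums[ref] = sums.get(ref, 0.0) + val
            counts[ref] = counts.get(ref, 0) + 1
        for pos in prof.missing:
            masked.add(pos + off - 1)
    values = {p: sums[p] / counts[p] for p in sums}
    missing = {p for p in masked if p not in values}
    return ReactivityProfile(
        values=values, missing=missing, scale_factor=1.0, n_replicates=counts
    )


def process_replicates(
    tables: list[IntensityTable],
    sd_threshold: float = 0.7,
) -> tuple[ReactivityProfile, dict]:
    """Full single-transcript chain: raw → normalize → SD filter → average.

    Returns the replicate-averaged profile (in transcript coordinates,
    offset recorded from the first table) and a QC report dict.
    """
    if not tables:
        raise ValueError("no intensity tables supplied")
    positions = tables[0].position
    for t in tables[1:]:
        if not np.array_equal(t.position, positions):
            raise ValueError("replicate tables must share positions")
    normalized = []
    scales = []
    for t in tables:
        raw = compute_raw_reactivity(t.treated, t.control)
        norm, scale = boxplot_normalize(raw)
        normalized.append(norm)
        scales.append(scale)
    arr = np.vstack(normalized)
    excluded = (
        filter_by_sd(arr, sd_threshold)
        if arr.shape[0] >= 2
        else np.zeros(arr.shape[1], dtype=bool)
    )
    mean = np.mean(arr, axis=0)
    values = {
        int(p): float(v) for p, v, ex in zip(positions, mean, excluded) if not ex
    }
    missing = {int(p) for p, ex in zip(positions, excluded) if ex}
    profile = ReactivityProfile(
        values=values,
        missing=missing,
        scale_factor=float(np.mean(scales)),
        n_replicates={int(p): arr.shape[0] for p in positions},
    )
    report = {
        "transcript_id": tables[0].transcript_id,
        "transcript_offset": tables[0].transcript_offset,
        "scale_factors": [float(s) for s in scales],
        "n_replicates": len(tables),
        "sd_threshold": sd_threshold,
        "excluded_positions": sorted(missing),
    }
    return profile, report
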