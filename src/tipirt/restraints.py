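"""Pseudo-free-energy restraints from SHAPE reactivities.

Reactivity S at a nucleotide is converted into an energy term

    dG(i) = m * ln(S(i) + 1) + b        [kcal/mol]

added to the nearest-neighbor model each time nucleotide i takes part in
a helix stack. Flexible (reactive) nucleotides are thereby penalized for
pairing, while unreactive nucleotides (b < 0) are rewarded. Missing or
negative reactivities contribute nothing.

Defaults m = 1.8, b = −0.6 kcal/mol follow the established restraint
parameterization for this functional form; both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RestraintParams", "shape_pseudo_energy", "pseudo_energy_array"]


@dataclass(frozen=True)
class RestraintParams:
    """Slope/intercept of the log-linear reactivity→energy map.

    m: kcal/mol per ln-unit of (S + 1); must be ≥ 0.
    b: kcal/mol intercept (the energy charged at S = 0).
    double_charge: charge helix-interior nucleotides once per flanking
        stack (twice in total) when True; once overall when False.
    """

    m: float = 1.8
    b: float = -0.6
    double_charge: bool = True

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("slope m must be nonnegative")


def shape_pseudo_energy(S: float | None, params: RestraintParams) -> float:
    """Pseudo-energy for one nucleotide with reactivity ``S`` (kcal/mol).

    None, NaN or negative S → 0 (treated as no data).
    """
    if S is None:
        return 0.0
    S = float(S)
    if math.isnan(S) or S < 0:
        return 0.0
    return params.m * math.log(S + 1.0) + params.b


def pseudo_energy_array(reactivities, params: RestraintParams) -> np.ndarray:
    """Vector of per-nucleotide pseudo-energies; NaN/negative → 0."""
    arr = np.asarray(reactivities, dtype=float)
    out = np.zeros_like(arr)
    ok = np.isfinite(arr) & (arr >= 0)
    out[ok] = params.m * np.log(arr[ok] + 1.0) + params.b
    return out
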