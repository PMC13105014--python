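"""Geometric twist-strain model for cross-beta fibrils.

A cross-beta structure stacks peptide molecules at b ~ 0.48 nm along the
growth axis.  If the fibril twists with cross-over distance d, successive
molecules are rotated by

    rho = b * pi / d        (radians)

about the axis.  A conformationally ordered segment of extended length L,
rotating rigidly about its midpoint, then has its N- and C-terminal ends
displaced transversely by L * sin(rho/2) relative to the molecule above, so
the intermolecular distance at the segment ends grows to

    s = sqrt(b^2 + L^2 * sin^2(rho/2))      (nm).

Large s strains the backbone hydrogen bonds at segment ends; this couples
ordered-segment length to attainable twist rate and is why short ordered
cores permit rapid twisting (small d) while long cores force slow twisting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "DEFAULT_STACKING_NM",
    "StrainProfile",
    "inter_molecular_angle",
    "end_spacing",
    "max_ordered_length",
    "strain_profile",
    "sweep",
]

#: Cross-beta stacking distance between molecules along the growth axis, nm.
DEFAULT_STACKING_NM = 0.48


def _check(b: float, d: float | None = None, L: float | None = None) -> None:
    if b <= 0:
        raise InvalidParameterError(f"stacking distance b must be positive, got {b}")
    if d is not None and not (d > 0):
        raise InvalidParameterError(f"cross-over distance d must be positive, got {d}")
    if L is not None and L < 0:
        raise InvalidParameterError(f"ordered length L must be non-negative, got {L}")


def inter_molecular_angle(d: float, b: float = DEFAULT_STACKING_NM) -> float:
    """Rotation rho = b*pi/d (radians) between successive molecules.

    ``d`` is the cross-over distance in nm.  ``d = inf`` (untwisted) gives 0.
    """
    _check(b, d=d)
    if math.isinf(d):
        return 0.0
    return b * math.pi / d


def end_spacing(L: float, d: float, b: float = DEFAULT_STACKING_NM) -> float:
    """Intermolecular distance (nm) at the ends of an ordered segment.

    ``s = sqrt(b^2 + L^2 sin^2(rho/2))`` with ``rho = b*pi/d``.  Monotone
    increasing in L and decreasing in d; equals b exactly for L = 0 or
    d = inf.
    """
    _check(b, d=d, L=L)
    rho = inter_molecular_angle(d, b)
    return math.sqrt(b * b + (L * math.sin(rho / 2.0)) ** 2)


def max_ordered_length(d: float, s_max: float, b: float = DEFAULT_STACKING_NM) -> float:
    """Longest ordered segment whose end spacing stays below ``s_max``.

    Inverse of :func:`end_spacing` in L: ``L* = sqrt(s_max^2 - b^2) /
    sin(rho/2)``.  Formalizes the constraint that overly stretched end
    spacings cannot sustain stable backbone hydrogen bonds, limiting the
    twist rate a long ordered core can support.  ``s_max = b`` returns 0;
    ``s_max < b`` is infeasible and raises.
    """
    _check(b, d=d)
    if s_max < b:
        raise InvalidParameterError(
            f"no feasible length: s_max={s_max} is below the stacking distance b={b}"
        )
    if s_max == b:
        return 0.0
    rho = inter_molecular_angle(d, b)
    if rho == 0.0:
        return math.inf
    return math.sqrt(s_max * s_max - b * b) / math.sin(rho / 2.0)


@dataclass(frozen=True)
class StrainProfile:
    """One evaluation of the twist-strain model."""

    L: float  # ordered-segment length, nm
    d: float  # cross-over distance, nm
    b: float  # stacking distance, nm
    rho: float  # inter-molecular rotation, radians
    s: float  # end spacing, nm


def strain_profile(L: float, d: float, b: float = DEFAULT_STACKING_NM) -> StrainProfile:
    return StrainProfile(L=L, d=d, b=b, rho=inter_molecular_angle(d, b), s=end_spacing(L, d, b))


def sweep(L_values, d_values, b: float = DEFAULT_STACKING_NM) -> "np.ndarray":
    """End spacing over an (L, d) grid; returns array of shape (len(L), len(d))."""
    L = np.asarray(list(L_values), dtype=float)
    d = np.asarray(list(d_values), dtype=float)
    out = np.empty((L.size, d.size))
    for i, li in enumerate(L):
        for j, dj in enumerate(d):
            out[i, j] = end_spacing(float(li), float(dj), b)
    return out
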