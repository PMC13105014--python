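"""Helical-symmetry algebra for twisted cross-beta fibrils.

A fibril polymorph is characterized by the screw operation relating
successive repeats: a rotation (twist, degrees) about the growth axis plus an
axial translation (rise, angstroms).  Two-protofilament fibrils come in three
symmetry classes:

* ``C2`` -- the two cross-beta subunits are related by an exact 2-fold
  rotation about the growth axis; the helical repeat is one molecular layer
  per subunit (twist of a few degrees, rise ~4.7 A).
* ``pseudo-2_1`` -- the subunits are related by an approximate 2-fold screw:
  a single-start helix whose per-repeat twist is near +-180 deg with rise
  ~2.35 A (half the cross-beta stacking distance).
* ``C1`` -- the repeat contains conformationally inequivalent molecules not
  related by any symmetry operation.

The central observable in electron micrographs is the cross-over distance:
the axial distance over which the elongated cross-section rotates by 180 deg,
seen as the spacing between apparent width minima.  It follows directly from
twist and rise once the ~180 deg screw component of pseudo-2_1 twists is
removed, which is what :func:`fold_twist` does.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import InvalidParameterError
from .geometry import RigidTransform

__all__ = [
    "SYMMETRIES",
    "HelicalParams",
    "fold_twist",
    "crossover_distance",
    "twist_from_crossover",
    "ScrewOperator",
    "symmetry_operators",
    "read_params_table",
    "write_params_table",
]

SYMMETRIES = ("C1", "C2", "pseudo-2_1")

#: Accepted spellings for symmetry labels (depositions and CLIs vary).
_SYMMETRY_ALIASES = {
    "c1": "C1",
    "c2": "C2",
    "c_2": "C2",
    "pseudo-2_1": "pseudo-2_1",
    "pseudo-21": "pseudo-2_1",
    "pseudo2_1": "pseudo-2_1",
    "pseudo21": "pseudo-2_1",
    "quasi-2_1": "pseudo-2_1",
    "quasi 2_1": "pseudo-2_1",
    "quasi21": "pseudo-2_1",
    "2_1": "pseudo-2_1",
    "21": "pseudo-2_1",
}

_HANDEDNESS = ("left", "right", "undetermined")


def normalize_symmetry(label: str) -> str:
    key = str(label).strip().lower().replace("₁", "1").replace("₂", "2")
    if key in _SYMMETRY_ALIASES:
        return _SYMMETRY_ALIASES[key]
    raise InvalidParameterError(f"unknown symmetry label: {label!r}")


@dataclass
class HelicalParams:
    """Refined helical symmetry of one fibril polymorph.

    ``twist``/``rise`` are per helical repeat, exactly as deposited: for
    pseudo-2_1 polymorphs the repeat is one screw application (twist near
    +-180 deg), for C2 one layer, for two-molecule C1 repeats the full
    two-layer repeat.  ``handedness`` is metadata from map-model comparison
    and is never inferred from the sign of ``twist`` (depositions use both
    sign conventions for right-handed fibrils).
    """

    twist: float  # degrees per repeat, signed, stored verbatim
    rise: float  # angstroms per repeat
    symmetry: str = "C1"
    molecules_per_repeat: int = 1
    handedness: str = "undetermined"
    crossover_nm: float | None = None  # optional printed/measured value
    name: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.twist) or not math.isfinite(self.rise):
            raise InvalidParameterError("twist and rise must be finite")
        if self.rise <= 0:
            raise InvalidParameterError(f"rise must be positive, got {self.rise}")
        self.symmetry = normalize_symmetry(self.symmetry)
        if self.molecules_per_repeat < 1:
            raise InvalidParameterError("molecules_per_repeat must be >= 1")
        if self.handedness not in _HANDEDNESS:
            raise InvalidParameterError(
                f"handedness must be one of {_HANDEDNESS}, got {self.handedness!r}"
            )


def fold_twist(twist: float) -> float:
    """Reduce a per-repeat twist to its net cross-section rotation.

    Pseudo-2_1 twists are deposited as values near +-180 deg (one screw step).
    The apparent morphology depends only on the rotation modulo 180 deg, which
    this returns in the half-open interval (-90, +90].  A pure 2_1 screw
    (twist exactly +-180) folds to 0: an apparently untwisted fibril.
    Idempotent.
    """
    t = float(twist)
    if not math.isfinite(t):
        raise InvalidParameterError(f"twist must be finite, got {twist!r}")
    f = math.remainder(t, 180.0)
    if f <= -90.0:
        f += 180.0
    return f + 0.0  # normalize -0.0


def crossover_distance(p: HelicalParams | None = None, *, twist: float | None = None,
                       rise: float | None = None) -> tuple[float, int | None]:
    """Cross-over distance implied by helical symmetry.

    The cross-section rotates by ``fold_twist(twist)`` per ``rise``; the
    cross-over is the axial distance for a 180 deg rotation:

        d = rise * 180 / |fold_twist(twist)|     (A -> nm)

    Returns ``(d_nm, d_rounded)`` where ``d_rounded`` is the nearest-integer
    nanometre value printed in structure tables.  An untwisted fibril
    (fold_twist == 0) yields ``(inf, None)`` -- a representable state, since
    apparently untwisted fibrils do occur.
    """
    if p is not None:
        twist, rise = p.twist, p.rise
    if twist is None or rise is None:
        raise InvalidParameterError("crossover_distance needs twist and rise")
    if rise <= 0:
        raise InvalidParameterError(f"rise must be positive, got {rise}")
    f = fold_twist(twist)
    if f == 0.0:
        return math.inf, None
    d_nm = rise * 180.0 / abs(f) / 10.0
    return d_nm, int(round(d_nm))


def twist_from_crossover(d_nm: float, rise: float, screw: bool = False,
                         sign: int = -1) -> float:
    """Per-repeat twist producing cross-over distance ``d_nm`` at the given rise.

    Inverse of :func:`crossover_distance`.  ``screw=True`` adds the -180 deg
    screw component of a pseudo-2_1 repeat.  ``sign`` selects the sign of the
    folded twist (the cross-over is insensitive to it).  An infinite
    cross-over returns the untwisted value (0, or -180 for a pure screw).
    """
    if rise <= 0:
        raise InvalidParameterError(f"rise must be positive, got {rise}")
    if d_nm != math.inf and d_nm <= 0:
        raise InvalidParameterError(f"cross-over distance must be positive, got {d_nm}")
    if sign not in (-1, 1):
        raise InvalidParameterError("sign must be +1 or -1")
    fold = 0.0 if d_nm == math.inf else sign * rise * 180.0 / (10.0 * d_nm)
    return fold - 180.0 if screw else fold


@dataclass(frozen=True)
class ScrewOperator:
    """Rotation about the growth axis plus axial translation.

    ``angle_deg`` is kept unwrapped so composed operators report cumulative
    rotation (e.g. two pseudo-2_1 steps of -181.75 deg give -363.5 deg).
    """

    angle_deg: float
    rise: float  # angstroms along the axis
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def transform(self) -> RigidTransform:
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(np.radians(self.angle_deg) * u).as_matrix()
        return RigidTransform(rot, self.rise * u)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return self.transform.apply(xyz)

    def compose(self, other: "ScrewOperator") -> "ScrewOperator":
        if not np.allclose(self.axis, other.axis):
            raise InvalidParameterError("can only compose screw operators about a common axis")
        return ScrewOperator(self.angle_deg + other.angle_deg, self.rise + other.rise, self.axis)


def symmetry_operators(p: HelicalParams, n_layers: int) -> list[ScrewOperator]:
    """Rigid operators mapping a reference molecule onto every molecule of a segment.

    ``n_layers`` counts helical repeats along the growth axis.  For C2 each
    repeat contributes two molecules (the screw image and its 2-fold mate, a
    180 deg rotation with zero translation); for pseudo-2_1 each rise-repeat
    holds one molecule and the two subunits are the even/odd screw images, so
    a segment of ``n_layers`` layers per subunit contains ``2 * n_layers``
    operators.  Composition of returned operators is closed (same axis).
    """
    if n_layers < 1:
        raise InvalidParameterError(f"n_layers must be >= 1, got {n_layers}")
    sym = p.symmetry  # validated by HelicalParams
    ops: list[ScrewOperator] = []
    if sym == "pseudo-2_1":
        for k in range(2 * n_layers):
            ops.append(ScrewOperator(k * p.twist, k * p.rise))
    elif sym == "C2":
        for k in range(n_layers):
            ops.append(ScrewOperator(k * p.twist, k * p.rise))
            ops.append(ScrewOperator(k * p.twist + 180.0, k * p.rise))
    else:  # C1: one operator per repeat; inequivalent molecules share the screw
        for k in range(n_layers):
            ops.append(ScrewOperator(k * p.twist, k * p.rise))
    return ops


# ---------------------------------------------------------------------------
# Plain-text parameter tables

_TABLE_COLUMNS = ("name", "twist_deg", "rise_A", "symmetry", "handedness", "crossover_nm")


def read_params_table(path: str | Path) -> list[HelicalParams]:
    """Read polymorph parameter sets from a TSV or JSON table.

    TSV columns: ``name  twist_deg  rise_A  symmetry  handedness
    [crossover_nm]``.  JSON: a list of objects with the same keys.
    """
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        for ln in lines[1:]:
            rows.append(dict(zip(header, ln.split("\t"))))
    out = []
    for r in rows:
        xo = r.get("crossover_nm")
        out.append(
            HelicalParams(
                twist=float(r["twist_deg"]),
                rise=float(r["rise_A"]),
                symmetry=r.get("symmetry", "C1"),
                handedness=r.get("handedness", "undetermined") or "undetermined",
                crossover_nm=float(xo) if xo not in (None, "", "NA") else None,
                molecules_per_repeat=int(r.get("molecules_per_repeat", 1)),
                name=r.get("name", ""),
            )
        )
    return out


def write_params_table(params: Iterable[HelicalParams], path: str | Path) -> None:
    """Write polymorph parameters as TSV (or JSON if the path ends in .json)."""
    path = Path(path)
    params = list(params)
    if path.suffix.lower() == ".json":
        recs = [{"name": p.name, "twist_deg": p.twist, "rise_A": p.rise,
                 "symmetry": p.symmetry, "handedness": p.handedness,
                 "molecules_per_repeat": p.molecules_per_repeat,
                 "crossover_nm": p.crossover_nm} for p in params]
        path.write_text(json.dumps(recs, indent=1) + "\n")
        return
    lines = ["\t".join(_TABLE_COLUMNS)]
    for p in params:
        xo = "" if p.crossover_nm is None else f"{p.crossover_nm:g}"
        lines.append(
            f"{p.name}\t{p.twist:g}\t{p.rise:g}\t{p.symmetry}\t{p.handedness}\t{xo}"
        )
    path.write_text("\n".join(lines) + "\n")
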