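"""Rigid-body and dihedral geometry primitives.

Small numerical core used by the model-fitting, annotation, and synthesis
modules: least-squares rigid superposition (Kabsch, via
``scipy.spatial.transform.Rotation.align_vectors``), decomposition of a rigid
transform into a screw motion about an axis, and vectorized four-point
dihedral angles.

All coordinates are in angstroms, all angles in degrees unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError

__all__ = [
    "RigidTransform",
    "superpose",
    "screw_decompose",
    "signed_rotation_about",
    "dihedral",
    "circular_mean_deg",
    "circular_sd_deg",
    "circular_diff_deg",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal transform and the post-fit RMSD (angstroms).  Both
    inputs are ``(n, 3)`` arrays with matched rows; ``n >= 3`` is required for
    a well-posed rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InsufficientDataError("superpose requires matched (n, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise InsufficientDataError(f"superpose requires >= 3 matched atoms, got {n}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - ct, mobile - cm)
    rmsd = float(rssd) / np.sqrt(n)
    rmat = rot.as_matrix()
    return RigidTransform(rmat, ct - rmat @ cm), rmsd


def screw_decompose(t: RigidTransform) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Decompose a rigid transform into a screw motion.

    Returns ``(axis, angle_deg, axial_translation, point)`` where ``axis`` is
    a unit vector, ``angle_deg`` the rotation about it (right-hand rule, in
    (-180, 180]), ``axial_translation`` the displacement along the axis, and
    ``point`` a point on the screw axis (the one closest to the origin).

    For a (numerically) pure translation the axis is taken along the
    translation itself and the angle is 0.
    """
    rot = Rotation.from_matrix(t.rotation)
    rv = rot.as_rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        tr = np.asarray(t.translation, dtype=float)
        norm = np.linalg.norm(tr)
        axis = tr / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        return axis, 0.0, float(norm), np.zeros(3)
    axis = rv / angle
    h = float(axis @ t.translation)
    # Solve (I - R) p = t_perp for the axis point in the plane through origin.
    t_perp = t.translation - h * axis
    a = np.eye(3) - t.rotation
    point, *_ = np.linalg.lstsq(a, t_perp, rcond=None)
    point = point - (point @ axis) * axis
    return axis, float(np.degrees(angle)), h, point


def signed_rotation_about(t: RigidTransform, axis: np.ndarray) -> tuple[float, float]:
    """Rotation angle (deg) and axial translation of ``t`` measured about ``axis``.

    The sign follows the right-hand rule about the supplied axis, so results
    from different chain pairs of one fibril are directly comparable.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rv = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = np.linalg.norm(rv)
    if angle < 1e-12:
        return 0.0, float(axis @ t.translation)
    sign = 1.0 if rv @ axis >= 0 else -1.0
    return float(sign * np.degrees(angle)), float(axis @ t.translation)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in degrees for four points (vectorized).

    Accepts ``(3,)`` or ``(n, 3)`` arrays.  Returns NaN where the angle is
    undefined (collinear central atoms).
    """
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    m1 = np.cross(n1, b1 / np.where(b1n[:, None] > 0, b1n[:, None], 1.0))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(-y, x))  # IUPAC sign convention
    degenerate = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
    ang = np.where(degenerate, np.nan, ang)
    return ang if ang.size > 1 else float(ang[0])


def circular_mean_deg(angles: np.ndarray) -> float:
    """Circular mean of angles in degrees, NaNs ignored, result in (-180, 180]."""
    a = np.radians(np.asarray(angles, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    m = np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return float(m if m > -180.0 else 180.0)


def circular_sd_deg(angles: np.ndarray) -> float:
    """Circular standard deviation (degrees), NaNs ignored."""
    a = np.radians(np.asarray(angles, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    r = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def circular_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed circular difference a - b wrapped into (-180, 180]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = np.mod(d, 360.0)
    return np.where(d > 180.0, d - 360.0, d)
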