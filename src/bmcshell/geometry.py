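"""Low-level vector geometry shared by the lattice, trajectory and regraft layers.

All routines operate on plain ``numpy`` arrays in Cartesian Å and degrees and
are deliberately free of any atom-annotation logic.
"""

from __future__ import annotations

import numpy as np

#: Cross products with a norm below this are treated as degenerate (colinear points).
DEGENERACY_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when an angle or plane is requested from (nearly) colinear points."""


def signed_dihedral(p1, p2, p3, p4):
    """Signed dihedral angle of the ordered quadruple ``p1-p2-p3-p4`` in degrees.

    Uses the atan2 formulation, so the result lies in (-180, 180] and the sign
    follows the right-hand rule about the ``p2 -> p3`` axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < DEGENERACY_TOL or np.linalg.norm(n2) < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "dihedral undefined: consecutive points are (nearly) colinear"
        )
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return float(np.degrees(np.arctan2(y, x)))


def wrap_angle(angle_deg: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    a = (float(angle_deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def rotation_about_axis(axis, angle_deg, point=None):
    """Return ``(R, t)`` for a right-handed rotation about an axis line.

    ``axis`` is the direction vector, ``point`` a point on the line (origin if
    omitted).  The transform acts as ``x -> R @ x + t``.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < DEGENERACY_TOL:
        raise DegenerateGeometryError("rotation axis has zero length")
    u = axis / n
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    ux, uy, uz = u
    cross = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    rot = c * np.eye(3) + s * cross + (1.0 - c) * np.outer(u, u)
    if point is None:
        t = np.zeros(3)
    else:
        point = np.asarray(point, dtype=float)
        t = point - rot @ point
    return rot, t


def apply_transform(coords, rot, trans):
    """Apply ``x -> R @ x + t`` to an (n, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rot).T + np.asarray(trans)


def kabsch(mobile, target):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with the optimal proper rotation (det +1) and
    translation such that ``R @ m + t`` approximates ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch requires two equally shaped (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError("kabsch requires at least 3 atom pairs")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    if s[1] < DEGENERACY_TOL * max(s[0], 1.0):
        raise DegenerateGeometryError("kabsch selection is (nearly) colinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - rot @ cm
    moved = apply_transform(mobile, rot, t)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, t, rmsd


def fit_plane(points):
    """Best-fit plane through >= 3 points: returns ``(centroid, unit normal)``.

    For exactly three points this is the exact plane through them.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("a plane needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < DEGENERACY_TOL:
        raise DegenerateGeometryError("plane undefined: points are colinear")
    return centroid, vt[2]


def angle_between(v1, v2) -> float:
    """Unsigned angle between two vectors in degrees."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
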