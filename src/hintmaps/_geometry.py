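"""Small rigid-body geometry helpers shared across modules."""
from __future__ import annotations

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised when atoms are too close/collinear for a construction."""


def wrap_degrees(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle to (-180, 180]."""
    wrapped = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(angle) else wrapped


def wrap_degrees_positive(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle to [0, 360)."""
    wrapped = np.asarray(angle) % 360.0
    return float(wrapped) if np.isscalar(angle) else wrapped


def dihedral(p0, p1, p2, p3, collinear_tol: float = 1e-8) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the atan2 formulation, which is numerically stable away from the
    collinear degeneracy; collinear bond vectors raise.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    if np.linalg.norm(np.cross(b0, b1)) < collinear_tol or \
            np.linalg.norm(np.cross(b1, b2)) < collinear_tol:
        raise DegenerateGeometryError("undefined torsion: collinear atoms")
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    x = v @ w
    y = np.cross(b1u, v) @ w
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def kabsch(mobile: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of `mobile` onto `fixed`.

    Returns (R, t) such that mobile @ R.T + t approximates fixed.
    Proper rotation enforced (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    cm = mobile.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (mobile - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = cf - rot @ cm
    return rot, trans


def place_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position X bonded to c with |X-c|=bond,
    angle(X,c,b)=angle_deg and torsion(X,c,b,a)=torsion_deg."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise DegenerateGeometryError("collinear reference atoms for placement")
    n /= norm
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d2 = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d2


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (normalized internally) axis through the origin."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(a) * k + (1.0 - np.cos(a)) * (k @ k)
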