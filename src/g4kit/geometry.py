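"""Small geometric primitives shared by the analysis modules.

Everything operates on plain ``numpy`` arrays in Ångström; rotations are
3×3 proper orthonormal matrices.
"""

from __future__ import annotations

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised when an operation receives geometrically degenerate input."""


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize ``v``; raise on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    a, b = unit(a), unit(b)
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    cis (eclipsed) = 0°, trans = ±180°; sign by the right-hand rule about
    the p2→p3 axis. Returned on (−180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear points in torsion")
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane through ``points`` (n×3).

    Returns (centroid, unit normal). The normal sign is the SVD's choice;
    callers orient it as needed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a plane")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c)
    if s[1] < 1e-9:
        raise DegenerateGeometryError("collinear points, plane undefined")
    return c, vt[2]


def kabsch(mobile: np.ndarray, target: np.ndarray,
           allow_reflection: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t, rmsd) such that
    ``mobile @ R.T + t`` best fits ``target``. A proper rotation
    (det = +1) is enforced unless ``allow_reflection``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching n×3")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if allow_reflection:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    k = unit(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def signed_cycle_area(points: np.ndarray, view_axis: np.ndarray) -> float:
    """Signed area of the closed polygon ``points`` projected ⟂ ``view_axis``.

    Positive when the traversal runs counterclockwise as drawn in a
    right-handed frame whose third axis is ``view_axis`` (i.e. seen from the
    +view_axis side looking back against the axis).
    """
    v = unit(view_axis)
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    rel = pts - c
    total = 0.0
    n = len(pts)
    for i in range(n):
        total += np.dot(np.cross(rel[i], rel[(i + 1) % n]), v)
    area = 0.5 * total
    if abs(area) < 1e-9:
        raise DegenerateGeometryError("projected cycle is degenerate")
    return float(area)


def circular_mean_sd(angles_deg) -> tuple[float, float]:
    """Vector (circular) mean and circular standard deviation in degrees."""
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        raise ValueError("no angles")
    C, S = np.cos(a).mean(), np.sin(a).mean()
    R = min(np.hypot(C, S), 1.0)
    mean = np.degrees(np.arctan2(S, C))
    if R < 1e-12:
        return float(mean), 180.0
    sd = np.degrees(np.sqrt(max(-2.0 * np.log(R), 0.0)))
    return float(mean), float(sd)


def circular_distance(a_deg: float, b_deg: float) -> float:
    """Smallest absolute angular separation in degrees, in [0, 180]."""
    d = (a_deg - b_deg) % 360.0
    return float(min(d, 360.0 - d))


def place_atom(p1, p2, p3, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth point from three reference points and internal coordinates.

    ``bond`` = |p4−p3|, ``angle_deg`` = p2-p3-p4 angle, ``torsion_deg`` =
    p1-p2-p3-p4 torsion (NeRF construction). Used to build small backbone
    fragments with prescribed torsions.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    b1 = unit(p2 - p1)
    b2 = unit(p3 - p2)
    n = unit(np.cross(b1, b2))
    m = np.cross(n, b2)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d = -bond * np.cos(ang) * b2 \
        + bond * np.sin(ang) * np.cos(tor) * m \
        - bond * np.sin(ang) * np.sin(tor) * n
    return p3 + d
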