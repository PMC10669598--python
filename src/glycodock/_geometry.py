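"""Low-level vector geometry shared by the chain builder and the docking engine.

All coordinates are in Å, all angles in degrees unless a name says otherwise.
The dihedral sign convention is the standard IUPAC one (right-handed, looking
from atom 2 to atom 3), wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np

TETRAHEDRAL = 109.4712206344907  # arccos(-1/3)


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral or frame is requested on (near-)colinear points."""


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def angular_difference(a, b):
    """Signed circular difference a - b, wrapped to (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral(p1, p2, p3, p4, *, eps: float = 1e-10) -> float:
    """Signed dihedral angle of plane(p1,p2,p3) vs plane(p2,p3,p4), degrees.

    Raises DegenerateGeometryError if either atom triple is colinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < eps or np.linalg.norm(n1) < eps or np.linalg.norm(n2) < eps:
        raise DegenerateGeometryError("colinear or coincident points in dihedral")
    m1 = np.cross(n1, b2 / b2n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # negated so the sign follows the standard right-handed (IUPAC) convention
    return wrap_angle(-np.degrees(np.arctan2(y, x)))


def nerf_place(a, b, c, bond_length: float, bond_angle: float, torsion: float):
    """Place atom D so that |DC| = bond_length, angle(D,C,B) = bond_angle and
    dihedral(D, C, B, A) = torsion (degrees).  Natural extension reference frame.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)  # sign chosen so dihedral(D,C,B,A) == torsion
    b1 = b - a
    b2 = c - b
    u2 = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("colinear reference frame in nerf_place")
    n = n / nn
    m = np.cross(n, u2)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(chi),
            bond_length * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * u2 + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis_point, axis_dir, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (R, t) so that x -> R @ x + t rotates about the given axis (Rodrigues)."""
    p = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    th = np.radians(angle_deg)
    K = np.array([[0.0, -d[2], d[1]], [d[2], 0.0, -d[0]], [-d[1], d[0], 0.0]])
    R = np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
    t = p - R @ p
    return R, t


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping `moving` onto `target`.

    Proper rotation only (reflections rejected via the sign of det).
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def quaternion_to_matrix(q) -> np.ndarray:
    """Rotation matrix from a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(q, dtype=float)
    n = np.sqrt(w * w + x * x + y * y + z * z)
    w, x, y, z = w / n, x / n, y / n, z / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_multiply(q1, q2) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def axis_angle_quaternion(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = np.radians(angle_deg) / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def circular_mean_deg(angles) -> float:
    """Circular mean of angles in degrees, result wrapped to (-180, 180]."""
    a = np.radians(np.asarray(angles, dtype=float))
    s = np.sin(a).mean()
    c = np.cos(a).mean()
    return wrap_angle(np.degrees(np.arctan2(s, c)))


def circular_std_deg(angles) -> float:
    """Circular standard deviation in degrees (sqrt(-2 ln R) convention)."""
    a = np.radians(np.asarray(angles, dtype=float))
    R = np.hypot(np.sin(a).mean(), np.cos(a).mean())
    R = min(max(R, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(R))))
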