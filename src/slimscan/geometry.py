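"""Small 3-D geometry helpers shared across modules.

Internal-to-Cartesian placement follows the natural extension reference
frame (NeRF) construction: a new atom D is positioned from three
reference atoms A–B–C given the C–D bond length, the B–C–D bond angle
and the A–B–C–D torsion.
"""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """NeRF placement of atom D bonded to C.

    ``bond_angle_deg`` is the B–C–D angle, ``torsion_deg`` the A–B–C–D
    dihedral, both in degrees.
    """
    theta = np.deg2rad(bond_angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = _unit(np.asarray(c, float) - np.asarray(b, float))
    n = _unit(np.cross(np.asarray(b, float) - np.asarray(a, float), bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return np.asarray(c, float) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation about ``axis`` through ``angle_deg`` (Rodrigues)."""
    axis = _unit(np.asarray(axis, float))
    t = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
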