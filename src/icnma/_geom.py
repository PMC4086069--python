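"""Small geometric primitives shared across modules.

All coordinates are in Angstrom, all angles in radians unless a function
name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "rotation_about_axis",
    "kabsch",
    "rotation_angle",
]


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in (-pi, pi] (IUPAC sign convention)."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.arctan2(y, x))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, theta: float, chi: float
) -> np.ndarray:
    """Place atom D from reference atoms A, B, C (NeRF construction).

    D is at distance ``bond`` from C, with bond angle B-C-D ``theta`` and
    torsion A-B-C-D ``chi``.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), -np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a (unit) axis."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    ux, uy, uz = u
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cross = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * cross + (1.0 - c) * np.outer(u, u)


def kabsch(
    mobile: np.ndarray, ref: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid superposition (proper rotation enforced).

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits ``ref``;
    rmsd is the (weighted) root-mean-square residual after the fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("superposition weights sum to zero")
    mc = (w[:, None] * mobile).sum(axis=0) / wsum
    rc = (w[:, None] * ref).sum(axis=0) / wsum
    P = mobile - mc
    Q = ref - rc
    C = (w[:, None] * P).T @ Q
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    resid = P @ R.T + (R @ mc + t) - (Q + rc)
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum() / wsum))
    return R, t, rmsd


def rotation_angle(R: np.ndarray) -> float:
    """Magnitude of the rotation encoded in a rotation matrix, in radians."""
    return float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
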