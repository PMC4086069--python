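"""Mode-derived profiles and matrices.

All quantities use classical equipartition weighting: each mode contributes
in proportion to 1/lambda (softer modes fluctuate more), with kT absorbed
into the arbitrary stiffness unit.

* mobility (NMA B-factors): per-atom mean-square fluctuation, scaled by
  8 pi^2 / 3 to crystallographic B-factor convention, optionally rescaled
  to the experimental mean for comparison;
* deformability: per-atom local non-rigidity of the summed displacement
  field -- for every atom the best infinitesimal rigid motion of its
  neighbourhood is fitted per mode and the residual at the atom, weighted
  1/lambda and summed over modes, is reported (normalised to max 1).
  Rigid regions score ~0, hinges and linkers score high;
* covariance map: normalised cross-correlation of site displacements in
  [-1, 1];
* variance fractions: the relative importance (1/lambda share) of each mode.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .nma_core import ModeSet
from .structure_io import Structure

__all__ = [
    "variance_fractions",
    "cumulative_variance",
    "bfactors",
    "deformability",
    "covariance_map",
]


def variance_fractions(eigenvalues: np.ndarray) -> np.ndarray:
    """Per-mode share of the total 1/lambda fluctuation variance."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("variance fractions require strictly positive eigenvalues")
    inv = 1.0 / lam
    return inv / inv.sum()


def cumulative_variance(eigenvalues: np.ndarray) -> np.ndarray:
    return np.cumsum(variance_fractions(eigenvalues))


def _mode_fields(modes: ModeSet, n_atoms: int) -> np.ndarray:
    if modes.cartesian_vectors is None:
        raise ValueError("mode set lacks Cartesian vectors")
    return modes.cartesian_vectors.reshape(n_atoms, 3, -1)


def bfactors(
    modes: ModeSet,
    s: Structure,
    experimental: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted B-factors, B_i = (8 pi^2 / 3) sum_k |u_ik|^2 / lambda_k.

    If experimental values are given, the profile is linearly rescaled so
    its mean matches the experimental mean (ignoring non-positive entries);
    otherwise values are in arbitrary units.
    """
    U = _mode_fields(modes, s.n_atoms)  # N x 3 x m
    lam = modes.eigenvalues
    pos = lam > 0
    msf = np.einsum("iak,iak,k->i", U[:, :, pos], U[:, :, pos], 1.0 / lam[pos])
    B = (8.0 * np.pi**2 / 3.0) * msf
    if experimental is not None:
        exp = np.asarray(experimental, dtype=float)
        good = exp > 0
        if good.any() and B.mean() > 0:
            B = B * (exp[good].mean() / B.mean())
    return B


def _rigid_fit_residual(coords: np.ndarray, disp: np.ndarray, center: int) -> float:
    """Residual at ``center`` after the best infinitesimal rigid fit
    u ~ omega x (r - rbar) + t over the neighbourhood."""
    rbar = coords.mean(axis=0)
    d = coords - rbar
    n = len(coords)
    # design matrix for (omega, t): u_i = omega x d_i + t
    A = np.zeros((3 * n, 6))
    for i in range(n):
        dx, dy, dz = d[i]
        A[3 * i:3 * i + 3, :3] = np.array(
            [[0.0, dz, -dy], [-dz, 0.0, dx], [dy, -dx, 0.0]]
        )
        A[3 * i:3 * i + 3, 3:] = np.eye(3)
    sol, *_ = np.linalg.lstsq(A, disp.ravel(), rcond=None)
    pred = (A @ sol).reshape(n, 3)
    return float(np.linalg.norm(disp[center] - pred[center]))


def deformability(
    modes: ModeSet, s: Structure, shell_radius: float = 8.0
) -> np.ndarray:
    """Per-atom deformability of the 1/lambda-weighted modal field.

    The neighbourhood shell is broadened until it holds at least 4 atoms.
    The profile is normalised to a maximum of 1 (all-rigid fields return 0).
    """
    U = _mode_fields(modes, s.n_atoms)
    lam = modes.eigenvalues
    tree = cKDTree(s.coords)
    out = np.zeros(s.n_atoms)
    for i in range(s.n_atoms):
        r = shell_radius
        nbr = tree.query_ball_point(s.coords[i], r)
        while len(nbr) < 4:
            r *= 1.5
            nbr = tree.query_ball_point(s.coords[i], r)
        nbr = np.array(sorted(nbr))
        center = int(np.nonzero(nbr == i)[0][0])
        total = 0.0
        for k in range(modes.n_modes):
            if lam[k] <= 0:
                continue
            resid = _rigid_fit_residual(s.coords[nbr], U[nbr, :, k], center)
            total += resid**2 / lam[k]
        out[i] = total
    peak = out.max()
    # a numerically rigid field must stay ~0: only normalise when the peak
    # residual is meaningful relative to the field's own fluctuation scale
    scale = sum(
        float(np.mean(np.einsum("ia,ia->i", U[:, :, k], U[:, :, k]))) / lam[k]
        for k in range(modes.n_modes) if lam[k] > 0
    )
    if peak > 1e-16 * max(scale, 1e-300):
        return out / peak
    return out


def covariance_map(modes: ModeSet, n_atoms: int, normalized: bool = True) -> np.ndarray:
    """Site-site covariance C_ij = sum_k (u_ik . u_jk) / lambda_k.

    Normalised to cross-correlation (diagonal exactly 1); sites with zero
    total fluctuation get zero rows with a warning.
    """
    U = _mode_fields(modes, n_atoms)
    lam = modes.eigenvalues
    pos = lam > 0
    C = np.einsum("iak,jak,k->ij", U[:, :, pos], U[:, :, pos], 1.0 / lam[pos])
    if not normalized:
        return C
    diag = np.diag(C).copy()
    dead = diag <= 1e-30
    if dead.any():
        warnings.warn(f"{int(dead.sum())} sites have zero fluctuation; correlation set to 0")
        diag[dead] = 1.0
    scale = 1.0 / np.sqrt(diag)
    R = C * scale[:, None] * scale[None, :]
    R[dead, :] = 0.0
    R[:, dead] = 0.0
    np.fill_diagonal(R, np.where(dead, 0.0, 1.0))
    return np.clip(R, -1.0, 1.0)
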