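"""Generalized eigenproblem H x = lambda T x and mode animation.

Eigenvectors are normalised in the kinetic metric (X^T T X = I) and sorted
by ascending eigenvalue; the associated frequency is sqrt(lambda)/(2 pi)
in the model's arbitrary time unit.  Ties and the overall sign are fixed by
a lexicographic convention (first component above tolerance made positive)
so results are reproducible across solvers and platforms.

Animations displace the structure along one mode as

    q(t) = q0 + a x_k cos(2 pi t / P + delta)

with the amplitude ``a`` calibrated by root finding so the peak frame's
trace-atom RMSD from the input equals the requested excursion.  Every frame
is rebuilt with exact torsion rotations, so covalent geometry is preserved
to machine precision -- the defining advantage of dihedral-space modes over
Cartesian ones, whose straight-line excursions distort bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .internal_coords import TorsionalSystem, rebuild_cartesian
from .structure_io import Structure

__all__ = [
    "ModeSet",
    "AnimationSettings",
    "solve_dense",
    "solve_lowest_krylov",
    "solve_modes",
    "animate_mode",
    "write_nmd",
    "write_ic_modes",
]


class SolverError(Exception):
    pass


@dataclass
class ModeSet:
    eigenvalues: np.ndarray  # ascending
    ic_vectors: np.ndarray  # n x m, T-orthonormal columns
    cartesian_vectors: np.ndarray | None = None  # 3N x m (J @ x_k)
    n_modes_requested: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None)) / (2.0 * np.pi)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class AnimationSettings:
    amplitude: float = 2.0  # peak trace-atom RMSD of the excursion (Angstrom)
    n_frames: int = 16
    phase: float = 0.0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")


def _canonical_signs(X: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    X = X.copy()
    for k in range(X.shape[1]):
        nz = np.nonzero(np.abs(X[:, k]) > tol * max(np.abs(X[:, k]).max(), 1e-300))[0]
        if len(nz) and X[nz[0], k] < 0:
            X[:, k] = -X[:, k]
    return X


def _check_pencil(H, T):
    if H.shape != T.shape or H.shape[0] != H.shape[1]:
        raise ValueError("H and T must be square matrices of equal size")


def solve_dense(H: np.ndarray, T: np.ndarray, m: int | None = None) -> ModeSet:
    """Lowest ``m`` pairs of H x = lambda T x by dense reduction (LAPACK).

    T must be positive definite; returned vectors satisfy X^T T X = I.
    """
    _check_pencil(H, T)
    n = H.shape[0]
    m = n if m is None else min(m, n)
    try:
        w, X = sla.eigh(H, T, subset_by_index=[0, m - 1])
    except sla.LinAlgError as exc:
        raise SolverError(f"kinetic matrix not positive definite: {exc}") from exc
    X = _canonical_signs(X)
    return ModeSet(eigenvalues=w, ic_vectors=X, n_modes_requested=m)


def solve_lowest_krylov(H, T, m: int, maxiter: int | None = None) -> ModeSet:
    """Lowest ``m`` pairs by shift-invert Lanczos iteration (sigma = 0).

    Same contract as :func:`solve_dense`; intended for large systems where
    only the low-frequency end of the spectrum is needed.  A tiny PD
    regularisation (H + eps T) tolerates numerically semidefinite H.
    """
    _check_pencil(H, T)
    n = H.shape[0]
    if m >= n:
        return solve_dense(H, T, n)
    eps = 1e-10 * (np.trace(H) if not sp.issparse(H) else H.diagonal().sum()) / n
    Hs = sp.csc_matrix(H) if not sp.issparse(H) else H.tocsc()
    Ts = sp.csc_matrix(T) if not sp.issparse(T) else T.tocsc()
    Hreg = Hs + eps * Ts
    try:
        w, X = spla.eigsh(Hreg, k=m, M=Ts, sigma=0.0, which="LM", maxiter=maxiter)
    except spla.ArpackNoConvergence as exc:
        raise SolverError(
            f"shift-invert iteration failed to converge "
            f"({len(exc.eigenvalues)}/{m} pairs after max iterations)"
        ) from exc
    order = np.argsort(w)
    w = w[order] - eps
    X = X[:, order]
    # re-enforce T-orthonormality within degenerate clusters
    G = X.T @ (Ts @ X)
    L = np.linalg.cholesky(G)
    X = X @ np.linalg.inv(L).T
    X = _canonical_signs(X)
    return ModeSet(eigenvalues=w, ic_vectors=X, n_modes_requested=m)


def solve_modes(system: TorsionalSystem, m: int = 50, method: str = "auto") -> ModeSet:
    """Solve a torsional system and attach Cartesian mode vectors J x_k."""
    n = system.n
    m = min(m, n)
    if method == "auto":
        method = "krylov" if n > 1000 and m < n // 2 else "dense"
    if method == "dense":
        modes = solve_dense(system.hessian, system.kinetic, m)
    elif method == "krylov":
        modes = solve_lowest_krylov(system.hessian, system.kinetic, m)
    else:
        raise ValueError(f"unknown solver method {method!r}")
    modes.cartesian_vectors = system.jacobian @ modes.ic_vectors
    modes.n_modes_requested = m
    return modes


def _trace_rmsd(a: Structure, b: Structure, trace: np.ndarray) -> float:
    d = a.coords[trace] - b.coords[trace]
    return float(np.sqrt(np.einsum("ij,ij->i", d, d).mean()))


def animate_mode(
    s: Structure,
    dofs,
    modes: ModeSet,
    k: int,
    settings: AnimationSettings | None = None,
) -> list[Structure]:
    """Frames of one period of mode ``k`` at the requested peak excursion.

    The amplitude is calibrated so that the peak frame's trace-atom (CA/P)
    RMSD from ``s`` equals ``settings.amplitude``; with the default phase 0
    the first frame is the peak displacement.
    """
    from scipy.optimize import brentq

    settings = settings or AnimationSettings()
    if not 0 <= k < modes.n_modes:
        raise IndexError(f"mode index {k} out of range (have {modes.n_modes})")
    x = modes.ic_vectors[:, k]
    trace = s.calpha_indices()
    if len(trace) == 0:
        trace = np.arange(s.n_atoms)

    def peak_rmsd(a: float) -> float:
        # the rebuild is nonlinear, so the +a and -a excursions differ; the
        # animation's peak frame is whichever is larger
        return max(
            _trace_rmsd(rebuild_cartesian(s, dofs, a * x), s, trace),
            _trace_rmsd(rebuild_cartesian(s, dofs, -a * x), s, trace),
        )

    target = settings.amplitude
    a_hi = target / max(np.max(np.abs(modes.cartesian_vectors[:, k]))
                        if modes.cartesian_vectors is not None else 1.0, 1e-12)
    a_hi = max(a_hi, 1e-6)
    for _ in range(60):
        if peak_rmsd(a_hi) >= target:
            break
        a_hi *= 2.0
    else:
        raise ValueError("could not bracket the requested animation amplitude")
    a = brentq(lambda t: peak_rmsd(t) - target, 0.0, a_hi, xtol=1e-10)

    frames = []
    for f in range(settings.n_frames):
        phase = 2.0 * np.pi * f / settings.n_frames + settings.phase
        frames.append(rebuild_cartesian(s, dofs, a * np.cos(phase) * x))
    return frames


# ----------------------------------------------------------------------
# Mode export


def write_ic_modes(modes: ModeSet, dofs, path) -> None:
    """Plain-text internal-coordinate eigenvector table."""
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.8g}" for v in modes.eigenvalues) + "\n")
        fh.write("# dof\t" + "\t".join(f"mode{k+1}" for k in range(modes.n_modes)) + "\n")
        for i, d in enumerate(dofs):
            row = "\t".join(f"{modes.ic_vectors[i, k]:.8g}" for k in range(modes.n_modes))
            fh.write(f"{d.label}\t{row}\n")


def write_nmd(s: Structure, modes: ModeSet, path, title: str = "icnma") -> None:
    """NMWiz-compatible NMD file with Cartesian mode vectors."""
    if modes.cartesian_vectors is None:
        raise ValueError("mode set lacks Cartesian vectors")
    with open(path, "w") as fh:
        fh.write(f"title {title}\n")
        fh.write("names " + " ".join(str(n) for n in s.names) + "\n")
        fh.write("resnames " + " ".join(str(r) for r in s.res_names) + "\n")
        fh.write("chainids " + " ".join(str(c) for c in s.chain_ids) + "\n")
        fh.write("resids " + " ".join(str(r) for r in s.res_numbers) + "\n")
        fh.write("coordinates " + " ".join(f"{v:.3f}" for v in s.coords.ravel()) + "\n")
        for k in range(modes.n_modes):
            vec = modes.cartesian_vectors[:, k]
            lam = modes.eigenvalues[k]
            scale = 1.0 / np.sqrt(lam) if lam > 0 else 1.0
            fh.write(
                f"mode {k + 1} {scale:.6g} "
                + " ".join(f"{v:.6g}" for v in vec) + "\n"
            )
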