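"""Mode-space morphing between two (possibly homologous) conformations.

The source structure is deformed iteratively along its lowest-frequency
torsional modes so that the trace-atom (CA / P) RMSD to the target, over
sequence-matched residues only, decreases monotonically:

1. superpose the target onto the current frame (global Kabsch fit or the
   iteratively reweighted local fit that favours the best-matching region);
2. every ``mode_refresh_every`` accepted steps, rebuild the elastic network
   and re-solve the lowest modes of the *current* frame;
3. project the matched-atom difference vector onto the modes in the
   mass metric, a_k = x_k^T J^T M~ dr (M~ carries the matched-atom masses),
   which is the steepest-descent direction of the mass-weighted residual in
   mode space;
4. scale the internal-coordinate step to a fixed per-iteration trace RMSD
   and rebuild with exact torsion rotations, so every trajectory frame has
   the source's exact covalent geometry;
5. accept if the matched RMSD decreased, otherwise halve the step.

Unmatched residues (insertions) ride along with their chain and contribute
no RMSD signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elastic_network as enm
from . import internal_coords as ic
from ._geom import kabsch
from .nma_core import solve_modes
from .structure_io import (
    ResidueMatch,
    Structure,
    match_residues,
    matched_calpha_indices,
)

__all__ = [
    "MorphSettings",
    "MorphTrajectory",
    "superpose_global",
    "superpose_local",
    "morph",
]


@dataclass
class MorphSettings:
    n_modes_used: int = 20
    step_rmsd: float = 0.5
    superposition: str = "global"  # or "local"
    local_weight_scale: float = 5.0
    mode_refresh_every: int = 5
    rmsd_tol: float = 0.5
    max_iter: int = 2000
    potential: str = "inverse_exponential"
    potential_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.superposition not in ("global", "local"):
            raise ValueError("superposition must be 'global' or 'local'")
        for name in ("n_modes_used", "step_rmsd", "local_weight_scale",
                     "mode_refresh_every", "rmsd_tol", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MorphTrajectory:
    frames: list[Structure]
    rmsd_profile: list[float]
    converged: bool
    iterations: int
    match: ResidueMatch | None = None


def superpose_global(
    mobile: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition over matched coordinates."""
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if len(mobile) < 3:
        raise ValueError("need at least 3 matched pairs for superposition")
    return kabsch(mobile, ref)


def superpose_local(
    mobile: np.ndarray,
    ref: np.ndarray,
    weight_scale: float = 5.0,
    max_rounds: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Iteratively reweighted superposition favouring the best-matching
    region: w_i = exp(-d_i^2 / weight_scale^2) from the current per-pair
    deviations, iterated to a fixed point.

    Returns ``(R, t, weighted_rmsd, weights)``.
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if len(mobile) < 3:
        raise ValueError("need at least 3 matched pairs for superposition")
    w = np.ones(len(mobile))
    R, t, rmsd = kabsch(mobile, ref, w)
    for _ in range(max_rounds):
        d = np.linalg.norm(mobile @ R.T + t - ref, axis=1)
        w_new = np.exp(-(d / weight_scale) ** 2)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
        R, t, rmsd = kabsch(mobile, ref, w)
    return R, t, rmsd, w


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.einsum("ij,ij->i", d, d).mean()))


def _superpose_target(
    frame_ca: np.ndarray, target_ca: np.ndarray, settings: MorphSettings
) -> np.ndarray:
    """Target trace coordinates rigidly placed onto the current frame."""
    if settings.superposition == "global":
        R, t, _ = superpose_global(target_ca, frame_ca)
    else:
        R, t, _, _ = superpose_local(target_ca, frame_ca, settings.local_weight_scale)
    return target_ca @ R.T + t


def morph(
    source: Structure,
    target: Structure,
    settings: MorphSettings | None = None,
    match: ResidueMatch | None = None,
) -> MorphTrajectory:
    """Feasible transition trajectory from ``source`` toward ``target``.

    The reported RMSD is trace-atom (CA / P) only, over matched residue
    pairs; the trajectory records the source plus every accepted frame.
    """
    settings = settings or MorphSettings()
    if match is None:
        match = match_residues(source, target)
    ia, ib = matched_calpha_indices(source, target, match)
    if len(ia) < 3:
        raise ValueError("fewer than 3 matched trace atoms")
    w_atoms = source.masses[ia]

    current = source.copy()
    dofs = None
    modes = None
    X = None
    frames = [source.copy()]

    def matched_rmsd(frame: Structure) -> float:
        placed = _superpose_target(frame.coords[ia], target.coords[ib], settings)
        return _plain_rmsd(frame.coords[ia], placed)

    rmsd0 = matched_rmsd(current)
    rmsd_profile = [rmsd0]
    if rmsd0 <= settings.rmsd_tol:
        return MorphTrajectory([source.copy()], rmsd_profile, True, 0, match)

    step = settings.step_rmsd
    converged = False
    it = 0
    halvings = 0
    while it < settings.max_iter:
        if modes is None or it % settings.mode_refresh_every == 0:
            net = enm.build_network(current, settings.potential,
                                    dict(settings.potential_params))
            dofs = ic.define_dofs(current)
            system = ic.assemble(current, net, dofs)
            modes = solve_modes(system, m=settings.n_modes_used)
            X = modes.ic_vectors
            J = system.jacobian

        placed = _superpose_target(current.coords[ia], target.coords[ib], settings)
        dr = placed - current.coords[ia]
        # steepest-descent amplitudes in mode space under the mass metric
        Jsel = J.reshape(-1, 3, J.shape[1])[ia]  # matched trace rows
        g = np.einsum("iak,ia,i->k", Jsel, dr, w_atoms)
        amps = X.T @ g
        dq_dir = X @ amps
        # predicted per-step trace displacement for unit dq
        pred = np.einsum("iak,k->ia", Jsel, dq_dir)
        pred_rms = np.sqrt(np.einsum("ia,ia->i", pred, pred).mean())
        if pred_rms < 1e-12:
            break
        accepted = False
        while halvings < 10:
            dq = dq_dir * (step / pred_rms)
            trial = ic.rebuild_cartesian(current, dofs, dq)
            r = matched_rmsd(trial)
            if r < rmsd_profile[-1] - 1e-12:
                current = trial
                frames.append(trial)
                rmsd_profile.append(r)
                accepted = True
                halvings = 0
                step = min(settings.step_rmsd, step * 2.0)
                break
            step *= 0.5
            halvings += 1
            if step < 1e-6:
                break
        it += 1
        if not accepted:
            break
        if rmsd_profile[-1] <= settings.rmsd_tol:
            converged = True
            break

    return MorphTrajectory(frames, rmsd_profile, converged, it, match)


def write_rmsd_log(traj: MorphTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\trmsd\n")
        for k, r in enumerate(traj.rmsd_profile):
            fh.write(f"{k}\t{r:.6f}\n")
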