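"""Dynamic-domain decomposition of a mode's displacement field.

Atoms whose modal displacements are explained by one affine map
u(r) ~ A r + t move together as a (near-)rigid body.  Seed clusters of
contiguous residues are merged agglomeratively, always choosing the pair
whose joint affine fit increases the mass-weighted total squared residual
the least (Ward-style cost on affine fits), until the requested number of
domains remains.  The antisymmetric part of each domain's affine matrix
defines an instantaneous screw motion (rotation axis, angle and axial
translation) that summarises the domain's trajectory as a single arrow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Structure

__all__ = [
    "AffineModel",
    "DomainPartition",
    "ArrowDescriptor",
    "fit_affine",
    "cluster_mode",
    "arrow_from_affine",
    "arrows_for_partition",
]


@dataclass
class AffineModel:
    A: np.ndarray  # 3x3
    t: np.ndarray  # 3
    fit_error: float  # RMS residual (Angstrom) over member atoms
    degenerate: bool = False

    def predict(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.A.T + self.t


@dataclass
class DomainPartition:
    labels: np.ndarray  # per-atom domain id, 0..n_domains-1
    models: list[AffineModel]
    n_domains: int
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class ArrowDescriptor:
    kind: str  # "screw" or "translation"
    axis_point: np.ndarray
    axis_direction: np.ndarray
    rotation_angle: float  # radians (instantaneous, per unit mode amplitude)
    translation_along_axis: float
    domain_id: int = 0


def fit_affine(
    coords: np.ndarray, displacements: np.ndarray, weights: np.ndarray | None = None
) -> AffineModel:
    """Weighted least-squares affine fit u_i ~ A r_i + t.

    Degenerate (coplanar/collinear) member sets are solved with a
    pseudo-inverse and flagged.
    """
    coords = np.asarray(coords, float)
    disp = np.asarray(displacements, float)
    n = len(coords)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    D = np.hstack([coords, np.ones((n, 1))])  # n x 4
    Dw = D * sw[:, None]
    Uw = disp * sw[:, None]
    # rank check for a unique fit (needs 4 affinely independent points)
    degenerate = n < 4 or np.linalg.matrix_rank(D, tol=1e-8) < 4
    sol, *_ = np.linalg.lstsq(Dw, Uw, rcond=None)
    A = sol[:3].T
    t = sol[3]
    resid = disp - (coords @ A.T + t)
    rms = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum() / w.sum()))
    return AffineModel(A=A, t=t, fit_error=rms, degenerate=degenerate)


def _sse(coords, disp, weights) -> tuple[float, AffineModel]:
    model = fit_affine(coords, disp, weights)
    resid = disp - model.predict(coords)
    return float((weights * np.einsum("ij,ij->i", resid, resid)).sum()), model


def cluster_mode(
    s: Structure,
    field_: np.ndarray,
    n_clusters: int,
    seed_window: int = 4,
) -> DomainPartition:
    """Agglomerative affine clustering of a per-atom displacement field.

    Seeds are contiguous ``seed_window``-residue windows per chain; merges
    minimise the increase in mass-weighted total squared residual.  The
    result is deterministic for a given field.
    """
    field_ = np.asarray(field_, float).reshape(-1, 3)
    if field_.shape[0] != s.n_atoms:
        raise ValueError("displacement field length does not match atom count")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")

    # contiguous residue-window seeds, chain by chain
    ridx = s.residue_index()
    seeds: list[np.ndarray] = []
    for chain in s.chain_order():
        res_ids = sorted(set(ridx[s.chain_atom_indices(chain)]))
        for w0 in range(0, len(res_ids), seed_window):
            window = res_ids[w0:w0 + seed_window]
            atoms = np.nonzero(np.isin(ridx, window)
                               & (s.chain_ids == chain))[0]
            if len(atoms):
                seeds.append(atoms)
    if n_clusters > len(seeds):
        raise ValueError(
            f"requested {n_clusters} clusters but only {len(seeds)} seeds"
        )

    members = [list(a) for a in seeds]
    cost = {}
    models = {}
    for c in range(len(members)):
        atoms = np.array(members[c])
        cost[c], models[c] = _sse(s.coords[atoms], field_[atoms], s.masses[atoms])

    def merged_cost(c1, c2):
        atoms = np.array(members[c1] + members[c2])
        return _sse(s.coords[atoms], field_[atoms], s.masses[atoms])

    # adjacency is unrestricted: any pair may merge (domains need not be
    # contiguous in sequence)
    active = set(range(len(members)))
    pair_cache: dict[tuple[int, int], tuple[float, AffineModel]] = {}
    history = []
    while len(active) > n_clusters:
        best = None
        for c1 in sorted(active):
            for c2 in sorted(active):
                if c2 <= c1:
                    continue
                key = (c1, c2)
                if key not in pair_cache:
                    pair_cache[key] = merged_cost(c1, c2)
                sse_new, model = pair_cache[key]
                delta = sse_new - cost[c1] - cost[c2]
                if best is None or delta < best[0] - 1e-15:
                    best = (delta, c1, c2, sse_new, model)
        delta, c1, c2, sse_new, model = best
        members[c1] = members[c1] + members[c2]
        members[c2] = []
        cost[c1] = sse_new
        models[c1] = model
        active.discard(c2)
        pair_cache = {k: v for k, v in pair_cache.items()
                      if c1 not in k and c2 not in k}
        history.append((c1, c2, float(delta)))

    order = sorted(active, key=lambda c: min(members[c]))
    labels = np.full(s.n_atoms, -1, dtype=int)
    out_models = []
    for new_id, c in enumerate(order):
        atoms = np.array(members[c])
        labels[atoms] = new_id
        out_models.append(models[c])
    assert np.all(labels >= 0)
    return DomainPartition(
        labels=labels, models=out_models, n_domains=len(order),
        merge_history=history,
    )


def arrow_from_affine(
    model: AffineModel, centroid: np.ndarray, domain_id: int = 0
) -> ArrowDescriptor:
    """Screw decomposition of a domain's affine motion.

    The rotation vector omega comes from the antisymmetric part of A; the
    screw axis passes through the point of minimal displacement magnitude,
    and the translation component along the axis is omega-parallel.  A
    near-zero rotation yields a pure-translation arrow.
    """
    A = model.A
    omega = 0.5 * np.array([A[2, 1] - A[1, 2], A[0, 2] - A[2, 0], A[1, 0] - A[0, 1]])
    u_centroid = model.predict(centroid[None, :])[0]
    wnorm = float(np.linalg.norm(omega))
    if wnorm < 1e-9:
        tnorm = np.linalg.norm(model.t)
        direction = model.t / tnorm if tnorm > 0 else np.array([1.0, 0.0, 0.0])
        return ArrowDescriptor(
            kind="translation", axis_point=centroid.astype(float),
            axis_direction=direction, rotation_angle=0.0,
            translation_along_axis=float(np.dot(u_centroid, direction)),
            domain_id=domain_id,
        )
    e = omega / wnorm
    # rigid interpretation u(r) = omega x (r - p) + h e ; displacement at the
    # centroid fixes the effective translation
    t_eff = u_centroid - np.cross(omega, centroid)
    # point on the axis nearest the origin: p = (omega x t_eff) / |omega|^2
    p = np.cross(omega, t_eff) / wnorm**2
    h = float(np.dot(e, t_eff))
    return ArrowDescriptor(
        kind="screw", axis_point=p, axis_direction=e,
        rotation_angle=wnorm, translation_along_axis=h, domain_id=domain_id,
    )


def arrows_for_partition(
    s: Structure, partition: DomainPartition
) -> list[ArrowDescriptor]:
    out = []
    for dom in range(partition.n_domains):
        atoms = np.nonzero(partition.labels == dom)[0]
        m = s.masses[atoms]
        centroid = (m[:, None] * s.coords[atoms]).sum(axis=0) / m.sum()
        out.append(arrow_from_affine(partition.models[dom], centroid, dom))
    return out


# ----------------------------------------------------------------------
# Export


def write_partition(s: Structure, partition: DomainPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresnum\tdomain_id\n")
        seen = set()
        for i in range(s.n_atoms):
            key = (s.chain_ids[i], int(s.res_numbers[i]))
            if key in seen:
                continue
            seen.add(key)
            fh.write(f"{key[0]}\t{key[1]}\t{int(partition.labels[i])}\n")


def write_arrows(arrows: list[ArrowDescriptor], path) -> None:
    records = [
        {
            "domain_id": a.domain_id,
            "kind": a.kind,
            "axis_point": [float(x) for x in a.axis_point],
            "axis_direction": [float(x) for x in a.axis_direction],
            "rotation_angle": float(a.rotation_angle),
            "translation_along_axis": float(a.translation_along_axis),
        }
        for a in arrows
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def write_viewer_script(
    s: Structure, arrows: list[ArrowDescriptor], path, length_scale: float = 10.0
) -> None:
    """PyMOL-dialect CGO script drawing one arrow per domain."""
    with open(path, "w") as fh:
        fh.write("# draw primitives: one pseudo-atom pair + distance per arrow\n")
        for a in arrows:
            start = a.axis_point
            end = a.axis_point + length_scale * a.axis_direction
            fh.write(
                f"pseudoatom arrow{a.domain_id}_a, pos=[{start[0]:.2f}, "
                f"{start[1]:.2f}, {start[2]:.2f}]\n"
            )
            fh.write(
                f"pseudoatom arrow{a.domain_id}_b, pos=[{end[0]:.2f}, "
                f"{end[1]:.2f}, {end[2]:.2f}]\n"
            )
            fh.write(f"distance arrow{a.domain_id}, arrow{a.domain_id}_a, arrow{a.domain_id}_b\n")
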