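"""Dihedral-space degrees of freedom, Jacobian and torsional H / T matrices.

A structure is decomposed into *bodies*: connected components of its bond
graph.  The body containing the first atom is the kinematic root; every
other body (additional chains, rigid ligands) contributes 6 rigid-body
degrees of freedom (3 translations + 3 rotations about its centre of mass).
Within a body the free variables are backbone torsion angles:

* proteins at heavy_atom / five_point level: phi (C'-N-CA-C') and psi
  (N-CA-C'-N) per residue, omitting undefined termini and proline phi;
* proteins at calpha level: virtual torsions about consecutive CA-CA axes;
* nucleic acids at heavy_atom level: the rotatable backbone set
  {alpha, beta, gamma, epsilon, zeta}; delta and the sugar pucker are kept
  rigid; at CG levels virtual torsions over the reduced backbone trace;
* ligands: no internal degrees of freedom.

Each torsion rotates the downstream side of its bond (the component of the
bond graph containing the second axis atom once the axis edge is cut; edges
inside rings never qualify).  Raw rotational derivatives are projected to
satisfy the Eckart conditions -- every Jacobian column carries zero total
linear and angular momentum -- so the modes are free of net rigid-body
motion and independent of the (arbitrary) tree root.

The torsional Hessian and kinetic matrix follow as H = J^T K J and
T = J^T M J, valid at equilibrium where the potential gradient vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import elastic_network as enm
from ._geom import dihedral, kabsch, rotation_about_axis
from .structure_io import Structure

__all__ = [
    "DihedralDOF",
    "TorsionalSystem",
    "define_dofs",
    "free_dofs",
    "jacobian",
    "assemble",
    "rebuild_cartesian",
]

NUCLEIC_TORSIONS = (
    # name, quadruple as (residue offset, atom name) entries; axis = middle two
    ("alpha", ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'"))),
    ("beta", ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'"))),
    ("gamma", ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'"))),
    ("epsilon", ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P"))),
    ("zeta", ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'"))),
)


class DOFError(Exception):
    pass


@dataclass
class DihedralDOF:
    dof_index: int
    kind: str  # phi | psi | calpha_virtual | nucleic_backbone | inter_chain_rigid
    axis_atoms: tuple[int, int]
    moved_set: np.ndarray
    value: float = 0.0
    fixed: bool = False
    quad: tuple[int, int, int, int] | None = None
    # rigid-body bookkeeping (inter_chain_rigid only)
    rigid_mode: str | None = None  # "trans" | "rot"
    rigid_axis: np.ndarray | None = None
    body: int = 0
    label: str = ""

    @property
    def is_torsion(self) -> bool:
        return self.kind != "inter_chain_rigid"


@dataclass
class TorsionalSystem:
    dofs: list[DihedralDOF]
    jacobian: np.ndarray
    hessian: np.ndarray
    kinetic: np.ndarray

    @property
    def n(self) -> int:
        return len(self.dofs)


def free_dofs(dofs: list[DihedralDOF]) -> list[DihedralDOF]:
    return [d for d in dofs if not d.fixed]


# ----------------------------------------------------------------------
# DOF enumeration


def _adjacency(n_atoms: int, bond_list) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bond_list:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _bodies(n_atoms: int, adj) -> np.ndarray:
    """Connected-component label per atom, ordered by first atom index."""
    label = -np.ones(n_atoms, dtype=int)
    nxt = 0
    for seed in range(n_atoms):
        if label[seed] >= 0:
            continue
        stack = [seed]
        label[seed] = nxt
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if label[v] < 0:
                    label[v] = nxt
                    stack.append(v)
        nxt += 1
    return label


def _downstream(adj, a: int, b: int, body_atoms: set[int]) -> np.ndarray | None:
    """Atoms moved by rotating about bond (a, b): the component of b after
    cutting the edge, excluding b itself.  None if the edge lies in a ring."""
    seen = {b}
    stack = [b]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if u == b and v == a:
                continue
            if v == a:
                return None  # reached a without the cut edge -> ring
            if v not in seen:
                seen.add(v)
                stack.append(v)
    seen.discard(b)
    moved = sorted(seen & body_atoms)
    return np.array(moved, dtype=int)


def _residue_table(s: Structure):
    """Per residue: dict name->atom index, plus class/chain metadata."""
    out = []
    for sl in s.residue_slices():
        names = {}
        for i in range(sl.start, sl.stop):
            names.setdefault(s.names[i], i)
        out.append({
            "atoms": names,
            "class": s.molecule_class[sl.start],
            "chain": s.chain_ids[sl.start],
            "resnum": int(s.res_numbers[sl.start]),
            "resname": s.res_names[sl.start],
            "slice": sl,
        })
    return out


def _protein_phi_psi(s, residues, adj, body_atoms, body_label):
    cand = []
    for k, res in enumerate(residues):
        if res["class"] != "protein":
            continue
        A = res["atoms"]
        prev_res = residues[k - 1] if k > 0 else None
        next_res = residues[k + 1] if k + 1 < len(residues) else None
        same_prev = prev_res is not None and prev_res["chain"] == res["chain"]
        same_next = next_res is not None and next_res["chain"] == res["chain"]
        # phi: C'(k-1) - N - CA - C'
        if (same_prev and res["resname"] != "PRO"
                and all(n in A for n in ("N", "CA", "C")) and "C" in prev_res["atoms"]):
            quad = (prev_res["atoms"]["C"], A["N"], A["CA"], A["C"])
            cand.append(("phi", (A["N"], A["CA"]), quad, res, "phi"))
        # psi: N - CA - C' - N(k+1)
        if (same_next and all(n in A for n in ("N", "CA", "C"))
                and "N" in next_res["atoms"]):
            quad = (A["N"], A["CA"], A["C"], next_res["atoms"]["N"])
            cand.append(("psi", (A["CA"], A["C"]), quad, res, "psi"))
    return cand


def _nucleic_backbone(s, residues, adj, body_atoms, body_label):
    cand = []
    for k, res in enumerate(residues):
        if res["class"] != "nucleic":
            continue
        for name, spec in NUCLEIC_TORSIONS:
            quad = []
            ok = True
            for off, atom_name in spec:
                kk = k + off
                if not (0 <= kk < len(residues)) or residues[kk]["chain"] != res["chain"]:
                    ok = False
                    break
                idx = residues[kk]["atoms"].get(atom_name)
                if idx is None:
                    ok = False
                    break
                quad.append(idx)
            if ok:
                cand.append(("nucleic_backbone", (quad[1], quad[2]), tuple(quad), res, name))
    return cand


def _virtual_trace(s, residues, chain):
    """Trace-atom list (CA / P / C4') of one chain at CG levels."""
    trace = []
    for res in residues:
        if res["chain"] != chain or res["class"] == "ligand":
            continue
        for name in ("CA", "P", "C4'"):
            if name in res["atoms"]:
                trace.append((res["atoms"][name], res))
                if s.cg_level == "calpha" or name == "CA":
                    break
        # five_point nucleic contributes both P and C4' to the trace
    return trace


def define_dofs(
    s: Structure,
    fix_spec: str | None = None,
) -> list[DihedralDOF]:
    """Enumerate torsional and rigid-body degrees of freedom.

    ``fix_spec`` freezes DOFs: ``"A:10-50"`` (comma-separable residue
    ranges), ``"ss"`` (helix/strand residues from the source PDB records) or
    ``"random:<fraction>:<seed>"`` (an exact rounded fraction of the
    torsions, reproducible for a fixed seed).  Fixed DOFs stay in the list
    with ``fixed=True``; downstream consumers use the free subset.
    """
    bond_list = enm.bonds(s)
    adj = _adjacency(s.n_atoms, bond_list)
    body_label = _bodies(s.n_atoms, adj)
    residues = _residue_table(s)

    candidates = []  # (kind, axis, quad, residue)
    use_phi_psi = s.cg_level in ("heavy_atom", "five_point")
    if use_phi_psi:
        candidates += _protein_phi_psi(s, residues, adj, None, body_label)
        candidates += _nucleic_backbone(s, residues, adj, None, body_label)
    else:
        # virtual torsions over the CG backbone trace, per chain
        for chain in s.chain_order():
            trace = _virtual_trace(s, residues, chain)
            for t in range(1, len(trace) - 2):
                a, _ = trace[t]
                b, res = trace[t + 1]
                quad = (trace[t - 1][0], a, b, trace[t + 2][0])
                candidates.append(("calpha_virtual", (a, b), quad, res, "virtual"))
    if s.cg_level == "five_point":
        # nucleic five_point trace torsions (no atomic backbone present)
        for chain in s.chain_order():
            trace = [x for x in _virtual_trace(s, residues, chain)
                     if x[1]["class"] == "nucleic"]
            for t in range(1, len(trace) - 2):
                a, _ = trace[t]
                b, res = trace[t + 1]
                quad = (trace[t - 1][0], a, b, trace[t + 2][0])
                candidates.append(("calpha_virtual", (a, b), quad, res, "virtual"))

    body_sets = [set(np.nonzero(body_label == lab)[0])
                 for lab in range(body_label.max() + 1)]

    dofs: list[DihedralDOF] = []
    for kind, (a, b), quad, res, torname in candidates:
        if body_label[a] != body_label[b]:
            continue
        body = int(body_label[a])
        moved = _downstream(adj, a, b, body_sets[body])
        if moved is None or len(moved) == 0:
            continue
        upstream = len(body_sets[body]) - len(moved) - 2
        if upstream < 1:
            continue  # rotation would be (nearly) a rigid-body motion
        value = dihedral(*(s.coords[i] for i in quad))
        dofs.append(DihedralDOF(
            dof_index=len(dofs), kind=kind, axis_atoms=(int(a), int(b)),
            moved_set=moved, value=value, quad=quad, body=body,
            label=f"{torname}:{res['chain']}:{res['resnum']}",
        ))

    # rigid-body DOFs for every body except the root
    for body in range(1, body_label.max() + 1):
        atoms = np.array(sorted(body_sets[body]), dtype=int)
        if len(atoms) == 0:
            continue
        m = s.masses[atoms]
        com = (m[:, None] * s.coords[atoms]).sum(axis=0) / m.sum()
        for mode in ("trans", "rot"):
            for ax in np.eye(3):
                dofs.append(DihedralDOF(
                    dof_index=len(dofs), kind="inter_chain_rigid",
                    axis_atoms=(-1, -1), moved_set=atoms, value=0.0,
                    rigid_mode=mode, rigid_axis=ax.copy(), body=body,
                    label=f"rigid:{body}:{mode}",
                ))

    n_chain_atoms = s.n_atoms
    if not dofs:
        raise DOFError("no degrees of freedom could be defined")
    _apply_fix_spec(s, dofs, fix_spec, residues)
    n_free = len(free_dofs(dofs))
    if n_free == 0:
        raise DOFError("fix specification froze every degree of freedom")
    if n_free > 3 * n_chain_atoms - 6:
        raise DOFError("more DOFs than independent coordinates")
    return dofs


def _apply_fix_spec(s, dofs, fix_spec, residues):
    if not fix_spec:
        return
    torsions = [d for d in dofs if d.is_torsion]
    spec = fix_spec.strip()
    if spec.startswith("random:"):
        _, frac, seed = spec.split(":")
        frac = float(frac)
        rng = np.random.default_rng(int(seed))
        n_fix = int(round(frac * len(torsions)))
        for idx in rng.choice(len(torsions), size=n_fix, replace=False):
            torsions[idx].fixed = True
        return
    if spec == "ss":
        ranges = s.ss_ranges
        if not ranges:
            raise DOFError("no HELIX/SHEET records available for ss fixation")
    else:
        ranges = []
        for part in spec.split(","):
            chain, span = part.split(":")
            lo, hi = span.split("-")
            ranges.append((chain, int(lo), int(hi)))
    for d in torsions:
        chain, resnum = d.label.split(":")[1], int(d.label.split(":")[2])
        for c, lo, hi in ranges:
            if chain == c and lo <= resnum <= hi:
                d.fixed = True
                break


# ----------------------------------------------------------------------
# Jacobian


def _raw_column(s: Structure, d: DihedralDOF) -> np.ndarray:
    col = np.zeros((s.n_atoms, 3))
    if d.is_torsion:
        a, b = d.axis_atoms
        # axis oriented b -> a so that a positive dq increases the measured
        # dihedral (IUPAC sign convention)
        axis = s.coords[a] - s.coords[b]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise DOFError(f"zero-length torsion axis for DOF {d.label}")
        e = axis / norm
        col[d.moved_set] = np.cross(e, s.coords[d.moved_set] - s.coords[a])
    else:
        atoms = d.moved_set
        if d.rigid_mode == "trans":
            col[atoms] = d.rigid_axis
        else:
            m = s.masses[atoms]
            com = (m[:, None] * s.coords[atoms]).sum(axis=0) / m.sum()
            col[atoms] = np.cross(d.rigid_axis, s.coords[atoms] - com)
    return col


def eckart_project(s: Structure, col: np.ndarray) -> np.ndarray:
    """Remove net linear and angular momentum (about the COM) from a
    per-atom displacement field."""
    m = s.masses
    M = m.sum()
    com = (m[:, None] * s.coords).sum(axis=0) / M
    v = col - (m[:, None] * col).sum(axis=0) / M
    d = s.coords - com
    L = (m[:, None] * np.cross(d, v)).sum(axis=0)
    inertia = np.einsum("i,i->", m, np.einsum("ij,ij->i", d, d)) * np.eye(3) \
        - np.einsum("i,ij,ik->jk", m, d, d)
    omega = np.linalg.solve(inertia, L)
    return v - np.cross(omega, d)


def jacobian(s: Structure, dofs: list[DihedralDOF]) -> np.ndarray:
    """3N x n matrix of Eckart-projected Cartesian derivatives d r / d q."""
    free = free_dofs(dofs)
    J = np.zeros((3 * s.n_atoms, len(free)))
    for k, d in enumerate(free):
        col = eckart_project(s, _raw_column(s, d))
        J[:, k] = col.ravel()
    return J


# ----------------------------------------------------------------------
# H, T assembly


def assemble(s: Structure, net, dofs: list[DihedralDOF]) -> TorsionalSystem:
    """Torsional system: H = J^T K J, T = J^T M J (symmetric; T must be PD)."""
    J = jacobian(s, dofs)
    K = enm.cartesian_hessian(net, s)
    if sp.issparse(K):
        H = J.T @ (K @ J)
    else:
        H = J.T @ K @ J
    H = 0.5 * (H + H.T)
    mass3 = np.repeat(s.masses, 3)
    T = (J * mass3[:, None]).T @ J
    T = 0.5 * (T + T.T)
    tol = 1e-10 * max(np.trace(T) / max(len(T), 1), 1.0)
    w = np.linalg.eigvalsh(T)
    if w[0] <= tol:
        vec = np.linalg.eigh(T)[1][:, 0]
        worst = np.argsort(-np.abs(vec))[:3]
        names = [free_dofs(dofs)[i].label for i in worst]
        raise DOFError(
            f"kinetic matrix numerically singular (lambda_min={w[0]:.3g}); "
            f"dependent DOFs likely among {names}"
        )
    return TorsionalSystem(dofs=free_dofs(dofs), jacobian=J, hessian=H, kinetic=T)


# ----------------------------------------------------------------------
# Exact rebuilding


def rebuild_cartesian(
    s: Structure, dofs: list[DihedralDOF], dq: np.ndarray
) -> Structure:
    """Apply a finite internal-coordinate displacement by exact rotations.

    Torsions are composed along the kinematic tree (upstream first), so all
    bond lengths and bond angles are preserved exactly; the result is
    mass-weighted superposed back onto ``s`` to remove the arbitrary global
    frame.  ``dq = 0`` returns ``s`` unchanged.
    """
    free = free_dofs(dofs)
    dq = np.asarray(dq, dtype=float)
    if dq.shape != (len(free),):
        raise ValueError(f"dq must have length {len(free)}")
    coords = s.coords.copy()
    if np.any(dq != 0.0):
        for d, delta in zip(free, dq):
            if delta == 0.0:
                continue
            if d.is_torsion:
                a, b = d.axis_atoms
                axis = coords[a] - coords[b]
                R = rotation_about_axis(axis, delta)
                coords[d.moved_set] = (coords[d.moved_set] - coords[a]) @ R.T + coords[a]
            elif d.rigid_mode == "trans":
                coords[d.moved_set] += delta * d.rigid_axis
            else:
                atoms = d.moved_set
                m = s.masses[atoms]
                com = (m[:, None] * coords[atoms]).sum(axis=0) / m.sum()
                R = rotation_about_axis(d.rigid_axis, delta)
                coords[atoms] = (coords[atoms] - com) @ R.T + com
        R, t, _ = kabsch(coords, s.coords, weights=s.masses)
        coords = coords @ R.T + t
    return s.with_coords(coords)
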