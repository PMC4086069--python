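"""Deterministic synthetic structures for tests, examples and benchmarks.

Everything here is built from ideal covalent geometry with the NeRF
(natural extension of reference frame) construction, so generated torsion
angles are exact by construction and every fixture is bit-reproducible.
Available fixtures: ideal poly-alanine alpha-helices, extended chains,
two-domain hinge dumbbells with a known hinge angle, a minimal poly-U
backbone for nucleic DOF enumeration, and synthetic rigid-body displacement
fields with a known partition.
"""

from __future__ import annotations

import numpy as np

from ._geom import dihedral, kabsch, place_atom, rotation_angle
from .structure_io import ELEMENT_MASSES, Structure

__all__ = [
    "make_helix",
    "make_extended_chain",
    "make_peptide",
    "make_hinge_pair",
    "hinge_regions",
    "make_poly_u",
    "make_two_rigid_field",
    "helix_rise",
    "hinge_angle_between",
]

# Ideal peptide geometry (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O, A_C_CA_CB = 121.7, 111.2, 116.2, 120.8, 110.1
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-140.0, 135.0)


def _rad(x):
    return np.deg2rad(x)


def make_peptide(
    phi_psi: list[tuple[float, float]],
    res_name: str = "ALA",
    chain_id: str = "A",
    first_res_number: int = 1,
) -> Structure:
    """Poly-amino-acid chain with prescribed backbone (phi, psi) in degrees.

    Residues carry N, CA, C, O and (unless glycine) CB; phi of the first
    and psi of the last residue are placed with the listed values but are
    kinematically undefined.
    """
    n = len(phi_psi)
    if n < 2:
        raise ValueError("need at least 2 residues")
    atoms = []  # (name, element, coord, res_index)

    def add(name, element, coord, ri):
        atoms.append((name, element, np.asarray(coord, dtype=float), ri))

    # bootstrap residue 0 in a canonical frame
    N0 = np.zeros(3)
    CA0 = np.array([B_N_CA, 0.0, 0.0])
    ang = _rad(A_N_CA_C)
    C0 = CA0 + B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    add("N", "N", N0, 0)
    add("CA", "C", CA0, 0)
    add("C", "C", C0, 0)
    pos = {("N", 0): N0, ("CA", 0): CA0, ("C", 0): C0}

    for i in range(1, n):
        phi_prev, psi_prev = phi_psi[i - 1]
        Np = place_atom(pos[("N", i - 1)], pos[("CA", i - 1)], pos[("C", i - 1)],
                        B_C_N, _rad(A_CA_C_N), _rad(psi_prev))
        CAp = place_atom(pos[("CA", i - 1)], pos[("C", i - 1)], Np,
                         B_N_CA, _rad(A_C_N_CA), _rad(OMEGA))
        phi_i, _ = phi_psi[i]
        Cp = place_atom(pos[("C", i - 1)], Np, CAp,
                        B_CA_C, _rad(A_N_CA_C), _rad(phi_i))
        add("N", "N", Np, i)
        add("CA", "C", CAp, i)
        add("C", "C", Cp, i)
        pos[("N", i)] = Np
        pos[("CA", i)] = CAp
        pos[("C", i)] = Cp

    # decorate every residue with O and CB (placement order is irrelevant)
    decorated = []
    for i in range(n):
        _, psi_i = phi_psi[i]
        O = place_atom(pos[("N", i)], pos[("CA", i)], pos[("C", i)],
                       B_C_O, _rad(A_CA_C_O), _rad(psi_i) + np.pi)
        decorated.append(("O", "O", O, i))
        if res_name != "GLY":
            CB = place_atom(pos[("N", i)], pos[("C", i)], pos[("CA", i)],
                            B_CA_CB, _rad(A_C_CA_CB), _rad(-122.6))
            decorated.append(("CB", "C", CB, i))

    # assemble in PDB residue order N, CA, C, O, CB
    order = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}
    all_atoms = atoms + decorated
    all_atoms.sort(key=lambda a: (a[3], order[a[0]]))

    names = np.array([a[0] for a in all_atoms], dtype=object)
    elements = np.array([a[1] for a in all_atoms], dtype=object)
    coords = np.array([a[2] for a in all_atoms])
    ridx = np.array([a[3] for a in all_atoms])
    n_atoms = len(all_atoms)
    return Structure(
        coords=coords, names=names, elements=elements,
        res_names=np.array([res_name] * n_atoms, dtype=object),
        chain_ids=np.array([chain_id] * n_atoms, dtype=object),
        res_numbers=ridx + first_res_number,
        icodes=np.array([""] * n_atoms, dtype=object),
        occupancies=np.ones(n_atoms),
        bfactors=np.zeros(n_atoms),
        masses=np.array([ELEMENT_MASSES[e] for e in elements]),
        molecule_class=np.array(["protein"] * n_atoms, dtype=object),
        cg_level="heavy_atom",
    )


def make_helix(n_residues: int) -> Structure:
    """Ideal poly-alanine alpha-helix (phi = -57, psi = -47 degrees)."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues for a helix")
    return make_peptide([HELIX_PHI_PSI] * n_residues)


def make_extended_chain(n_residues: int) -> Structure:
    """Extended (beta-like) poly-alanine chain."""
    return make_peptide([EXTENDED_PHI_PSI] * n_residues)


def hinge_regions(n_per_domain: int, linker_len: int = 4) -> dict:
    """0-based residue index lists of the dumbbell's parts."""
    d1 = list(range(n_per_domain))
    lnk = list(range(n_per_domain, n_per_domain + linker_len))
    d2 = list(range(n_per_domain + linker_len, 2 * n_per_domain + linker_len))
    return {"domain1": d1, "linker": lnk, "domain2": d2}


def make_hinge_pair(
    n_per_domain: int = 20, hinge_angle: float = 40.0, linker_len: int = 4
) -> tuple[Structure, Structure]:
    """Two-domain helical dumbbell and a copy bent by a known hinge angle.

    The source is helix--extended-linker--helix; the target is produced by
    rotating everything downstream of the central linker psi axis by
    ``hinge_angle`` degrees with an exact torsion rotation, so the two
    structures share identical covalent geometry and differ by one known
    internal-coordinate displacement.
    """
    from .internal_coords import define_dofs, free_dofs, rebuild_cartesian

    if not 0.0 <= hinge_angle < 120.0:
        raise ValueError("hinge_angle must be in [0, 120) degrees")
    reg = hinge_regions(n_per_domain, linker_len)
    phi_psi = ([HELIX_PHI_PSI] * n_per_domain
               + [EXTENDED_PHI_PSI] * linker_len
               + [HELIX_PHI_PSI] * n_per_domain)
    source = make_peptide(phi_psi)
    if hinge_angle == 0.0:
        return source, source.copy()
    # central linker psi (0-based residue index n_per_domain + linker_len//2 - 1)
    pivot_resnum = reg["linker"][linker_len // 2 - 1] + 1
    dofs = define_dofs(source)
    dq = np.zeros(len(free_dofs(dofs)))
    hit = [k for k, d in enumerate(free_dofs(dofs))
           if d.kind == "psi" and d.label.endswith(f":{pivot_resnum}")]
    if not hit:
        raise RuntimeError("central linker psi DOF not found")
    dq[hit[0]] = _rad(hinge_angle)
    target = rebuild_cartesian(source, dofs, dq)
    # steric sanity: no pair from non-adjacent residues closer than 1.5 A
    from scipy.spatial import cKDTree

    ridx = target.residue_index()
    pairs = cKDTree(target.coords).query_pairs(1.5)
    clashes = [(i, j) for i, j in pairs if abs(ridx[i] - ridx[j]) >= 2]
    if clashes:
        raise RuntimeError(
            f"hinge fixture has {len(clashes)} steric clashes; "
            "choose a different hinge angle or domain size"
        )
    return source, target


# ----------------------------------------------------------------------
# Minimal nucleic backbone

NUCLEIC_STEPS = (
    # atom, element, bond, angle(deg), torsion name
    ("C5'", "C", 1.44, 120.9, "alpha"),
    ("C4'", "C", 1.51, 111.5, "beta"),
    ("C3'", "C", 1.53, 115.5, "gamma"),
    ("O3'", "O", 1.42, 110.6, "delta"),
    ("P", "P", 1.60, 119.7, "epsilon"),
    ("O5'", "O", 1.59, 103.8, "zeta"),
)

POLY_U_TORSIONS = {
    "alpha": -65.0, "beta": 180.0, "gamma": 55.0,
    "delta": 80.0, "epsilon": -150.0, "zeta": -70.0,
}


def make_poly_u(n_residues: int) -> Structure:
    """Minimal poly-U backbone (P, O5', C5', C4', C3', O3' per residue).

    A-form-like backbone torsions; the sugar ring and base are not built
    (this fixture exists to exercise nucleic DOF enumeration).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 nucleotides")
    chain = [("P", "P"), ("O5'", "O")]
    coords = [np.zeros(3), np.array([1.59, 0.0, 0.0])]
    ang0 = _rad(120.9)
    coords.append(coords[1] + 1.44 * np.array([np.cos(np.pi - ang0), np.sin(np.pi - ang0), 0.0]))
    chain.append(("C5'", "C"))
    step_cycle = NUCLEIC_STEPS[1:] + NUCLEIC_STEPS[:1]  # next to place: C4'
    k = 0
    total = 6 * n_residues
    while len(chain) < total:
        name, el, bond, angle_deg, torsion = step_cycle[k % len(step_cycle)]
        a, b, c = coords[-3], coords[-2], coords[-1]
        coords.append(place_atom(a, b, c, bond, _rad(angle_deg),
                                 _rad(POLY_U_TORSIONS[torsion])))
        chain.append((name, el))
        k += 1
    coords = np.array(coords[:total])
    names = np.array([c[0] for c in chain[:total]], dtype=object)
    elements = np.array([c[1] for c in chain[:total]], dtype=object)
    ridx = np.repeat(np.arange(n_residues), 6)
    return Structure(
        coords=coords, names=names, elements=elements,
        res_names=np.array(["U"] * total, dtype=object),
        chain_ids=np.array(["A"] * total, dtype=object),
        res_numbers=ridx + 1,
        icodes=np.array([""] * total, dtype=object),
        occupancies=np.ones(total),
        bfactors=np.zeros(total),
        masses=np.array([ELEMENT_MASSES[e] for e in elements]),
        molecule_class=np.array(["nucleic"] * total, dtype=object),
        cg_level="heavy_atom",
    )


# ----------------------------------------------------------------------
# Synthetic displacement fields


def make_two_rigid_field(
    n_per_domain: int = 12, seed: int = 0
) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Dumbbell plus a displacement field of two distinct rigid motions.

    Returns ``(structure, field, labels)`` where atoms of each domain (and
    its half of the linker) move under their own infinitesimal rotation +
    translation; labels give the generating partition.
    """
    rng = np.random.default_rng(seed)
    s, _ = make_hinge_pair(n_per_domain, hinge_angle=25.0)
    ridx = s.residue_index()
    # boundary at the first linker residue so the generating partition is a
    # union of contiguous 4-residue windows (n_per_domain must be a multiple
    # of the clustering seed window for exact recovery to be well-posed)
    labels = np.where(ridx < n_per_domain, 0, 1)
    field = np.zeros_like(s.coords)
    for lab in (0, 1):
        atoms = np.nonzero(labels == lab)[0]
        omega = rng.normal(size=3) * 0.05
        t = rng.normal(size=3) * 0.5
        centre = s.coords[atoms].mean(axis=0)
        field[atoms] = np.cross(omega, s.coords[atoms] - centre) + t
    return s, field, labels


# ----------------------------------------------------------------------
# Fixture oracles (used by tests and the worked examples)


def helix_rise(s: Structure) -> float:
    """Mean rise per residue along the best-fit helix axis (CA trace)."""
    ca = s.coords[s.calpha_indices()]
    centred = ca - ca.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ Vt[0]
    return float(np.abs(np.diff(np.sort(proj))).mean())


def hinge_angle_between(
    a: Structure, b: Structure, domain1_atoms: np.ndarray, domain2_atoms: np.ndarray
) -> float:
    """Rotation (degrees) of domain 2 between two conformers, after aligning
    domain 1 -- the recovered hinge angle of a dumbbell pair."""
    R1, t1, _ = kabsch(b.coords[domain1_atoms], a.coords[domain1_atoms])
    moved = b.coords @ R1.T + t1
    R2, _, _ = kabsch(moved[domain2_atoms], a.coords[domain2_atoms])
    return float(np.rad2deg(rotation_angle(R2)))
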