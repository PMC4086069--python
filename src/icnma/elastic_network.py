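"""Harmonic elastic-network construction and the Cartesian Hessian.

The potential is a pairwise harmonic well

    V = sum_{i<j} F_ij (r_ij - r_ij^0)^2

with the input conformation as the minimum (r^0 = current distances), so
V = 0 at the input and the curvature of each spring is 2 F_ij.  Two
stiffness functions are provided: the inverse-exponential sigmoid

    k(r) = k0 / (1 + (r/r0)^p)

(default k0 = 1, r0 = 3.8 A -- the Calpha-Calpha virtual bond length --
p = 6) and the classical distance cutoff k(r) = k0 for r <= cutoff.
Sequentially bonded sites are always connected regardless of the stiffness
function, which guarantees chain connectivity at coarse-grained levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "Spring",
    "ElasticNetwork",
    "stiffness_cutoff",
    "stiffness_inverse_exponential",
    "build_network",
    "cartesian_hessian",
    "network_energy",
    "linking_matrix",
    "bonds",
]

#: dense Hessian below this many atoms, sparse at or above
SPARSE_THRESHOLD = 1500


@dataclass
class Spring:
    i: int
    j: int
    rest_length: float
    stiffness: float

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("spring requires i < j")
        if self.rest_length <= 0:
            raise ValueError("non-positive rest length")
        if self.stiffness < 0:
            raise ValueError("negative stiffness")


@dataclass
class ElasticNetwork:
    springs: list[Spring]
    potential_name: str = "inverse_exponential"
    parameters: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.springs)

    def arrays(self):
        """(i, j, rest_length, stiffness) as flat numpy arrays."""
        i = np.array([s.i for s in self.springs], dtype=int)
        j = np.array([s.j for s in self.springs], dtype=int)
        r0 = np.array([s.rest_length for s in self.springs])
        k = np.array([s.stiffness for s in self.springs])
        return i, j, r0, k


def stiffness_cutoff(r: float, cutoff: float = 8.0, k0: float = 1.0) -> float:
    """Step stiffness: k0 inside the cutoff (boundary inclusive), 0 outside."""
    if r <= 0 or cutoff <= 0:
        raise ValueError("distance and cutoff must be positive")
    return k0 if r <= cutoff else 0.0


def stiffness_inverse_exponential(
    r: float, k0: float = 1.0, r0: float = 3.8, p: float = 6.0
) -> float:
    """Sigmoidal stiffness k0 / (1 + (r/r0)^p); equals k0/2 at r = r0."""
    if r <= 0 or r0 <= 0 or p <= 0 or k0 <= 0:
        raise ValueError("all parameters must be positive")
    return k0 / (1.0 + (r / r0) ** p)


def bonds(s: Structure) -> list[tuple[int, int]]:
    """Covalent / virtual bond list for the structure's CG level.

    heavy_atom: distance-based (1.85 A, widened to 2.25 A for S/P pairs)
    within a chain.  CG levels: backbone succession plus pseudo-atom
    attachments; calpha uses consecutive-CA virtual bonds (< 4.5 A).
    """
    out: set[tuple[int, int]] = set()
    if s.cg_level == "heavy_atom":
        tree = cKDTree(s.coords)
        for i, j in tree.query_pairs(2.25):
            d = np.linalg.norm(s.coords[i] - s.coords[j])
            heavy = {s.elements[i].upper(), s.elements[j].upper()} & {"S", "P", "SE"}
            if d <= (2.25 if heavy else 1.85) and s.chain_ids[i] == s.chain_ids[j]:
                out.add((min(i, j), max(i, j)))
        return sorted(out)

    slices = s.residue_slices()
    prev_tail: dict[str, int | None] = {}
    for sl in slices:
        cls = s.molecule_class[sl.start]
        chain = s.chain_ids[sl.start]
        names = list(s.names[sl])

        def gi(name):
            return sl.start + names.index(name) if name in names else None

        if cls == "protein":
            if s.cg_level == "calpha":
                ca = gi("CA")
                if prev_tail.get(chain) is not None and ca is not None:
                    if np.linalg.norm(s.coords[ca] - s.coords[prev_tail[chain]]) < 4.5:
                        out.add((prev_tail[chain], ca))
                prev_tail[chain] = ca
            else:  # five_point
                n, ca, c, o, sc = gi("N"), gi("CA"), gi("C"), gi("O"), gi("SC")
                for a, b in ((n, ca), (ca, c), (c, o), (ca, sc)):
                    if a is not None and b is not None:
                        out.add((min(a, b), max(a, b)))
                if prev_tail.get(chain) is not None and n is not None:
                    out.add((prev_tail[chain], n))
                prev_tail[chain] = c
        elif cls == "nucleic":
            if s.cg_level == "calpha":
                p = sl.start
                if prev_tail.get(chain) is not None:
                    out.add((prev_tail[chain], p))
                prev_tail[chain] = p
            else:
                p, c4, nb = gi("P"), gi("C4'"), gi("NB")
                for a, b in ((p, c4), (c4, nb)):
                    if a is not None and b is not None:
                        out.add((min(a, b), max(a, b)))
                tail = c4 if c4 is not None else p
                head = p if p is not None else c4
                if prev_tail.get(chain) is not None and head is not None:
                    out.add((min(prev_tail[chain], head), max(prev_tail[chain], head)))
                prev_tail[chain] = tail
        else:  # ligand: distance bonds within the residue
            coords = s.coords[sl]
            tree = cKDTree(coords)
            for i, j in tree.query_pairs(1.85):
                out.add((sl.start + min(i, j), sl.start + max(i, j)))
    return sorted(out)


def build_network(
    s: Structure,
    potential: str = "inverse_exponential",
    params: dict | None = None,
) -> ElasticNetwork:
    """Create springs for all site pairs with non-negligible stiffness.

    Rest lengths are the current distances (the input conformation is the
    energy minimum).  Bonded neighbours are always included.
    """
    if s.n_atoms < 2:
        raise ValueError("need at least 2 atoms to build a network")
    params = dict(params or {})
    k0 = params.setdefault("k0", 1.0)
    if potential == "cutoff":
        cutoff = params.setdefault(
            "cutoff", 8.0 if s.cg_level == "calpha" else 5.0
        )
        radius = cutoff
    elif potential == "inverse_exponential":
        r0 = params.setdefault("r0", 3.8)
        p = params.setdefault("p", 6.0)
        floor = params.setdefault("floor", 1e-6)
        # truncation radius where k(r) drops below floor*k0
        radius = r0 * (1.0 / floor - 1.0) ** (1.0 / p)
    else:
        raise ValueError(f"unknown potential {potential!r}")

    bond_set = set(bonds(s))
    pair_set = set(cKDTree(s.coords).query_pairs(radius))
    pair_set.update(bond_set)
    springs = []
    for i, j in sorted(pair_set):
        d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
        if d <= 0:
            raise ValueError(f"coincident atoms {i}, {j}")
        if potential == "cutoff":
            k = stiffness_cutoff(d, cutoff, k0) if d <= cutoff else 0.0
        else:
            k = stiffness_inverse_exponential(d, k0, r0, p)
        if (i, j) in bond_set and k <= 0:
            k = k0  # bonded pairs never disconnect
        if k > 0:
            springs.append(Spring(i, j, d, k))
    net = ElasticNetwork(springs, potential, params)
    # connectivity check
    deg = np.zeros(s.n_atoms)
    for spr in springs:
        deg[spr.i] += 1
        deg[spr.j] += 1
    if np.any(deg == 0):
        warnings.warn(
            f"{int((deg == 0).sum())} atoms have no spring; rigid-body modes will inflate"
        )
    return net


def network_energy(net: ElasticNetwork, coords: np.ndarray) -> float:
    """Evaluate V = sum F_ij (r_ij - r_ij^0)^2 at arbitrary coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    i, j, r0, k = net.arrays()
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(np.sum(k * (d - r0) ** 2))


def cartesian_hessian(net: ElasticNetwork, s: Structure, sparse: bool | None = None):
    """Assemble the 3N x 3N second-derivative matrix of the network energy.

    Valid at equilibrium (rest lengths equal to current distances): each
    spring contributes the block 2 F_ij (u u^T) on the diagonal and its
    negative off-diagonal, with u the unit inter-site vector.
    """
    n = s.n_atoms
    i, j, r0, k = net.arrays()
    d = np.linalg.norm(s.coords[i] - s.coords[j], axis=1)
    if np.any(np.abs(d - r0) > 1e-6 * np.maximum(1.0, r0)):
        raise ValueError("network rest lengths do not match current coordinates")
    if sparse is None:
        sparse = n >= SPARSE_THRESHOLD
    u = (s.coords[j] - s.coords[i]) / d[:, None]
    blocks = 2.0 * k[:, None, None] * np.einsum("na,nb->nab", u, u)
    if not sparse:
        K = np.zeros((3 * n, 3 * n))
        for (a, b), B in zip(zip(i, j), blocks):
            K[3 * a:3 * a + 3, 3 * b:3 * b + 3] -= B
            K[3 * b:3 * b + 3, 3 * a:3 * a + 3] -= B
            K[3 * a:3 * a + 3, 3 * a:3 * a + 3] += B
            K[3 * b:3 * b + 3, 3 * b:3 * b + 3] += B
        return K
    rows, cols, vals = [], [], []
    for (a, b), B in zip(zip(i, j), blocks):
        for (ra, ca, sgn) in ((a, b, -1.0), (b, a, -1.0), (a, a, 1.0), (b, b, 1.0)):
            for x in range(3):
                for y in range(3):
                    rows.append(3 * ra + x)
                    cols.append(3 * ca + y)
                    vals.append(sgn * B[x, y])
    return sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()


def linking_matrix(net: ElasticNetwork, n_atoms: int) -> np.ndarray:
    """Symmetric N x N matrix of spring stiffnesses (0 where no spring)."""
    L = np.zeros((n_atoms, n_atoms))
    for spr in net.springs:
        L[spr.i, spr.j] = spr.stiffness
        L[spr.j, spr.i] = spr.stiffness
    return L


def write_linking_matrix(L: np.ndarray, path, triplets: bool = False) -> None:
    if triplets:
        with open(path, "w") as fh:
            for i in range(L.shape[0]):
                for j in range(i + 1, L.shape[1]):
                    if L[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{L[i, j]:.6g}\n")
    else:
        np.savetxt(path, L, fmt="%.6g")
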