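"""Structure reading/writing, coarse graining and homolog residue matching.

The in-memory :class:`Structure` is an array-of-columns container (one numpy
array per atom attribute) holding heavy atoms only, grouped contiguously by
chain and residue in file order.  Three coarse-grain levels are supported:

``heavy_atom``
    all non-hydrogen atoms (the finest level);
``five_point``
    protein residues reduced to N, CA, C, O and one side-chain centroid
    pseudo-atom carrying the side-chain mass (glycine keeps 4 sites);
    nucleotides reduced to P, C4' and a base centroid;
``calpha``
    one site per amino acid at the CA position carrying the full residue
    mass; nucleotides reduced to the P atom.

Ligand residues are kept as all heavy atoms at every level and treated as
internally rigid downstream.  Per-residue mass is conserved exactly by every
reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "ResidueMatch",
    "read_pdb",
    "coarse_grain",
    "match_residues",
    "write_pdb",
    "write_multimodel_pdb",
    "write_profile",
]

# Standard atomic masses (amu); sufficient for biomolecular heavy atoms.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "MG": 24.305, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "ZN": 65.38, "NA": 22.990, "K": 39.098, "CU": 63.546, "NI": 58.693,
    "CO": 58.933, "MO": 95.95, "W": 183.84, "B": 10.81,
}

AMINO_ACIDS_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

NUCLEIC_NAMES = {"A", "C", "G", "U", "T", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"}

PROTEIN_BACKBONE = ("N", "CA", "C", "O", "OXT")
CG_LEVELS = ("heavy_atom", "five_point", "calpha")


class StructureError(Exception):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclass
class AtomRecord:
    """A single heavy atom (view of one row of a :class:`Structure`)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    mass: float = 12.011


def _mass_of(element: str, name: str) -> float:
    el = element.strip().upper()
    if not el:
        el = name.strip().upper().lstrip("0123456789")[:1]
    if el not in ELEMENT_MASSES:
        raise StructureError(f"unknown element {element!r} for atom {name!r}")
    return ELEMENT_MASSES[el]


class Structure:
    """Ordered heavy-atom structure at a chosen coarse-grain level.

    Atoms are stored as parallel numpy arrays and are grouped contiguously
    by chain then residue, in file order.  ``molecule_class`` tags each atom
    as ``protein``, ``nucleic`` or ``ligand``.
    """

    def __init__(
        self,
        coords: np.ndarray,
        names: np.ndarray,
        elements: np.ndarray,
        res_names: np.ndarray,
        chain_ids: np.ndarray,
        res_numbers: np.ndarray,
        icodes: np.ndarray,
        occupancies: np.ndarray,
        bfactors: np.ndarray,
        masses: np.ndarray,
        molecule_class: np.ndarray,
        cg_level: str = "heavy_atom",
        ss_ranges: list[tuple[str, int, int]] | None = None,
    ):
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.res_names = np.asarray(res_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.res_numbers = np.asarray(res_numbers, dtype=int)
        self.icodes = np.asarray(icodes, dtype=object)
        self.occupancies = np.asarray(occupancies, dtype=float)
        self.bfactors = np.asarray(bfactors, dtype=float)
        self.masses = np.asarray(masses, dtype=float)
        self.molecule_class = np.asarray(molecule_class, dtype=object)
        if cg_level not in CG_LEVELS:
            raise ValueError(f"unknown cg_level {cg_level!r}")
        self.cg_level = cg_level
        # helix/sheet residue ranges from the source file, for "ss" fixation
        self.ss_ranges = list(ss_ranges or [])
        for arr in (self.names, self.elements, self.res_names, self.chain_ids,
                    self.res_numbers, self.icodes, self.occupancies,
                    self.bfactors, self.masses, self.molecule_class):
            if len(arr) != n:
                raise StructureError("inconsistent per-atom array lengths")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise StructureError("non-positive atomic mass")
        self._residue_starts: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=i + 1, name=self.names[i], element=self.elements[i],
            residue_name=self.res_names[i], chain_id=self.chain_ids[i],
            residue_number=int(self.res_numbers[i]),
            insertion_code=self.icodes[i], coord=self.coords[i].copy(),
            occupancy=float(self.occupancies[i]),
            bfactor=float(self.bfactors[i]), mass=float(self.masses[i]),
        )

    @property
    def residue_starts(self) -> np.ndarray:
        """Start index of each residue (file order)."""
        if self._residue_starts is None:
            keys = [
                (self.chain_ids[i], self.res_numbers[i], self.icodes[i])
                for i in range(self.n_atoms)
            ]
            starts = [0] + [i for i in range(1, self.n_atoms) if keys[i] != keys[i - 1]]
            self._residue_starts = np.array(starts, dtype=int)
        return self._residue_starts

    @property
    def n_residues(self) -> int:
        return len(self.residue_starts)

    def residue_slices(self) -> list[slice]:
        starts = self.residue_starts
        ends = list(starts[1:]) + [self.n_atoms]
        return [slice(int(a), int(b)) for a, b in zip(starts, ends)]

    def residue_index(self) -> np.ndarray:
        """Per-atom residue index (0-based, file order)."""
        idx = np.zeros(self.n_atoms, dtype=int)
        for k, sl in enumerate(self.residue_slices()):
            idx[sl] = k
        return idx

    def chain_order(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen

    def chain_atom_indices(self, chain_id: str) -> np.ndarray:
        return np.nonzero(self.chain_ids == chain_id)[0]

    def calpha_indices(self) -> np.ndarray:
        """Indices of CA atoms (protein) or the per-residue trace site.

        At nucleic residues the P (or C4' at five_point when P is absent)
        serves as the trace atom; ligands contribute nothing.
        """
        out = []
        for sl in self.residue_slices():
            cls = self.molecule_class[sl.start]
            names = self.names[sl]
            if cls == "protein":
                hit = np.nonzero(names == "CA")[0]
            elif cls == "nucleic":
                hit = np.nonzero(names == "P")[0]
                if len(hit) == 0:
                    hit = np.nonzero(names == "C4'")[0]
            else:
                continue
            if len(hit):
                out.append(sl.start + int(hit[0]))
        return np.array(out, dtype=int)

    def copy(self) -> "Structure":
        return Structure(
            self.coords.copy(), self.names.copy(), self.elements.copy(),
            self.res_names.copy(), self.chain_ids.copy(),
            self.res_numbers.copy(), self.icodes.copy(),
            self.occupancies.copy(), self.bfactors.copy(), self.masses.copy(),
            self.molecule_class.copy(), self.cg_level, list(self.ss_ranges),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(out.coords) != self.n_atoms:
            raise StructureError("coordinate array has wrong length")
        return out

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return Structure(
            self.coords[idx], self.names[idx], self.elements[idx],
            self.res_names[idx], self.chain_ids[idx], self.res_numbers[idx],
            self.icodes[idx], self.occupancies[idx], self.bfactors[idx],
            self.masses[idx], self.molecule_class[idx], self.cg_level,
            list(self.ss_ranges),
        )

    def total_mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        return (self.masses[:, None] * self.coords).sum(axis=0) / self.masses.sum()


@dataclass
class ResidueMatch:
    """Residue correspondence between two structures from sequence alignment."""

    pairs: list[tuple[str, int, str, int]]
    alignment_score: float
    coverage: float
    # 0-based residue indices into each structure, parallel to ``pairs``
    residue_index_pairs: list[tuple[int, int]] = field(default_factory=list)


# ----------------------------------------------------------------------
# Reading / writing


def _classify_residue(res_name: str, hetero: bool, atom_names: set[str]) -> str:
    if res_name in AMINO_ACIDS_3TO1 or (not hetero and "CA" in atom_names and "N" in atom_names):
        return "protein"
    if res_name in NUCLEIC_NAMES:
        return "nucleic"
    return "ligand"


def _parse_ss_records(path) -> list[tuple[str, int, int]]:
    ranges = []
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("HELIX"):
                    ranges.append((line[19].strip(), int(line[21:25]), int(line[33:37])))
                elif line.startswith("SHEET"):
                    ranges.append((line[21].strip(), int(line[22:26]), int(line[33:37])))
    except (ValueError, IndexError, OSError):
        pass
    return ranges


def read_pdb(path, model_index: int = 1) -> Structure:
    """Read one model of a PDB file into a heavy-atom :class:`Structure`.

    Hydrogens and waters are discarded; alternate locations are resolved to
    the highest-occupancy conformer; HETATM groups are tagged ``ligand``.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
    except OSError as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    arr = pdb_file.get_structure(
        model=model_index, altloc="occupancy",
        extra_fields=["b_factor", "occupancy"],
    )
    keep = ~np.isin(arr.element, ("H", "D"))
    keep &= ~np.isin(arr.res_name, tuple(WATER_NAMES))
    arr = arr[keep]
    if arr.array_length() == 0:
        raise StructureError(f"no heavy atoms parsed from {path}")

    n = arr.array_length()
    classes = np.empty(n, dtype=object)
    # classify residue-wise
    res_key = None
    start = 0
    for i in range(n + 1):
        if i < n:
            key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i])
        if i == n or key != res_key:
            if res_key is not None:
                names = set(arr.atom_name[start:i])
                classes[start:i] = _classify_residue(
                    arr.res_name[start], bool(arr.hetero[start]), names
                )
            res_key = key
            start = i
    masses = np.array([_mass_of(el, nm) for el, nm in zip(arr.element, arr.atom_name)])
    return Structure(
        coords=arr.coord,
        names=arr.atom_name.astype(object),
        elements=arr.element.astype(object),
        res_names=arr.res_name.astype(object),
        chain_ids=arr.chain_id.astype(object),
        res_numbers=arr.res_id,
        icodes=arr.ins_code.astype(object),
        occupancies=arr.occupancy,
        bfactors=arr.b_factor,
        masses=masses,
        molecule_class=classes,
        cg_level="heavy_atom",
        ss_ranges=_parse_ss_records(path),
    )


def _to_atom_array(s: Structure, bfactors: np.ndarray | None = None):
    import biotite.structure as struc

    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = np.array([c[:4] for c in s.chain_ids], dtype="U4")
    arr.res_id = s.res_numbers
    arr.ins_code = np.array([c[:1] for c in s.icodes], dtype="U1")
    arr.res_name = np.array([r[:5] for r in s.res_names], dtype="U5")
    arr.atom_name = np.array([n[:6] for n in s.names], dtype="U6")
    arr.element = np.array([e[:2] for e in s.elements], dtype="U2")
    arr.hetero = np.array(s.molecule_class == "ligand")
    arr.set_annotation("occupancy", s.occupancies.astype(float))
    b = s.bfactors if bfactors is None else np.asarray(bfactors, dtype=float)
    arr.set_annotation("b_factor", b)
    return arr


def write_pdb(s: Structure, path, bfactors: np.ndarray | None = None) -> None:
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(_to_atom_array(s, bfactors))
    f.write(str(path))


def write_multimodel_pdb(
    frames: list[Structure], path, bfactors: np.ndarray | None = None
) -> None:
    """Write frames sharing one atom ordering as a multi-MODEL PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if not frames:
        raise StructureError("no frames to write")
    n = frames[0].n_atoms
    for k, fr in enumerate(frames):
        if fr.n_atoms != n or not np.array_equal(fr.names, frames[0].names):
            raise StructureError(f"frame {k} does not share the atom ordering of frame 0")
    stack = struc.stack([_to_atom_array(fr, bfactors) for fr in frames])
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_profile(s: Structure, values: np.ndarray, path, header: str = "value") -> None:
    """Write a per-atom profile as TSV (chain, resnum, atom, value)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"chain\tresnum\tatom\t{header}\n")
        for i in range(s.n_atoms):
            fh.write(
                f"{s.chain_ids[i]}\t{s.res_numbers[i]}\t{s.names[i]}\t{values[i]:.6g}\n"
            )


# ----------------------------------------------------------------------
# Coarse graining


def _reduce_residue(s: Structure, sl: slice, level: str):
    """Yield (template_atom_index, name, element, coord, mass) for one residue."""
    cls = s.molecule_class[sl.start]
    names = s.names[sl]
    coords = s.coords[sl]
    masses = s.masses[sl]
    idx0 = sl.start

    def pick(name):
        hit = np.nonzero(names == name)[0]
        return int(hit[0]) if len(hit) else None

    if cls == "ligand":
        for j in range(len(names)):
            yield idx0 + j, names[j], s.elements[idx0 + j], coords[j], masses[j]
        return

    if cls == "protein":
        ca = pick("CA")
        if ca is None:
            warnings.warn(
                f"residue {s.res_names[idx0]} {s.res_numbers[idx0]} lacks CA; kept as-is"
            )
            for j in range(len(names)):
                yield idx0 + j, names[j], s.elements[idx0 + j], coords[j], masses[j]
            return
        if level == "calpha":
            yield idx0 + ca, "CA", "C", coords[ca], masses.sum()
            return
        # five_point
        side = [j for j in range(len(names)) if names[j] not in PROTEIN_BACKBONE]
        for bb in ("N", "CA", "C", "O"):
            j = pick(bb)
            if j is not None:
                m = masses[j]
                if bb == "C":  # fold any OXT into the carbonyl carbon site
                    ox = pick("OXT")
                    if ox is not None:
                        m = m + masses[ox]
                yield idx0 + j, bb, s.elements[idx0 + j], coords[j], m
        if side:
            msum = masses[side].sum()
            centroid = (masses[side, None] * coords[side]).sum(axis=0) / msum
            yield idx0 + side[0], "SC", "C", centroid, msum
        return

    # nucleic
    p = pick("P")
    c4 = pick("C4'")
    if level == "calpha":
        anchor = p if p is not None else c4
        if anchor is None:
            anchor = 0
        yield idx0 + anchor, "P" if p is not None else names[anchor], \
            s.elements[idx0 + anchor], coords[anchor], masses.sum()
        return
    # five_point nucleotide: P (phosphate group), C4' (sugar), base centroid
    phosphate = [j for j in range(len(names)) if names[j] in ("P", "OP1", "OP2", "OP3")]
    sugar = [j for j in range(len(names))
             if names[j].endswith("'") or names[j] in ("O5'", "O3'")]
    base = [j for j in range(len(names)) if j not in phosphate and j not in sugar]
    if p is not None and phosphate:
        yield idx0 + p, "P", "P", coords[p], masses[phosphate].sum()
    if c4 is not None and sugar:
        yield idx0 + c4, "C4'", "C", coords[c4], masses[sugar].sum()
    if base:
        msum = masses[base].sum()
        centroid = (masses[base, None] * coords[base]).sum(axis=0) / msum
        yield idx0 + base[0], "NB", "N", centroid, msum


def coarse_grain(s: Structure, level: str) -> Structure:
    """Reduce a heavy-atom structure to ``five_point`` or ``calpha`` sites.

    Per-residue mass is conserved exactly; ligands keep all heavy atoms.
    """
    if level not in CG_LEVELS:
        raise ValueError(f"unknown cg_level {level!r}")
    if level == "heavy_atom":
        return s.copy()
    if s.cg_level != "heavy_atom":
        raise StructureError("coarse_grain expects a heavy_atom-level input")
    rows = []
    for sl in s.residue_slices():
        for tpl, name, element, coord, mass in _reduce_residue(s, sl, level):
            rows.append((tpl, name, element, coord, mass))
    tpl_idx = np.array([r[0] for r in rows], dtype=int)
    return Structure(
        coords=np.array([r[3] for r in rows]),
        names=np.array([r[1] for r in rows], dtype=object),
        elements=np.array([r[2] for r in rows], dtype=object),
        res_names=s.res_names[tpl_idx],
        chain_ids=s.chain_ids[tpl_idx],
        res_numbers=s.res_numbers[tpl_idx],
        icodes=s.icodes[tpl_idx],
        occupancies=s.occupancies[tpl_idx],
        bfactors=s.bfactors[tpl_idx],
        masses=np.array([r[4] for r in rows]),
        molecule_class=s.molecule_class[tpl_idx],
        cg_level=level,
        ss_ranges=list(s.ss_ranges),
    )


# ----------------------------------------------------------------------
# Homolog matching


def _chain_sequence(s: Structure, chain_id: str):
    """One-letter sequence + residue descriptors for one chain (protein/nucleic)."""
    letters = []
    residues = []
    ridx = s.residue_index()
    for k, sl in enumerate(s.residue_slices()):
        if s.chain_ids[sl.start] != chain_id:
            continue
        cls = s.molecule_class[sl.start]
        rn = s.res_names[sl.start]
        if cls == "protein":
            letters.append(AMINO_ACIDS_3TO1.get(rn, "X"))
        elif cls == "nucleic":
            letters.append(rn.lstrip("D")[-1] if rn else "N")
        else:
            continue
        residues.append((k, int(s.res_numbers[sl.start])))
    del ridx
    return "".join(letters), residues


def _align(seq_a: str, seq_b: str, nucleic: bool):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if nucleic:
        aligner.match_score = 5
        aligner.mismatch_score = -4
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            pairs.append((a0 + off, b0 + off))
    return float(aln.score), pairs


def match_residues(a: Structure, b: Structure, min_coverage: float = 0.25) -> ResidueMatch:
    """Match residues of two (possibly homologous) structures chain by chain.

    Each chain of ``a`` is paired with the unused chain of ``b`` whose global
    alignment scores highest; aligned non-gap columns become residue pairs.
    Identical sequences give the identity mapping.
    """
    chains_a = [c for c in a.chain_order() if _chain_sequence(a, c)[0]]
    chains_b = [c for c in b.chain_order() if _chain_sequence(b, c)[0]]
    if not chains_a or not chains_b:
        raise StructureError("no protein/nucleic chains to match")
    seqs_a = {c: _chain_sequence(a, c) for c in chains_a}
    seqs_b = {c: _chain_sequence(b, c) for c in chains_b}

    def is_nucleic(s: Structure, c: str) -> bool:
        idx = s.chain_atom_indices(c)
        return bool(np.any(s.molecule_class[idx] == "nucleic"))

    pairs: list[tuple[str, int, str, int]] = []
    ridx_pairs: list[tuple[int, int]] = []
    total_score = 0.0
    used_b: set[str] = set()
    matched_src = 0
    for ca in chains_a:
        seq_a, res_a = seqs_a[ca]
        best = None
        for cb in chains_b:
            if cb in used_b:
                continue
            seq_b, res_b = seqs_b[cb]
            score, idx_pairs = _align(seq_a, seq_b, is_nucleic(a, ca))
            cov = len(idx_pairs) / max(len(seq_a), 1)
            if best is None or score > best[0]:
                best = (score, cb, idx_pairs, cov, res_b)
        if best is None:
            continue
        score, cb, idx_pairs, cov, res_b = best
        if cov < min_coverage:
            continue
        used_b.add(cb)
        total_score += score
        matched_src += len(idx_pairs)
        for ia, ib in idx_pairs:
            pairs.append((ca, res_a[ia][1], cb, res_b[ib][1]))
            ridx_pairs.append((res_a[ia][0], res_b[ib][0]))
    n_src = sum(len(seqs_a[c][0]) for c in chains_a)
    coverage = matched_src / max(n_src, 1)
    if not pairs:
        raise StructureError("no chain pair aligned above the coverage threshold")
    return ResidueMatch(
        pairs=pairs, alignment_score=total_score, coverage=coverage,
        residue_index_pairs=ridx_pairs,
    )


def matched_calpha_indices(
    a: Structure, b: Structure, match: ResidueMatch
) -> tuple[np.ndarray, np.ndarray]:
    """Atom indices of matched trace (CA / P) atoms, parallel arrays."""
    def trace_of(s: Structure) -> dict[int, int]:
        out = {}
        ridx = s.residue_index()
        for i in s.calpha_indices():
            out[int(ridx[i])] = int(i)
        return out

    ta, tb = trace_of(a), trace_of(b)
    ia, ib = [], []
    for ra, rb in match.residue_index_pairs:
        if ra in ta and rb in tb:
            ia.append(ta[ra])
            ib.append(tb[rb])
    return np.array(ia, dtype=int), np.array(ib, dtype=int)
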