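# Methods

## Model

A structure is modelled as an elastic network: every pair of sites within
range is joined by a harmonic spring with energy `F_ij (r_ij − r_ij⁰)²`
(note: no ½ prefactor — the curvature of a spring is therefore `2 F_ij`,
and the Cartesian Hessian `K` carries `2F` blocks; all derived analyses are
invariant to this overall scale). The input conformation is the energy
minimum by construction: rest lengths are the observed distances, so the
energy is zero at the input and positive for any non-rigid deformation of a
connected network.

Two stiffness functions are available:

* **inverse exponential** (default): `k(r) = k0 / (1 + (r/r0)^p)` with
  `k0 = 1`, `r0 = 3.8 Å` (the Cα–Cα virtual-bond length) and `p = 6`. The
  sixth-power sigmoid halves at `r0` and decays fast enough that springs
  with `k < 10⁻⁶ k0` are truncated. The exact functional form is a
  swappable strategy (`elastic_network.stiffness_*`).
* **distance cutoff**: constant `k0` up to a cutoff (boundary inclusive),
  default 8 Å at Cα level, 5 Å at heavy-atom level.

Sequentially bonded sites are always connected regardless of the stiffness
function, so coarse-grained chains can never fall apart into disconnected
bodies by accident.

## Degrees of freedom and kinematics

Internal coordinates are backbone torsions. The bond graph is cut at each
candidate axis; the connected component on the downstream side is the
torsion's moved set (an axis inside a ring never separates the graph and is
discarded, which automatically freezes sugar puckers and aromatic rings).
Per level:

* heavy-atom and five-point proteins: φ (C′–N–Cα–C′) and ψ (N–Cα–C′–N) per
  residue; φ of the first residue, ψ of the last and proline φ are
  undefined/frozen. Side-chain χ torsions are excluded: side groups ride
  rigidly on the backbone, which is the standard choice for collective-mode
  analysis.
* Cα level: the φ/ψ atoms do not exist, so the DOFs are virtual torsions
  about consecutive Cα–Cα axes (N−3 per chain). The same applies to the
  reduced nucleic trace.
* nucleic acids (heavy-atom): the rotatable backbone set
  {α, β, γ, ε, ζ}; δ and the ribose are rigid.
* every connected body other than the one containing the first atom
  (additional chains, rigid ligands) contributes 3 translational + 3
  rotational rigid-body DOFs about its centre of mass.

DOFs can be frozen by residue range, by the source file's HELIX/SHEET
records, or as an exact rounded random fraction with a seed (a cheap extra
coarse-graining step).

The Jacobian column of a torsion is the rotational derivative
`e × (r_i − p)` over the moved set, with the axis oriented so a positive
step increases the IUPAC dihedral. Columns are then Eckart-projected:
net linear momentum is removed, then net angular momentum about the centre
of mass (the two projections commute in the mass metric). Consequences
verified by tests: modes carry no rigid-body motion, the spectrum of a
connected network is strictly positive, and mode shapes do not depend on
the arbitrary kinematic root.

`H = Jᵀ K J` and `T = Jᵀ M J` are assembled densely (adequate at the scale
this package targets; the Hessian switches to sparse storage above 1500
atoms). `T` is checked for positive definiteness and the offending DOFs are
named when it fails (e.g. duplicated atoms).

Finite displacements are applied by exact sequential rotations along the
chain (upstream torsions first), then mass-weighted superposition back onto
the input to remove the arbitrary global frame. This preserves bond lengths
and angles to machine precision and agrees with `r + J Δq` to second order
in `‖Δq‖`.

## Eigensolution

`solve_dense` uses the LAPACK generalized symmetric solver; `solve_lowest`
uses shift-invert Lanczos at σ = 0 on `H + εT` (ε = 10⁻¹⁰·tr(H)/n) to
tolerate numerically semidefinite `H`, then re-orthonormalises in the `T`
metric. Both return ascending eigenvalues with `XᵀTX = I`; signs are fixed
lexicographically (first significant component positive) so results are
reproducible across solvers. The automatic choice switches to the iterative
solver above n = 1000 when few modes are requested. Default mode count: 50
or n, whichever is smaller.

Animations sample one period of `q(t) = q⁰ + a x_k cos(2πt/P)` at 16 frames
(δ = 0: the first frame is the peak). The amplitude `a` is calibrated by
bracketing + Brent root finding so the *peak frame's* trace-atom (Cα/P)
RMSD equals the requested excursion; because the rebuild is nonlinear the
+a and −a excursions differ slightly and the larger of the two defines the
peak.

## Analyses

All mode-weighted sums use classical equipartition, weight `1/λ_k`, with
kT absorbed into the arbitrary stiffness unit.

* **Mobility / B-factors**: `B_i = (8π²/3) Σ_k |u_ik|²/λ_k`, linearly
  rescaled to the experimental mean when experimental values exist.
* **Deformability**: for each atom and mode, the best infinitesimal rigid
  motion (ω, t) of the atoms within an 8 Å shell (broadened until ≥ 4
  members) is fitted by linear least squares; the atom's residual from that
  local rigid fit, squared, 1/λ-weighted and summed over modes, measures
  local non-rigidity. Profiles are normalised to a maximum of 1 — except
  when the peak is at numerical-noise level relative to the field's own
  fluctuation scale, so that an exactly rigid field reports ~0 rather than
  noise blown up to 1. The exact deformability formula in the literature is
  not fully specified; this local rigid-fit residual realises its stated
  behaviour (high at hinges/linkers, ~0 inside rigid domains) and is a
  swappable strategy.
* **Covariance map**: the dynamical cross-correlation
  `C_ij = Σ_k (u_ik·u_jk)/λ_k`, normalised by `√(C_ii C_jj)` into [−1, 1];
  for a single mode this is the cosine between displacement directions.
  Zero-fluctuation sites get zero rows with a warning.
* **Variance fractions**: `f_k = (1/λ_k)/Σ(1/λ_j)`.

## Morphing

The source is deformed toward the target in mode space: superpose the
target onto the current frame over sequence-matched trace atoms (global
Kabsch, or Gaussian-weighted IRLS "local" superposition with
`w_i = exp(−d_i²/s²)`, `s = 5 Å` by default, iterated to a fixed point);
project the difference vector onto the current lowest 20 modes via the
mass-metric gradient `a = Xᵀ Jᵀ M̃ Δr`; scale the step to 0.5 Å of trace
RMSD; rebuild exactly; accept only if the matched RMSD decreases, halving
the step otherwise (stall after 10 consecutive halvings). Modes are
refreshed from the deformed structure every 5 accepted steps. Residue
matching uses global pairwise alignment (BLOSUM62, gap open 10 / extend
0.5; +5/−4 for nucleic), so homologs with substitutions morph over all
aligned positions while insertions ride along without contributing signal.

The default stopping tolerance is 0.5 Å. Parameter-recovery checks (e.g.
recovering a constructed 40° hinge angle to ~1°) run the morph to 0.2 Å,
since a residual of 0.5 Å on a ~16 Å domain arm still corresponds to
several degrees of hinge error.

## Dynamic domains and arrows

A mode's displacement field is clustered agglomeratively: seeds are
contiguous 4-residue windows (small enough to resolve domains, large enough
for stable affine fits); each merge minimises the increase in mass-weighted
total squared residual of the merged affine fit `u ≈ A r + t` (Ward-style).
The antisymmetric part of each domain's `A` gives the rotation vector ω;
the screw axis passes through `(ω × t_eff)/|ω|²` and the axial translation
is `ω̂·t_eff`. Near-zero rotations degrade gracefully to pure-translation
arrows. The rendered curved-arrow path search of the original visualisation
is out of scope; the screw descriptor plus an axis polyline carries the
same information.

## Synthetic fixtures

`icnma.fixtures` builds all test inputs from ideal covalent geometry by
NeRF construction, bit-reproducibly: ideal poly-alanine α-helices
(φ = −57°, ψ = −47°; rise ≈ 1.5 Å/residue), extended chains, two-domain
hinge dumbbells whose conformers differ by one known internal-coordinate
displacement (so morphing has an exact ground truth), a minimal poly-U
backbone for nucleic DOF enumeration, and two/three-rigid-body displacement
fields with window-aligned generating partitions. What these fixtures do
*not* emulate: side-chain packing and rotamers, crystallographic disorder
(altlocs, missing atoms aside from targeted deletions), realistic sequence
composition, and experimental B-factor noise. Tests passing on them
demonstrate the correctness of the mechanics (kinematics, solvers,
clustering, convergence machinery), not prediction quality on real
crystal structures — the reference-reproduction tests on real PDB entries
cover that and require network access to fetch the entries.

## Numerical choices and limitations

* All problem sizes in tests and the acceptance script are desk-scale
  (≤ 300 atoms, ≤ 200-dimensional pencils), chosen so the whole suite runs
  in seconds while still exercising every code path including the iterative
  eigensolver.
* Finite-difference cross-checks use central differences (h = 10⁻⁵ Å for
  the Hessian, 10⁻⁶ rad for the Jacobian) with 10⁻⁶ agreement thresholds.
* Degenerate eigenvalues: the returned subspace is checked against the
  dense solver by principal angles; individual vectors within a degenerate
  cluster are not reproducible and should not be compared directly.
* The morph minimises RMSD greedily along low modes; it produces *feasible*
  (stereochemically exact, collectively smooth) pathways, not
  energy-optimal transition states, and local loop rearrangements outside
  the low-frequency subspace limit the final residual.
* Collinear structures (inertia tensor singular) are not supported by the
  Eckart projection; no biological chain is collinear in practice.
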