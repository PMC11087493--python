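# Methods

## Scope and model system

The toolkit analyzes icosahedral capsid structures of the kind exemplified
by the yeast L-A virus: a T = 1 shell of 60 asymmetric dimers (protomer
roles A and B, 120 Gag subunits in total), with capsid-stabilizing
cation-π interactions within and across protomers. It takes atomic models
(PDB/mmCIF), per-residue resolvability score tables, and 2D particle-pick
tables as input; it performs no image processing, model building, or map
analysis.

## Cation-π detection

**Geometric rule.** A contact is recorded between a cationic charge center
and an aromatic ring when

1. the charge-center → ring-centroid distance is ≤ `d_max` (default 5 Å), and
2. the angle θ between the ring normal and the centroid→cation vector,
   folded into [0°, 90°], is ≤ `theta_max` (default 45°).

The distance threshold of 5 Å is the conventional default for this
interaction class. "Perpendicular alignment" is operationalized as a 45°
acceptance cone about the ring normal — the standard criterion in the
cation-π literature — and is exposed as a parameter. Both thresholds are
inclusive, and the planted-fixture generator places geometry exactly on
them to verify the boundary behavior.

**Groups.**

- Cations: Arg → CZ (the symmetry center of the delocalized guanidinium —
  chosen over the NH1/NH2 midpoint so a single well-defined point
  represents the group), Lys → NZ, His (opt-in) → midpoint of ND1/NE2.
- Rings: Phe/Tyr six-ring (CG, CD1, CD2, CE1, CE2, CZ); Trp five-ring
  (CG, CD1, CD2, NE1, CE2) and six-ring (CD2, CE2, CE3, CZ2, CZ3, CH2)
  tested independently, one contact per qualifying ring; His five-ring
  opt-in. His is excluded by default on both sides because its protonation
  state is unknown in a heavy-atom model.
- Ring centroid = mean of member atoms; normal = smallest-eigenvalue
  eigenvector of the centered covariance (least-squares plane); the
  planarity RMS is reported. Residues with missing ring or charge atoms
  are skipped with a warning rather than raising.

**Search.** Candidate pairs come from a k-d-tree radius query over ring
centroids bounded by `d_max`; the result is guaranteed (and tested) to be
identical to an O(n²) all-pairs scan. Output is sorted by (cation residue,
ring residue, ring label) for determinism.

**Symmetry handling.** Chain copies produced by assembly expansion carry an
`_opNN` suffix (NN = zero-padded operator id; 00 is the identity). Scope is
intra-chain iff both residues share a chain id; a pair whose operator
suffixes differ is flagged symmetry-related. On expanded assemblies an
optional de-duplication reports each asymmetric-unit-unique contact once,
keeping the representative with the lexicographically smallest operator
pair — otherwise per-asymmetric-unit counts would be inflated 60-fold.

## Interaction networks

Networks are connected components of the graph whose nodes are residues and
whose edges are contacts (networkx). Component ids are assigned in order of
each component's smallest member residue, so output is deterministic under
any input permutation. The per-structure summary counts networks and the
union of participating side chains; the batch survey normalizes contacts
per 100 residues so capsids of different sizes are comparable across viral
families. Networks are computed on the asymmetric unit by default, matching
per-asymmetric-unit reporting; an assembly mode computes them on the
expanded capsid without de-duplication.

## Structure handling

Parsing is delegated to gemmi. Alternate locations collapse to the
highest-occupancy conformer (ties toward altloc 'A'); zero-occupancy atoms,
waters, and hydrogens are dropped by default (cryo-EM/X-ray inputs here are
heavy-atom models; a flag re-admits hydrogens). Coordinates are Å
throughout; no unit conversion occurs anywhere.

The 60 proper rotations of the icosahedral group are generated by closure
from a five-fold rotation about the vertex direction (0, 1, φ) and a
two-fold rotation about z, in the standard 532 orientation (two-fold axes
along the coordinate axes). The identity carries operator id 0; the
remaining elements are ordered by a lexicographic key on rounded matrix
entries, so ids are stable. Operators read from mmCIF assembly records are
preferred when present; `--assume-icosahedral` substitutes the generated
set for entries without annotation.

## Interface enumeration and energetics

**Classes.** For a symmetry-expanded capsid, every chain-copy pair with at
least one inter-atomic distance ≤ the contact cutoff (default 5 Å) yields
an interface descriptor. Descriptors merge into classes by a
rotation-invariant fingerprint: the sorted multiset of residue contact
pairs, with each side identified by its protomer role (or base chain id)
and asymmetric-unit residue numbering, canonicalized over the two
orientations. For a T = 1 dimer capsid this recovers the capsomere's
distinct interfaces — the intra-dimer contact plus the surrounding
inter-capsomere ones; for a vertex-transitive toy 12-mer all 30 edges
collapse to a single class.

**Energy model.** The interface score decomposes exactly as
`E_total = E_vdw + E_es + E_ds`:

- `E_vdw`: 12-6 pair potential over inter-chain heavy-atom pairs within
  8.5 Å, with a bundled per-element (rmin/2, ε) table and
  Lorentz–Berthelot combining; at the pair minimum the energy is exactly
  −ε_pair.
- `E_es`: Coulomb sum `k·q_i·q_j / (ε_r·r_ij)` over formal side-chain
  charges (Arg +0.5/+0.5 on NH1/NH2, Lys +1 on NZ, Asp/Glu −0.5 on each
  carboxylate oxygen), k = 332.0636 kcal·Å/(mol·e²), constant dielectric
  ε_r = 10 — a common choice for screened rigid-body scoring.
- `E_ds`: Σ ASP(element) × ΔSASA over all atoms, where ΔSASA is the
  solvent-accessible surface area buried on complex formation. SASA uses a
  deterministic Shrake–Rupley scheme: each atom's probe-expanded sphere
  (probe 1.4 Å) is sampled with a 960-point golden-spiral lattice and
  points inside any neighbor's sphere are occluded. The bundled atomic
  solvation parameters make apolar burial favorable (C −0.0151, S −0.0110
  kcal/mol/Å²) and polar burial unfavorable (N/O +0.0228).

This is an internal, fully documented scoring backend: only signs,
rankings, and the exact three-term decomposition are contracted. Absolute
values are not comparable to any external docking or refinement pipeline,
and the package makes no claim about externally published interface
energies. The deterministic point lattice is not rotated with the
coordinates, so `E_ds` is rigid-body invariant only to sampling resolution
(~10⁻² kcal/mol at 960 points); `E_vdw` and `E_es` are invariant to
floating-point precision.

**Greedy assembly.** The assembly graph has one node per protomer copy and
one edge per contacting pair, carrying its class's `E_total`. Starting from
a chosen subunit (default: lexicographically first chain — role A, identity
operator), each step places the unplaced node adjacent to the shell with
the minimum (most favorable) summed edge energy into the placed set, ties
broken by lowest node id. A complete 120-protomer capsid therefore takes
exactly 119 additions, the placed set always induces a connected subgraph,
and the cumulative energy equals the sum over edges internal to the placed
set — an invariant the tests check step by step. The trajectory report also
counts distinct per-step energy values, since several additions typically
share an energy level by symmetry. This is a static, template-based
ordering; it makes no claim about assembly kinetics or mechanism in vivo.
A helper (`connectivity_cutoff`) computes the smallest chain-centroid
cutoff that keeps a toy capsid's contact graph connected (the minimum
spanning tree bottleneck × 1.05), which decouples tests from monomer size.

## Survey and resolvability statistics

The resolvability comparison takes a per-residue score table (chain, resid,
resname, score; higher = better resolved — any such score is accepted, as
the metric itself is produced upstream) and tests whether residues engaged
in cation-π contacts are better resolved than same-type residues that are
not. The default is the pooled-variance Student's two-sample t-test with
Welch's variant by flag; stratification by residue type is on by default so
each comparison is within one side-chain chemistry. Groups with fewer than
2 observations are skipped (or raise when nothing is testable), and a
zero-variance degenerate case raises rather than returning NaN. The test
statistic is verified against the closed-form pooled formula to 1e-9 and
its type-I error is calibrated by null simulation (10,000 replicates, two
N(0,1) groups of 10): the empirical rejection rate at α = 0.05 must lie in
[0.04, 0.06].

## Community statistics

Particle picks are 2D coordinates in nm (micrograph scale). Nearest
neighbors come from a k-d tree, with mutual nearest pairs reported once;
distances are center-to-center by default with an optional
diameter-corrected edge-to-edge variant (the choice is a convention, both
are provided). Communities are single-linkage clusters at a user-supplied
cutoff — the cutoff has no default because grouping in micrographs is a
magnification-dependent judgment; singletons are counted separately and
excluded from size statistics by default. Box statistics use
linear-interpolation quantiles and Tukey 1.5·IQR whiskers with points
beyond reported as outliers. Packaging efficiency is
100 × n_full / (n_full + n_empty) over mature capsids, reported raw and
rounded to the nearest ten percent.

## Synthetic fixtures

All generators are pure functions of their spec, seeded through
`numpy.random.Generator(PCG64)`, so outputs are bit-reproducible.

- **Planted pairs** place an ideal planar ring (centroid at the origin,
  normal = z) and a cation charge center at exactly
  distance·(sin θ, 0, cos θ), so the detection rule can be exercised on a
  grid straddling both thresholds with zero geometric ambiguity.
- **Toy capsids** expand a monomer placed at a given radius along a
  generic (non-symmetry-axis) direction with the 60 icosahedral rotations;
  a separate vertex capsid puts 12 one-atom monomers on the icosahedron
  vertices, giving a vertex-transitive assembly whose 30 edges form one
  interface class.
- **Random structures** scatter idealized side-chain templates (planar
  rings, guanidinium/ammonium groups) at random positions and orientations
  in a box; they exercise the neighbor search against the brute-force
  oracle on irregular geometry. Template bond geometry is idealized, not
  refined — detection depends only on centroids, normals, and charge
  centers, which the templates realize exactly.
- **Particle fields** place communities on a widely spaced grid with sizes
  drawn from N(12, 4) (rounded, floor 2), radial member offsets
  |N(45, 10)| nm, diameters N(40, 2) nm, and a 0.377 full fraction —
  emulating the observed micrograph statistics of mature-virion
  communities. Ground-truth sizes are returned for recovery tests.

What the fixtures do **not** emulate: real side-chain conformational
variety, missing atoms and alternate conformations at scale, density-map
noise, or the manual curation a human expert applies to borderline
contacts. Passing tests therefore demonstrate the correctness of the
geometric, group-theoretic, and statistical machinery — not agreement with
any manually curated count on a deposited model, which additionally depends
on model quality and curation choices.

## Numerical conventions and degenerate inputs

- Quantiles: linear interpolation between order statistics.
- Ring normals are two-sided; θ is always folded into [0°, 90°].
- Threshold comparisons are inclusive (≤).
- Ties in the greedy step break to the lowest node id; ties in altloc
  occupancy break to 'A'; operator ids order the group elements
  deterministically.
- Degenerate inputs raise informative errors rather than returning
  sentinels: empty operator lists, disconnected assembly graphs (listing
  unreachable nodes), missing element parameters (naming the atom), groups
  too small or too constant for a t-test, fewer than 4 values for box
  statistics, fewer than 2 picks for neighbor distances.

## Problem sizes used in the bundled checks

The self-contained checks run on: a 9-point planted grid; 20 random
structures of 220 residues (~1,300 atoms each) for oracle equivalence; the
full 60-operator closure (3,600 products); 120-chain toy capsids for
expansion, interface, and assembly checks; 10,000 null replicates for
t-test calibration; and 200-community particle fields (~2,400 picks). These
sizes exercise every code path at full fidelity while keeping the suite
fast on a laptop.

## Known limitations

- Exact reproduction of manually curated interaction counts on deposited
  capsid models is not asserted; the raw geometric set plus flags is the
  contract.
- The energy backend's absolute values are not transferable to other force
  fields; only decomposition structure, signs, and rankings are meaningful.
- The greedy assembly pathway is a static energetic ordering, not a
  kinetic or thermodynamic model.
- Crystallographic space-group symmetry is out of scope; only point-group
  assembly operators are supported.
- Resolvability scores are consumed, never computed, and the edge- vs
  center-distance convention for particle pairs is a documented choice.
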