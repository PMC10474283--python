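# Methods

This note documents the models, parameter choices, and numerical
conventions behind each analysis stage, and what the synthetic
validation data do and do not establish.

## Collective variables

Two reaction coordinates describe the hinge equilibrium of the
two-domain protein (mature-sequence numbering, residues Pro22–Pro133):

* `phe63_asnrepeat_distance` — the distance between the Cα of Phe63 and
  the center of mass of the Asn-repeat Cα atoms (Asn113–Asn116), in Å.
  The Phe63 reference point is its Cα, consistent with the Cα phrasing
  of the repeat group; a whole-residue COM is one option away.
* `interdomain_theta` — the angle subtended at the COM of Cα group
  (ii) Lys120–Asn129 by the COMs of groups (i) Cys60–Val62 + Lys67–Cys69
  and (iii) Phe90–Asp96 + Asn100–Tyr107, in degrees.  Which of the
  three groups is the vertex is a convention; we take the second-listed
  group (ordered-triple angle notation) and make it configurable.

All Cα groups are equal-mass, so mass versus geometric weighting cannot
change these two CVs.  Angles are computed as
arccos of the normalized dot product, clipped to [−1, 1]; a vertex
within 1e-9 Å of an arm COM is a hard error rather than a NaN.

## Free-energy landscape

The joint CV histogram is Boltzmann-inverted,
`G_ij = −ln(n_ij / n_max)` in kT, so the highest-density bin is exactly
zero and ΔG between any two bins equals the log count ratio exactly.
Defaults: 120 bins per axis spanning the data range, T = 310 K
(temperature is a pure display scale here: 1 kT = 2.577 kJ/mol at
310 K).  Empty bins are masked, never imputed — inventing barrier
heights where nothing was sampled is worse than a blank.  No kernel
smoothing is applied.

`locate_minima` reports 4-neighbour local minima.  On a sampled surface
a single basin yields several shallow minima; the `min_separation`
option performs non-maximum suppression in bin space (deepest first) so
"top k basins" means k *distinct* basins.  When reading basins of a
2000-frame ensemble we use 24 bins, putting the bin width (~2°) on the
scale of the per-state angular spread; the 120-bin default is
appropriate for the much larger sample a full simulation study
provides.

## GROMOS clustering

Pairwise best-fit RMSD (fit and measurement on the same selection,
backbone by default) feeds the classic neighbour-counting loop: the
unassigned frame with the most neighbours below the cutoff (strictly
`< 4.0 Å`, ties to the lowest frame index) becomes a center, its
neighbourhood becomes a cluster and is removed, until no frames remain.
Every frame is assigned; isolated frames become singletons.  Clusters
are relabelled by size, and populations are percentages of all frames.
Equilibration removal (e.g. the first 50 ns) is a separate
`time_window` step, not baked into the clustering.

The F×F matrix is computed with batched 3×3 SVDs via the trace
identity `rmsd² = (Σ|a|² + Σ|b|² − 2(σ₁+σ₂±σ₃))/N`, which makes the
two-million-pair matrix of a 2000-frame ensemble a ~20 s computation.
The identity cancels catastrophically when frames are congruent, so
entries with msd < 1e-6 Å² are recomputed through the explicit optimal
rotation; the matrix is exact to ~1e-12 Å there.  The matrix is held
in memory (fine to F ≈ 5000; beyond that, compute row blocks and
stream them).

## Elastic network and RTB

The anisotropic network model connects every atom pair within a cutoff
by a harmonic spring; off-diagonal Hessian super-elements are
`−k(r) Δx Δxᵀ / r²` and diagonal blocks enforce translational
invariance exactly.  Spring stiffness is uniform by default (the
low-frequency mode *shapes* of hinge systems are robust to the k(r)
profile; an inverse-r⁶ weighting is available).  Cutoff: 8 Å is the
conventional all-atom choice and the default; for Cα-only
pseudo-proteins we use 10 Å, in line with the larger cutoffs customary
for coarse one-bead-per-residue networks — at 8 Å a Cα-only domain is
under-connected and develops spurious floppy modes.

RTB projects the mass-weighted Hessian onto each block's rigid-body
subspace (3 translations + up to 3 rotations about the block COM;
degenerate axes of near-collinear blocks are dropped via a rank-revealing
QR), diagonalizes the reduced matrix, and back-projects.  Blocks default
to one residue.  With single-atom blocks the projection spans the full
space, so RTB reproduces the exact spectrum — a built-in correctness
check — and for multi-atom blocks the reduced eigenvalues bound the
full ones from above (variational property, asserted in tests).
Eigenvectors are reported as normalized Cartesian displacement fields,
orthogonal in the mass-weighted metric; modes are numbered with the six
rigid-body modes first, so "mode 7" is the softest internal motion.

## PCA and overlap

Essential-dynamics PCA superposes all frames onto the iteratively
refit ensemble-average structure over the fit selection, then
diagonalizes the coordinate covariance of the analysis selection.
Superposition removes rigid-body variance, so planted test motions are
constructed orthogonal to the rigid subspace.  Overlap between
displacement vectors is the raw normalized inner product (signed); the
Pearson (centered) variant is a flag, since "correlation" between mode
vectors is reported ambiguously in the literature.  Identical or
negated inputs return ±1 exactly.

## Contacts and occupancy

A residue of group A is in contact in a frame iff any of its heavy
atoms (element ≠ H/D) lies within the cutoff of any heavy atom of
group B; the comparison is inclusive (≤ 3.5 Å) so boundary ties are
deterministic.  Queries run through a k-d tree and are tested to agree
exactly with an all-pairs scan.  Prevalence is reported to one decimal;
prevalence × F/100 is always an integer frame count.  Membrane contacts
reuse the same machinery with group B restricted to head or tail beads;
residue classes follow the fixed 9/7/4 hydrophobic/polar/charged
partition of the twenty standard residues.

The hydrogen-bond proxy counts N/O donor–acceptor pairs within the
cutoff, optionally gated by a donor–H–acceptor angle when hydrogens are
present (H assigned to the donor within 1.25 Å).  It is a geometric
stand-in for interaction-type analysis, not an energetic model.

Occupancy grids bin selected atom centers (e.g. water oxygens) on a
1 Å lattice spanning their bounding box padded by one voxel; a voxel is
occupied in a frame if it contains at least one selected atom, so
occupancy × F is integral.  Whether the conventional 0.44 isovalue
refers to a smoothed density or binary occupancy varies between tools;
we implement the binary definition (testable exactly) and leave the
threshold configurable.  Export is OpenDX text.

## Synthetic data: what it emulates

The hinge generator builds two internally stiff domains — antiparallel
bundles of ideal helix segments packed on a 2×2 lateral grid — joined
by a 4-residue linker near the origin.  The helix rise is 2.1 Å per
residue, slightly extended toward a 3₁₀-like geometry: the longer
lever arms keep conformations of the two planted states well beyond
the 4 Å clustering cutoff while the within-state spread stays well
inside it, which is the regime the two-state analysis assumes.  The
segment packing order and the domain-A anchor geometry were chosen so
that (a) the built-in angle CV sweeps ~10–160° as the hinge rotates,
covering the physiological closed/open range with margin, and (b) the
linker, stacked along the hinge axis, makes rotation about that axis
the softest internal elastic-network motion, so mode 7 is the hinge
mode by construction.

Per frame a state is drawn from the mixture weights (defaults 85°/118°
at 0.7/0.3 — closed-dominant), a target angle from
Normal(state, 3°), and the hinge rotation that makes the measured CV
equal that target *exactly* is found by bracketed root-finding; frames
are expressed in domain-B-fixed coordinates (domain A and the linker
carry the rotation), to which every analysis is indifferent.  Isotropic
0.3 Å Gaussian jitter models thermal noise.  Defaults are 2000 frames
at 250 ps spacing (500 ns).  Everything is a pure function of the seed.

The ligand, hydration, and membrane generators plant exact schedules:
a rigid 4-atom ligand whose nearest atom sits at the contact distance
from one designated residue in exactly `round(fraction × F)` frames
(placement is validated so no other residue ever comes within 3.5 Å);
one water occupying a fixed voxel in an exact fraction of frames and
scattered far away otherwise; and a two-leaflet slab of pseudo-lipids
with labelled P head beads and C tail beads under a protein whose
anchor residues are held within 3.5 Å of the heads while everything
else stays beyond 5 Å.  A membrane placement that cannot satisfy those
margins (e.g. a buried anchor of a globular domain) is an error, not a
silent approximation; `make_anchor_foot_protein` provides a receptor
with a protruding LEU/SER foot for which it is feasible.

**What passing these tests shows — and does not.**  The generators
reproduce the *statistical structure* the analyses assume: discrete
states with Gaussian spread, exact contact/occupancy schedules, rigid
domains.  They contain no force-field physics, no solvent, no
correlated dynamics, no partial or asymmetric contacts.  Recovery of
planted truth therefore validates the estimators and their
implementations, not any claim about real trajectories — headline
numbers from the motivating study (cluster populations, state
geometries, mode correlations) depend on undeposited simulations and
are deliberately not reproduction targets.

## Numerical conventions

Superposition is weighted Kabsch with reflection correction
(determinant forced to +1); collinear fit sets are rejected.  RMSD
deviations are mass-unweighted by default, matching common trajectory
tools.  Element inference falls back from PDB columns 77–78 to the atom
name, consulting a two-letter element table first but only outside
standard amino acids and waters — in a protein residue "CA" is an
alpha-carbon, not calcium.  `heavy` excludes both H and D.  Atom
indices are 0-based internally; residue IDs stay 1-based as in the
file.  Time windows are half-open `[t0, t1)`.  All generator and
analysis randomness flows through explicitly seeded `numpy` generators.

## Known limitations

No periodic-boundary handling (inputs are assumed whole/unwrapped, as
post-processed trajectories are); no mmCIF or compressed trajectory
formats; no WHAM/MBAR reweighting; no force-field Hessians or physical
frequency units; the hydrogen-bond proxy has no energetics.  The
in-memory RMSD matrix bounds clustering at a few thousand frames.
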