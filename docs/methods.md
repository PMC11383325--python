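# Methods

## Superposition and deviation metrics

All deviation/fluctuation metrics are defined after weighted least-squares
rigid-body superposition (Kabsch algorithm: SVD of the weighted
cross-covariance with the determinant-corrected proper rotation, so
reflections are never returned).  Degenerate geometry — fewer than three
atoms, or a (near-)collinear point cloud, where the rotation about the line
is undetermined — raises an error rather than returning an arbitrary
optimum.  Weights default to uniform: for Cα-only and backbone analyses
mass weighting is immaterial, and unweighted fitting is the convention of
the standard trajectory tools.

The RMSD reference is the trajectory's first frame by default (overridable
with any structure or coordinate set); fitting and measurement both default
to backbone atoms (N, CA, C, O).  Per-domain RMSD fits *locally* — the
domain's atoms onto the domain's own initial backbone — so the series
measures internal deformation of the domain, deliberately excluding its
rigid-body motion relative to the rest of the protein.  This differs from a
global fit and the code treats the two as distinct operations.

RMSF is taken about the **ensemble mean** after fitting, not about the
reference.  The reference only orients the frames.  This choice is forced
by an internal consistency requirement: the covariance matrix is built
about the ensemble mean, and with both conventions aligned the identity
trace(C) = Σ_i RMSF_i² holds exactly (it is asserted at 1e-10 relative in
the tests).  Two per-residue aggregation modes exist: `CA` (the Cα atom's
fluctuation) and `backbone-mean` (root of the mean-square fluctuation over
the residue's backbone atoms).

## Essential dynamics

The covariance is the unweighted second moment of the analysis atoms (Cα by
default) about their ensemble mean, normalised by F (population
convention); with that convention the variance of the projection onto
eigenvector k equals eigenvalue k exactly, which the tests assert at 1e-9
relative.  The default fitting selection for covariance construction is the
backbone while the analysis set is Cα — fitting on the backbone and
analysing Cα honours the common practice for essential-dynamics pipelines.

Eigendecomposition uses the symmetric solver; eigenvalues are sorted
nonincreasing, tiny negative values inside a 1e-9·trace band (numerical
PSD violations) are clipped to zero, and each eigenvector's sign is fixed
so its largest-magnitude component is positive.  The sign convention makes
eigenvectors, projections and mode endpoints bit-reproducible across BLAS
builds; within degenerate eigenvalue subspaces the basis remains arbitrary
up to the solver's ordering, which is documented rather than fixed.

Mode endpoints displace the mean structure by ±amplitude·√λ along a mode
(default amplitude 2, i.e. two standard deviations of the collective
coordinate) and export per-residue displacement vectors for porcupine-style
rendering.

### When to superpose

`build_covariance`, `rmsf_per_residue` and the run pipeline accept
`superpose=False`.  Superposition projects the six rigid-body degrees of
freedom out of every frame; for real trajectories that is indispensable,
but it also removes any *collective drift* present in the displacement
field itself.  The synthetic generator emits frames in a common laboratory
frame, and its planted one-directional domain motions have a nonzero net
translation component; fitting would convert the planted correlations into
artefacts (two positively shifted domains become anticorrelated once their
common motion is subtracted).  Planted-truth validation therefore runs
unfitted, and the rigid-jitter pathway validates the fitted route: metrics
of a jittered ensemble after fitting match the unjittered ensemble to
1e-6 or better, because the optimal superposition composes exactly with any
rigid transform.

## Cross-correlation

The DCCM entry is the normalised inner product of residue displacement
covariances, computed by taking traces of the 3×3 blocks of the covariance
matrix — the "post-process the PCA covariance" route, not a second pass
over frames, so DCCM and essential dynamics are guaranteed consistent.
Δr is displacement from the ensemble mean after fitting (the only
convention under which the DCCM derives from the PCA covariance).  A
residue with zero self-variance has no defined correlation and raises an
error naming the residue.

Per-residue scores sum the off-diagonal row, Cs_i = Σ_{j≠i} CC_ij, with the
self-term always excluded; the intra-domain part restricts j to residue i's
domain and the inter-domain parts to each partner domain, so
cs_intra + Σ_b cs_inter[b] = cs_total identically.  Domain accumulation
sums Cs over a domain's residues.  Raw sums are the default (they match the
"accumulated score" convention) but scale with domain size — a 25×25
residue pair block contributes 625 terms — so a `per-residue-pair`
normalisation (divide by contributing ordered pairs) is offered and every
output labels which was used.

## Hydrogen bonds

Detection is geometric: donor–acceptor distance ≤ 0.35 nm and
hydrogen–donor–acceptor angle ≤ 30°, with N and O as donor and acceptor
elements — the default criteria of the common MD analysis tools, and
configurable since conventions differ.  Hydrogens are assigned to their
covalent donor by distance (nearest N/O within 0.12 nm, ambiguous cases to
the nearest with a log entry); structures without explicit hydrogens are
rejected.  Occupancy is the percentage of frames a donor–hydrogen–acceptor
triple is bonded; the persistence filter is strict (> 10 %), and tables use
the `R160(HN)-R156(O)` donor(hydrogen)–acceptor(atom) labelling with
occupancies printed to one decimal.  For replicate trajectories both
averaging conventions are available and labelled: per-replica occupancies
averaged (`--no-pool`), or frames pooled before computing occupancy
(`--pool`).

## SASA

Shrake–Rupley point sampling with a deterministic golden-spiral point set
(default 960 points), probe radius 0.14 nm, and a bundled element radius
table (H 0.110, C 0.170, N 0.155, O 0.152, S/P 0.180 nm).  A point on an
atom's probe-inflated sphere is inaccessible if strictly inside a
neighbour's inflated sphere; points exactly *on* a neighbour surface (a
measure-zero degeneracy that arises for coincident atoms) are assigned to
the lower atom index, which keeps the total finite and deterministic.
Per-residue areas are sums of per-atom areas and partition the total
exactly.  Accuracy at 960 points is ~1–2 % against analytic two-sphere
results and an independent implementation with matched radii.

## The synthetic generator

The factor model plants, per residue i of domain d:

    r_i(t) = r_i0 + σ_i (ρ_d f_d(t) + √(1−ρ_d²) ε_i(t)) u_i

with domain factors f correlated across domains by a PSD unit-diagonal
matrix R and iid residue noise ε.  Displacements are one-dimensional along
unit directions u_i; that is what keeps the ground truth closed-form:
RMSF_i = σ_i, Σ-blocks σ_iσ_jK_ij u_iu_jᵀ with K_ij = ρ_aρ_bR_ab, and
DCCM_ij = ρ_aρ_bR_ab(u_i·u_j).  Anisotropy can be introduced through the
direction field without losing tractability.

Default study conditions: two 25-residue domains (a deliberately simplified
stand-in for the counter-moving recognition-lobe domains seen in Cas-protein
ensembles — an analogy for testing, not a claim of equivalence), per-residue
σ = 0.08 nm (a typical stable-residue Cα fluctuation; flexible loops in real
proteins reach several times that), loadings ρ = 1 with R₁₂ = −0.8 planting
a strong anticorrelation, F = 5000 frames at 1 ps spacing, fixed seeds.
All sampling is bit-exact reproducible per seed; derived seeds are spawned
from a single master seed.

Optional per-frame rigid jitter (uniform random rotation plus a 0.5 nm-scale
translation) exercises the superposition machinery.  Toy structures are
poly-alanine: Cα-only chains (exact 0.38 nm spacing extended; 0.23 nm
radius / 0.15 nm rise / 100° twist helix) or full backbones built from
ideal internal coordinates at α-helical (−57°, −47°) or extended
(−135°, 135°) torsions, with amide hydrogens on residues 2..n.  The helical
backbone carries genuine i→i+4 N–H···O bonds (0.309 nm, 10°), which is what
lets the H-bond pathway be validated on constructed geometry.

What the generator does *not* emulate: anharmonicity, multi-basin kinetics,
solvent, side chains, temperature dependence, and time correlation (frames
are iid draws).  Passing tests therefore demonstrate estimator correctness
on Gaussian ensembles with known truth — they do not certify behaviour on
real trajectories beyond the linear-statistics regime these estimators
address by construction.

## Run pipeline and reports

`run_single` executes a requested analysis subset from a validated config
and writes deterministic outputs (CSV/TSV at 6 significant digits,
occupancies at one decimal), then a manifest listing every file with its
SHA-256 checksum plus config hash, package version and seed — identical
(config, input, seed) triples give byte-identical trees.  `run_compare`
runs two ensembles under identical settings, refuses incompatible inputs
(different residue counts or domain maps), and writes paired tables and
DCCM / domain-score difference maps.

Per-frame-expensive analyses default to frame strides chosen for long
ensembles: H-bonds and SASA analyse every 10th frame and the all-to-all
RMSD matrix caps at 100 frames (the quadratic pair count dominates
otherwise).  All strides are configuration fields; analyses that are cheap
per frame (RMSD, RMSF, covariance, DCCM) always use every loaded frame.

## Numerical and interface choices

- Internal units nm/ps; Å only at PDB boundaries (one internal unit avoids
  silent factor-10 errors).
- Residue indexing 1-based with closed intervals, matching mutation labels
  like R160 or D868.
- Structure files: MODEL 1 is the structure (warning if more), altLoc blank
  or 'A' kept, insertion codes rejected (simulation-derived PDBs do not use
  them), single chain enforced unless a chain id is passed.
- Missing frame times are synthesised as stride × frame index (default
  1 ps).
- Degenerate ties: eigenvector signs per the largest-component rule; H-bond
  table ordering by occupancy then labels; SASA surface ties by atom index.

## Known limitations

Trajectory dialects are text-only (multi-model PDB, xyz-table); binary
formats need external conversion.  The DCCM captures linear correlation
only — mutual-information style generalised correlations are out of scope.
Raw-sum domain scores are size-dependent by design; compare domains of
different sizes with the per-pair normalisation.  The all-to-all RMSD
matrix is O(F²) in superpositions and is strided accordingly.
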