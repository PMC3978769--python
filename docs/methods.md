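# Methods

`encounterdock` models the association of two rigid proteins: a systematic
rigid-body search over their mutual orientations with a smooth physics-based
score, back-calculation of paramagnetic relaxation enhancement (PRE) profiles
from the resulting pose ensembles, and a principal-component characterization
of the energy landscape around the native pose in exponential-map coordinates.
This note records the models, their assumptions, the tunable parameters, and
the design choices made where the design was genuinely open.

## Rigid-body docking energy

The receptor is fixed; the ligand is rotated and translated. For each member
of a deterministic quasi-uniform rotation set, every translation on a cubic
grid (default spacing 1.0 Å) is scored with

    E = E_attr + w1 · E_rep + w2 · E_elec + w3 · E_pair

with default weights w1 = 4, w2 = 600, w3 = 5. The electrostatic term uses
the screened kernel

    E_elec = Σᵢⱼ qᵢqⱼ / sqrt(r² + D² exp(−r²/4D²)),

finite at contact (value qᵢqⱼ/D at r = 0) and Coulombic for r ≫ D. D is an
atom-type-independent generalized-Born scale; its value is not dictated by
the published weights, and we default to **D = 2.0 Å** (the order of a heavy
atom's Born radius), configurable. The pairwise contact potential
E_pair = Σᵢⱼ ε_{tᵢtⱼ} is evaluated through the eigendecomposition of the
symmetric type matrix ε: each retained eigencomponent becomes one correlation
channel, so the translational scan for one rotation costs P + 2 forward FFTs
and one inverse FFT. The retained rank is the smallest one covering 99% of
the absolute-eigenvalue mass by default.

The functional forms of the van der Waals channels are deliberately simple
and isolated behind the channel builder so alternatives are drop-in:

* **attractive**: a square well of depth 0.5 on grid nodes between the core
  radius and core + 2.0 Å of any receptor atom;
* **repulsive**: a constant penalty of height 1.0 inside the core, where the
  core radius is 0.9 × (atom radius + 1.7 Å probe). The finite height
  tolerates moderate steric overlap, keeping the landscape smooth enough for
  a rigid-body search.

Ligand atoms are snapped to their nearest grid node (trilinear spreading is
not implemented; nearest-node assignment is used identically by the FFT path
and the brute-force oracle so their equivalence is exact). Tie-breaks among
equal-energy translations go to the lowest flat grid index. The scan treats
translations circularly; only non-wrapping placements are eligible for
retention. `brute_force_scan` evaluates the identical discretized double sum
with no Fourier transforms and is the module's central oracle: the two agree
to ~1e-15 relative on every tested input.

`pose_energy` evaluates the same functional forms continuously (no grid) for
poses generated off-grid, e.g. along the contact manifold.

**Rotation sampling.** A deterministic layered low-dispersion spiral on the
quaternion 3-sphere (super-Fibonacci sequence), with the identity rotation
prepended by convention. Production scale is 70,000 rotations (~5°
resolution); the desk profile uses 500. Nearest-neighbor dispersion decreases
with count, which the tests check.

**Clustering.** Greedy, energy-ordered: the lowest-energy unassigned pose
seeds a cluster and absorbs all poses within 10 Å pairwise interface RMSD
(ligand interface Cα RMSD; receptors already share a frame).

## PRE back-calculation

The transverse PRE rate of a backbone amide proton at distance r from an
unpaired electron follows the r⁻⁶ law

    Γ_ji = C · Σₖ r_ikj⁻⁶,  C = 1.2 × 10¹⁰ Å⁶/s,

summed over the K rotamer positions of the paramagnetic label (EDTA-Mn²⁺
labels populate three rotamers; weights are uniform by default and labels
from separate dockings are pooled equally). Per-structure rates are capped at
90 s⁻¹ — beyond that both measured and computed values are dominated by tiny
distance fluctuations. Fast exchange makes the observable the
population-weighted ensemble mean ⟨Γ₂(i)⟩ = Σⱼ Γ_ji / N_st. Profiles are
normalized to their maximum before comparison; values flagged saturated
(> 60 s⁻¹) sit at the normalized level 1.0. The Pearson comparison against
an experimental table clips saturated points to 1.0 and keeps them by
default; an exclude-saturated policy is selectable (whether saturated points
enter published correlation coefficients is not specified anywhere we could
follow, so both policies ship).

Amide protons are built geometrically when absent: 1.01 Å from N along the
external bisector of the C(prev)–N–CA angle, in that plane; chain starts and
prolines are skipped, and an explicit H atom always wins over the builder.

Note an intentional unit firewall: `two_state_average` takes *rates* as
inputs and never invokes C. The classic two-state illustration (a 1% minor
species at 8 Å versus a major species with Γ₂ ≈ 2 s⁻¹ at 30 Å giving a ~30-fold
apparent enhancement) assumes a correlation time for which Γ₂(30 Å) = 2 s⁻¹,
whereas C = 1.2 × 10¹⁰ Å⁶/s gives 16.5 s⁻¹ at 30 Å. The two parameterizations
coexist; we document rather than reconcile them, and `rate_at_distance`
performs reference-rate r⁻⁶ scaling without C.

## Exponential-map landscape coordinates

Contacting poses form a 5-D manifold: the approach direction (two angles)
and the ligand orientation (three), with the contact distance r determined by
the touching condition. Euler-style charts suffer gimbal lock, so both
factors use exponential maps, giving independent Euclidean coordinates
(σ₁, σ₂, ω₁, ω₂, ω₃) with the native pose at the origin:

* σ = (−φ sin θ, φ cos θ), where θ, φ are the longitude and colatitude of
  the vector from the receptor center to the posed ligand interface center,
  in the landscape frame;
* ω is the principal-branch axis-angle vector (rotation-group logarithm) of
  the pose rotation relative to the native one, expressed in frame axes.
  Rotations at exactly π sit on the branch cut and raise an error; the
  sampled region (22.5° radius) never approaches it.

**Frame convention.** Origin at the receptor center; z toward the native
interface center. The in-plane x axis is fixed by a structure-intrinsic
reference — the first receptor atom direction orthogonalized against z —
rather than a lab axis, so the frame co-rotates with the complex: rigidly
moving the whole system leaves every pose's coordinates unchanged (verified
to 1e-8), and eigenvectors are reproducible run to run.

**Contact distance.** The smallest r along the approach direction at which
no heavy-atom pair is closer than 0.9 × the sum of radii (the same overlap
tolerance spirit as the smooth potential) while the critical pair touches.
We solve the per-pair quadratics along the ray in closed form — equivalent
to bracketing/bisection but exact; the tests verify agreement with an
independent bisection oracle to 0.01 Å.

**Sampling and PCA.** The near-native region is a 5-D ball of angular radius
22.5° (≈ a 10 Å IRMSD neighborhood for small proteins); samples beyond 10 Å
IRMSD are discarded. Coordinates are then *balanced* — each column divided
by its sample standard deviation (computed after the IRMSD filter) — and the
lowest-energy fraction (default 5%) enters PCA of the mean-centered
covariance. Eigenvalues are reported in percent of their sum; v₁, v₂ span
the permissive subspace, v₄, v₅ the restrictive one. When selecting a
spatially uniform subset from docked poses the package uses greedy
farthest-point subsampling (the exact historical selection rule is
unpublished; in synthetic mode an exactly uniform ball sample is generated
directly through the exponential maps and the contact condition instead, and
scored with the continuous energy).

## Subspace statistics

Principal angles between subspaces are the arccosines of the singular values
of the basis inner-product matrix. The scalar "angle between two subspaces"
is ambiguous, and the choice matters for the Monte Carlo calibration:

* `largest` principal angle (Grassmann ∞-distance) — the default for
  pairwise discrepancy tables;
* `smallest` principal angle;
* `axis_to_plane` — the angle between the most restrictive axis (v₅) of one
  sample and the restrictive plane of the other.

Under the rotation-invariant null (two independent 100-point isotropic 5-D
samples; PCA eigenvector matrices are then Haar-distributed, so the
restrictive planes are uniform on the Grassmannian), the probability of an
angle below 30° is ≈ 0.005 for `largest`, ≈ 0.435 for `smallest`, and
exactly sin³30° = 0.125 for `axis_to_plane` (the squared cosine of a random
axis against a random 2-plane in 5-D is Beta(1, 3/2)). Only the third
definition is consistent with the reference chance-agreement probability of
≈ 0.13 used to calibrate benchmark-level significance, so it is the default
for the agreement null; the package's Monte Carlo estimate at 1000
replicates reproduces it within sampling error.

The smallest-eigenvalue null draws 100 isotropic 5-D vectors per replicate
and asks how often the smallest normalized eigenvalue falls below 10%:
≈ 0.002–0.005, i.e. observed restrictive eigenvalues are not undersampling
artifacts. Agreement across a benchmark of n complexes is combined with the
exact binomial upper tail, accumulated in log space so probabilities at the
1e-28 scale remain representable (P(≥ 37 of 42 at p = 0.131) ≈ 9.4 × 10⁻²⁸).

Monte Carlo nulls use i.i.d. standard-normal coordinates: only rotation
invariance matters, since eigenvalue normalization removes isotropic scale.

## The synthetic toy complex

`make_toy_complex` generates, deterministically per seed, two pseudo-globular
chains of N/CA/C pseudo-residues (spherical-spiral Cα traces with backbone
atoms placed at standard bond lengths, tilted so the amide-proton
construction is well defined) facing each other along z with one van der
Waals contact gap. Receptor residues on the facing cap carry charge +1.0 e
and ligand cap residues −1.0 e, planting a charge-complementary energy
minimum at the generated (native) placement that end-to-end docking
recovers; the same patch atoms carry the apolar pair type. Default sizes
(24/12 residues, 72/36 atoms, receptor radius 5 Å) are chosen so the docking
grid at 1.0 Å spacing is ≈ 32³ and a 500-rotation scan runs in seconds.

What the toy emulates: shape-complementary contact, a planted funnel,
per-residue Cα/amide machinery, realistic radii. What it does not: side
chains, real electrostatics or desolvation statistics, protein-scale
dimensions (its ~15 Å extent means PRE rates computed with the physical C
saturate across the whole toy — by design the PRE tests therefore exercise
closed-form mixtures and per-structure gradients, not realistic profile
shapes), and conformational change. Passing tests demonstrate the
machinery's correctness, not predictive accuracy on real complexes.

## Numerical choices and problem sizes

* FFT scans use complex FFTs over the full grid; circular translations are
  masked to non-wrapping placements at retention time.
* Pose/coordinate round-trips hold to 1e-8 over 1000 draws; FFT/brute-force
  agreement to 1e-6 relative (observed ~1e-15); superposition uses Kabsch
  SVD with an explicit collinearity guard (second singular value < 1e-8 ×
  first).
* Sample statistics use ddof = 1; balancing refuses zero-variance columns by
  name.
* Test and desk-profile problem sizes — 500 rotations, ≈ 32³ grids, 200
  retained poses, 1000–1500 landscape samples, 1000 Monte Carlo replicates —
  are the package's chosen desk scale: large enough for every statistical
  check to resolve its target, small enough to iterate quickly. Production
  scale (70,000 rotations, 10,000 poses per label rotamer) is exposed as the
  `production_profile` configuration and exercises identical code paths.

## Known limitations

* Rigid-body only: no side-chain repacking, minimization, or flexibility.
* The attractive/repulsive channel forms are simple square wells; published
  grid potentials of this family use calibrated shells and a trained contact
  matrix, so absolute energies are not comparable across programs (the pair
  matrix is a pluggable TSV input).
* PRE uses the single-constant Solomon–Bloembergen prefactor C; no explicit
  correlation-time spectral densities, titration-series concentration
  dependence, or population fitting.
* mmCIF assemblies, symmetry expansion, nucleic acids and missing-loop
  modeling are out of scope; altloc resolution keeps the highest-occupancy
  conformer only.
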