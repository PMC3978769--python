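# encounterdock

Tools for studying **protein–protein encounter complexes** — the transient,
lowly populated intermediates through which two proteins find their specific
binding mode. The package implements three connected pieces of machinery:

1. **FFT correlation docking.** Exhaustive rigid-body sampling of the mutual
   orientations of a receptor and a ligand: a deterministic quasi-uniform set
   of rotations, and for each rotation a full translational scan on a 1.0 Å
   grid evaluated as a handful of FFT correlations. The smooth score

       E = E_attr + w₁·E_rep + w₂·E_elec + w₃·E_pair   (w₁, w₂, w₃ = 4, 600, 5)

   combines square-well van der Waals terms with a finite repulsive core
   (moderate overlap is tolerated), screened electrostatics
   qᵢqⱼ/√(r² + D²e^(−r²/4D²)), and a pairwise contact potential entered
   through its eigendecomposition. Low-energy poses are retained per rotation
   and clustered at 10 Å interface RMSD (IRMSD).

2. **PRE back-calculation.** The ensemble of low-energy docked structures
   predicts transverse paramagnetic relaxation enhancement rates of receptor
   amide protons: Γ_ji = C·Σₖ r_ikj⁻⁶ with C = 1.2 × 10¹⁰ Å⁶/s, summed over
   spin-label rotamers, capped at 90 s⁻¹, and averaged over the ensemble in
   the fast-exchange limit, ⟨Γ₂(i)⟩ = Σⱼ Γ_ji / N_st. Because Γ₂ scales as
   r⁻⁶, even a 1% minor species in close contact dominates the observed rate,
   which is what makes PRE a sensitive probe of encounter states.

3. **Energy-landscape PCA.** Poses in contact form a 5-D manifold
   parameterized by exponential maps — sphere-tangent coordinates (σ₁, σ₂)
   for the approach direction and the rotation-group logarithm (ω₁, ω₂, ω₃)
   for the orientation — with the native pose at the origin and the contact
   distance r fixed by the touching condition. After variance balancing, PCA
   of the lowest-energy near-native sample splits the coordinates into a
   *permissive* subspace (v₁, v₂: directions encounter complexes explore
   freely) and a *restrictive* subspace (v₄, v₅: directions the funnel pins
   down). Monte Carlo null models and an exact log-space binomial tail
   quantify when small eigenvalues and cross-method subspace agreement are
   significant.

Everything runs end to end on a bundled synthetic toy complex with a planted
charge-complementary interface, so the full pipeline is testable in seconds
without downloads. See `docs/methods.md` for models, parameters and design
choices.

## Worked example

```python
import numpy as np
from encounterdock import (make_toy_complex, generate_rotations, dock,
                           EnergyWeights, default_pair_potential,
                           cluster_poses, compute_irmsd,
                           rate_at_distance, two_state_average)

# two-state fast-exchange example
gamma_b = rate_at_distance(2.0, 30.0, 8.0)
apparent = two_state_average(0.99, 2.0, 0.01, gamma_b)
print(f"Gamma2,B(8 A) = {gamma_b:.1f} /s")
print(f"apparent Gamma2 = {apparent:.1f} /s ({apparent / 2.0:.1f}-fold)")

# end-to-end toy docking
native = make_toy_complex(seed=7)
poses = dock(native.receptor, native.ligand, generate_rotations(500),
             EnergyWeights(), default_pair_potential())
poses.sort(key=lambda p: p.energy)
top = poses[:200]
clusters = cluster_poses(top, native)
center = top[clusters[0].center]
print(f"{len(top)} poses -> {len(clusters)} cluster(s); "
      f"top center: E = {center.energy:.1f}, "
      f"IRMSD = {compute_irmsd(center, native):.2f} A")
```

prints

```
Gamma2,B(8 A) = 5561.8 /s
apparent Gamma2 = 57.6 /s (28.8-fold)
200 poses -> 1 cluster(s); top center: E = -3751.6, IRMSD = 6.65 A
```

The first two lines are the fast-exchange arithmetic: a minor species
populated at only 1% but in close contact (8 Å) raises the apparent PRE rate
about 30-fold over the major species alone — the footprint by which encounter
complexes are detected. The docking lines show the 500-rotation scan
recovering the toy's planted interface: all 200 retained low-energy poses
fall in a single cluster whose center sits 6.65 Å IRMSD from the generated
native pose, within the toy's interface diameter.

A command-line interface mirrors the library
(`encounterdock dock|pre|landscape|nulls|fixtures|run|validate`); the `run`
subcommand executes the full synthetic pipeline and writes pose tables, PRE
profiles and the landscape PCA report, and `validate` runs the Monte Carlo
null models, the binomial combination and a planted-subspace recovery check.

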