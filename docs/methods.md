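# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `epiflex`. Values quoted here are defaults; everything
is overridable through the API or CLI.

## Simulated B-factors

**Model.** The B-factor (temperature factor) of an atom is
B = 8π²⟨u²⟩, with u the displacement of the atom from its mean position.
Computed from a conformational ensemble instead of crystallographic
refinement, it measures local mobility free of lattice disorder and
refinement error. Two conventions coexist and differ by a factor of 3:

- `peraxis` (default): B = (8π²/3)·⟨|Δr|²⟩, the crystallographic
  convention implemented by PTRAJ/CPPTRAJ `atomicfluct`. For isotropic
  Gaussian displacements with per-coordinate SD σ, B = 8π²σ²
  (σ = 0.30 Å ⇒ B ≈ 7.1 Å²).
- `total`: B = 8π²·⟨|Δr|²⟩, the literal 3-D reading.

Reported values in the Å-squared range of folded proteins (~5–15 Å²)
presume the per-axis convention; the switch exists because published
descriptions often quote the total formula while tools compute per-axis.

**Superposition protocol.** Internal motion must be separated from global
rigid-body motion before fluctuations mean anything. The pipeline uses the
standard two-step fit: (1) every frame, pooled across all replicas, is
superposed (unweighted Kabsch on all Cα atoms; reflections excluded) onto
the first saved conformation, and the fitted coordinates are averaged
arithmetically into an average conformation; (2) every original frame is
superposed onto that average. Exactly two passes, no iteration; the output
pose is anchored to the first saved conformation. Pooling (rather than one
average per replica) makes all replicas commensurable; the alternative was
considered and rejected because per-replica references would let slow
between-replica drift contaminate the per-residue fluctuations
differently in each replica.

**Replica statistics.** Within each replica, fluctuations are taken about
that replica's own mean position (switchable to the pooled mean via
`fluctuation_reference`); between-replica drift therefore inflates the SE,
not B. The reported per-residue value is the mean over the R replicas; its
standard error is the sample SD across replicas divided by √R (the
standard replica-ensemble estimator), and confidence intervals are
mean ± z·SE with z = 1.96, the large-sample normal quantile (no
small-sample t correction by default; the intended sample sizes exceed
100). Loop- and chain-level averages propagate error as
SE = √(Σ SEᵢ²)/n. Reports round to 0.1 Å²; internal math is full
precision.

**Small-sample correction.** Superposing each frame onto a common
reference absorbs the 6 rigid-body components of the fluctuation field —
a deterministic deflation of the mean-square fluctuation by ≈ 2/N for an
N-residue chain — and taking fluctuations about the sample mean removes
another 1/F. Both are negligible for long trajectories of large proteins
but visible for statistically independent frames: at N = 230, F = 500 the
combined ~1% deflation exceeds the replica SE. By default each replica's
raw MSF is therefore rescaled by 3N/(3N−6) · F/(F−1), which is exact for
homogeneous isotropic fluctuations and approximate otherwise (the absorbed
rotational variance actually distributes non-uniformly with lever arm, so
a small per-residue residual of either sign remains — see Limitations).
`small_sample_correction=False` reproduces raw `atomicfluct` semantics
bit-for-bit.

## Antigenicity scoring

A surface loop is called *potentially antigenic* when its mean Cα B
strictly exceeds a cutoff, default 9.00 Å² — a conservative threshold
roughly 2 Å² above whole-protein means of ~7 Å², consistent with the
empirical link between high main-chain B-factors and antigenicity. Ties at
the cutoff are non-antigenic (strict `>`). Loop membership is resolved in
crystal numbering with insertion-code expansion (36–38C includes 38, 38A,
38B, 38C), since that is the scheme loop tables are printed in. Variant
comparison reports per-loop deltas and flags disjoint 95% CIs as
significant; no additional hypothesis test is performed.

The packaged default loop table holds the twelve PR3 surface loops
(epitopes 1/3/4/5) in both crystal and sequential (NCBI P24158.3)
numbering. The two schemes are printed inconsistently for some loops in
the source material (e.g. a 14-residue crystal range against a 5-residue
sequential range for L5A); the table records both as printed and treats
crystal numbering as authoritative. The packaged per-residue numbering
map therefore covers only the loops whose spans agree after
insertion-code expansion (L1C, L3A, L3B, L3C, L4A, L4B, L5C); queries
outside it raise a lookup error rather than guessing.

## Conformational clustering

Frames are compared by *pairwise fitted* CαRMSD — each pair superposed
independently, matching standard cluster-analysis practice — and grouped
by average-linkage agglomeration: merging proceeds while the minimum
average between-cluster distance does not exceed ε (default 3.0 Å, the
CPPTRAJ `epsilon` semantics). This equals cutting the average-linkage
dendrogram at height ε, which is how it is computed (scipy hierarchy on
the condensed matrix); an independent naive merge-loop oracle verifies the
equivalence in the test suite. Cluster ids are assigned by order of first
frame occurrence and ties for the most populated cluster break to the
lowest id, so results are bit-for-bit reproducible. A cluster's
representative is the arithmetic mean of its superposed member frames
(time-averaged conformation, no energy minimisation). The exact O(F²)
matrix path is intended for ≤ ~5,000 frames; the CLI exposes `--stride`
for longer trajectories.

Comparisons of a representative to a reference structure run over the
residues common to both (matched by chain, crystal number, insertion
code), so chains of slightly different length (16–238 vs 16–239) compare
cleanly.

## Synthetic ensembles

The generator emulates the statistical structure of short, replicated
equilibrium simulations of a folded protein, not their physics: each frame
is an idealised Cα chain (helical or extended trace, consecutive Cα–Cα
distances 3.8 Å) plus independent isotropic Gaussian displacements per
residue, optionally composed with an arbitrary per-frame rigid motion
(uniform random rotation; translation uniform in ±20 Å) that the fitting
stage must remove. Ground truth is exact: B_true = 8π²σᵢ². Noise and
rigid motions come from independent child streams of one seed, so the
same seed yields bit-identical ensembles and toggling rigid motion does
not change the noise draws.

Default study conditions, chosen once to mirror a PR3-like antigen at
desk scale: 230 residues, 20 replicas × 500 frames, baseline B = 5.5 Å²,
the twelve loops elevated to 9.5–13 Å² (straddling the 9.00 Å² cutoff),
giving whole-chain means of ~7 Å². Three variant patterns differ only in
the two mobility-switching loops: L3B at 6.9 Å² (latent) or 12.8 Å²
(activated) and L5B at 8.5/9.6 Å², producing 10, 11 and 11 antigenic
loops for the PR3-, iPR3- and iHm5-like patterns respectively.

Two-state ensembles for clustering draw each frame from the reference or
from a copy with an interior region displaced along +x (default test
conditions: residues 13–18 of a 30-mer displaced 25 Å, whose *fitted*
Cα separation is ≈ 10 Å — rigid-body fitting absorbs much of a raw
displacement, and a terminal-region displacement would be absorbed almost
entirely), plus the usual noise. True state labels are returned for
verification.

What the generator deliberately omits — and hence what passing tests do
*not* establish about real data: temporal autocorrelation (MD frames are
correlated; effective sample sizes are smaller and SEs wider than the
iid case), anisotropic and correlated inter-residue motions, multi-well
landscapes beyond the two-state toy, and solvent/forcefield physics. The
pipeline consumes real trajectories through the same interfaces when they
are available.

## Numerical and I/O choices

- Kabsch via SVD with determinant correction; degenerate (collinear)
  inputs raise instead of returning an arbitrary rotation. Batched
  covariance/SVD paths make 10⁴-frame fits interactive; the pairwise
  matrix uses the singular-value identity rmsd² = (E₀ − 2D)/N, accurate
  to ~10⁻⁷ Å for near-identical frames.
- PDB reading (Biopython, strict mode) keeps Cα atoms only, prefers
  altloc `' '` then `'A'`, skips residues lacking a Cα with a warning,
  and reports malformed records with their line number. Multi-model PDB
  is the normative trajectory dialect; DCD/NetCDF load via mdtraj behind
  the same contract.
- B-factor columns write to 2 decimals, clamped at 999.99 (PDB fixed
  width) with a warning; coordinates to 3 decimals.
- CLI outputs carry a provenance header (version, config hash, seed) and
  are byte-identical across reruns; error classes map to distinct
  non-zero exit codes.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` runs the three variant profiles at the full study
conditions (230 residues × 20 replicas × 500 frames), parameter recovery
on truth spanning 5–15 Å² at the same size, rigid-motion invariance at
60 × 3 × 50, 30 random superposition toys against the grid-search oracle,
30 small clustering toys against the naive agglomeration oracle, a
200-frame two-state mixture at w = 0.7, and the SE-scaling regression
over R ∈ {4, 8, 16, 32} with three generations averaged per R.

## Known limitations

- The dof correction is uniform per replica; its per-residue residual
  (geometry-dependent, ≲ 0.5% at N ≥ 100) means truth coverage of the
  95% CI hovers a few points below nominal for perfectly iid synthetic
  data. For real (autocorrelated) trajectories the replica SE dominates
  and the residual is irrelevant.
- The z = 1.96 interval slightly under-covers for small R (t₁₉'s 97.5%
  point is 2.09); kept for protocol fidelity.
- Average-linkage semantics differ at exact ties from naive sequential
  merging only in pathological equal-distance cases; random-geometry
  inputs never produce them.
- The antigenicity cutoff is a heuristic on mobility, not a binding
  predictor: scoring says a loop is mobile enough to be antibody-adaptable,
  not that an antibody exists for it.
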