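# Methods

This document specifies the model implemented by `ecdyn`, every tunable
parameter with its units, default, and rationale, the design of the synthetic
validator, numerical choices, and known limitations. Nothing here makes an
empirical claim that is not computed by the test suite or by
`scripts/acceptance.py`.

## 1. Essential collective dynamics

### 1.1 Segmentation

A trajectory of *T* frames is cut into `n_segments` contiguous,
non-overlapping windows of `segment_length` frames. If
`n_segments × segment_length < T`, the `take` policy selects which frames to
keep: `"tail"` (default) keeps the last frames, `"head"` the first, `"all"`
requires an exact partition. Segments are treated as independent replicas;
all ensemble statistics (mean image distances, flexibility mean/SD) are taken
across segments.

Defaults: `n_segments=100`, `segment_length=None` (auto: `T // n_segments`,
must be ≥ 2 frames). For the synthetic studies in the tests and the
acceptance script, the frozen protocol is **50 segments × 40 frames, tail**,
chosen once at design time so each segment holds enough frames (40 ≥ 3N/10
for the default systems) for a stable covariance while 50 replicas give a
low-noise average.

### 1.2 Superposition

Each segment's frames are least-squares superposed onto the segment's first
frame with the Kabsch algorithm (`superpose=True` default), removing global
rotation and translation so the covariance captures internal motion only.
RMSD after superposition of rigidly transformed copies is exactly zero up to
round-off (verified to ≤ 1e-8 in the tests). Degenerate (collinear)
references are rejected.

### 1.3 Essential space and atom images

For each segment, the 3N×3N Cartesian covariance C of the selected atoms
(default selection `"name CA"`) is computed with the population estimator
(ddof = 0) and diagonalized with `numpy.linalg.eigh`. The essential dimension
*m* is the smallest number of leading eigenvectors whose cumulative
eigenvalue sum reaches `fraction` of the trace (default **0.90**); `fixed_m`
overrides it. The image of atom *i* is the m-vector of unsigned per-atom
mode amplitudes, ξᵢₖ = ‖(vᵏ₃ᵢ, vᵏ₃ᵢ₊₁, vᵏ₃ᵢ₊₂)‖. Images are dimensionless
(eigenvectors are unit-normalized); optional `mode_weighting="sqrt_eigenvalue"`
rescales component *k* by √(λₖ/λ₁), emphasizing dominant modes, and is off by
default so the default images depend only on mode shapes, not amplitudes.

Unsigned amplitudes discard the relative phase of the motion: two atom groups
moving in anti-phase with *equal* amplitude produce identical images. The
analysis therefore resolves domains by amplitude structure, not phase (see
limitations, §5).

### 1.4 Correlation map, flexibility, domains

- **Correlation map**: d_ij = ‖ξᵢ − ξⱼ‖ per segment, averaged over segments.
  Dimensionless; symmetric with zero diagonal and satisfies the triangle
  inequality per segment (metric properties verified on random image sets).
- **Flexibility**: F_i = ‖ξᵢ − ξ̄‖ with ξ̄ the centroid of all atom images in
  the segment; reported as mean and SD across segments. Identities: F ≡ 0
  for coincident images; for two atoms, F = half the pair distance.
- **Dynamic domains**: single-linkage connected components of the relation
  d_ij ≤ d_c. Components smaller than `min_domain_size` (default **3** atoms,
  so a domain is more than an incidental pair) are reported as unassigned
  (label −1). Domain count is monotone non-increasing in d_c.

Default `d_c` = **0.0015** (dimensionless image distance) when a threshold is
given explicitly to `cluster_domains`. The pipeline instead selects d_c
automatically (`select_threshold`): candidate thresholds are the 40 quantiles
(2%–98%) of the positive pair distances — a scale-free grid, since image
distances shrink roughly as 1/√N with system size — and the choice maximizes
(number of domains, then atoms outside the largest domain), restricted to
partitions whose largest domain holds > 10% of the atoms (rejecting
shattered partitions). Diagnostics for every candidate are returned and
written to `domains.json`.

### 1.5 B-factor comparison

Crystallographic B-factors (Å²) are extracted per residue (`CA-only` default,
or `backbone-mean` over N/CA/C) and flexibility profiles are normalized onto
the reference by `minmax` (default; affine map onto the reference range) or
`zscore` (match reference mean/SD). Both are invariant to affine rescaling of
the input profile. Agreement is reported as Pearson and Spearman correlation
over the residues common to both profiles (error if fewer than 3, or if a
profile is constant).

### 1.6 Interface contacts

For two disjoint atom selections, residue pairs are classified by minimum
heavy-atom distance with ≤-cutoffs (Å): `polar` 3.5 (N/O/S with N/O/S),
`hbond_range` 4.0 (N/O with N/O), `nonpolar` 4.5 (C with C), `neighbor` 5.0
(any heavy pair). These are conventional crystallographic interaction ranges;
no geometry (angles, protonation) is used, so `hbond_range` means
"within hydrogen-bonding distance", not a verified hydrogen bond. Hydrogens
are ignored. The most specific class is reported with all satisfied classes
listed; the implementation is verified against a brute-force O(n²) scan.

## 2. Synthetic validator

### 2.1 Model

`generate_enm_trajectory` integrates overdamped Langevin dynamics on an
isotropic harmonic network,

    γ dx = −H (x − x₀) dt + √(2 kB T γ) dW ,

with the Euler–Maruyama scheme. The Hessian H is the spring-weighted graph
Laplacian ⊗ I₃ (each spring pulls the vector difference of its endpoints
isotropically). The equilibrium law is Gaussian with covariance
**C = kB·T·H⁺** (pseudoinverse over the non-null modes), so every pipeline
quantity has an analytic oracle: `analytic_covariance`, `analytic_msf`.
`sample_equilibrium` draws i.i.d. frames from this law exactly.

Units: kcal/mol/Å² for spring constants, Kelvin for temperature,
kB = 0.0019872 kcal/(mol·K), friction γ in (kcal/mol/Å²)·time, so distances
come out in Å. Time units are arbitrary (only the product dt/γ matters).

Parameters (ENMSpec): `temperature` (default 310 K, physiological),
`friction=1.0`, `dt` (must satisfy the stability bound dt·λmax/γ < 2,
enforced at construction), `stride` (frames kept every `stride` steps),
`initial="equilibrium"` (start from an exact equilibrium draw, so no burn-in
is needed; `"native"` starts at x₀ and discards a burn-in).

### 2.2 Block systems

`make_block_system` builds a multi-domain test system: `n_blocks` internally
stiff atom clusters connected by soft hinge chains. Defaults:
`atoms_per_block=14`, `size_step=12` (block *b* has 14+12·b atoms),
`hinge_atoms=4` per hinge, `stiff_k=5.0`, `soft_k=0.5`,
`stiffness_contrast=2.0` (block *b* uses stiff_k·2ᵇ), `bridge_k=0.5` (one
direct inter-block spring), `block_spacing=16 Å`, `block_radius=3 Å` with a
per-block radius increment, `temperature=310`, `n_frames=2000`, `stride=20`,
dt set automatically to 0.2·γ/λmax.

The asymmetries are deliberate and load-bearing. Because atom images are
unsigned (§1.3), two *identical* blocks moving in anti-phase have equal modal
amplitudes and hence coincident images — a perfectly symmetric system is
mathematically unrecoverable by this method. Breaking the symmetry in size
(relative-motion modes give per-atom amplitudes scaling like the opposite
block's size), radius, and stiffness (ascending, so the small soft block is
the mobile "lid") gives each block a distinct amplitude signature. The bridge
spring keeps the hinge the softest element, so hinge atoms have the highest
analytic mean-square fluctuation (verified in the tests). These defaults were
fixed at design time and define the study systems used by the acceptance
criteria; with `size_step=0, stiffness_contrast=1` the factory also produces
fully symmetric systems for counting/geometry tests.

### 2.3 What the generator does and does not emulate

Emulates: Gaussian equilibrium fluctuations about a single minimum,
time-correlated overdamped dynamics, multi-domain amplitude structure,
hinge softness, rigid-body null modes (translations; rotations too in the
anisotropic Hessian variant used only for analysis of null-space structure).

Does not emulate: anharmonicity, conformational transitions between minima,
solvent structure, inertial dynamics (no mass term), side chains, or global
tumbling (frames are generated without rotation; the pipeline's robustness to
tumbling is tested by applying random rigid transforms afterwards).

## 3. Numerical choices

- Eigendecomposition via `numpy.linalg.eigh` (LAPACK); verified against an
  independent cyclic Jacobi implementation to 1e-8 on random PSD matrices.
- Covariance uses the population (ddof=0) estimator, matching the analytic
  oracle's definition.
- Single-linkage clustering runs on the condensed distance matrix via
  `scipy.cluster.hierarchy`; verified against a boolean transitive-closure
  oracle.
- Langevin integration is vectorized Euler–Maruyama; the construction-time
  stability check rejects dt·λmax/γ ≥ 2 (exit code 2 from the CLI).
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces trajectories and analysis artifacts byte-for-byte.
- TSV artifacts are written with fixed column orders and 8-significant-digit
  floats so reruns are byte-identical.

## 4. Reported quantities

`scripts/acceptance.py --seed S --out F` regenerates, for the default two-
and three-block systems over five seeds derived from S: the domain-recovery
Adjusted Rand Index (unassigned atoms counted as singleton labels — a
dissolved block is penalized, never rewarded — and hinge atoms excluded since
they carry no block identity), the Spearman correlation between mean
flexibility and analytic mean-square fluctuation, the mean essential
dimension and captured variance fraction per segment, the recovered domain
count, and the Frobenius relative error between a 5000-frame sampled
covariance and the analytic covariance of a three-atom chain.

## 5. Limitations

- **Phase blindness.** Unsigned images cannot distinguish anti-phase from
  in-phase motion of groups with equal amplitude; perfectly symmetric
  two-domain systems are unresolvable in principle (§2.2). Real proteins are
  asymmetric, but near-symmetric assemblies (e.g. homodimers) may merge.
- Small blocks adjacent to much softer hinges can fall below the selected
  threshold's linkage and be reported unassigned rather than as a separate
  domain; the acceptance results for the three-block system reflect this
  (ARI 0.934 with the smallest block unassigned, not mislabeled).
- The flexibility descriptor ranks mobility within the essential subspace; it
  correlates with, but does not equal, mean-square fluctuation (Spearman,
  not Pearson, is the appropriate comparison).
- Segments are assumed long enough for a meaningful covariance; with
  `segment_length` ≪ 3N the essential space is rank-deficient and images are
  noisy. No automatic correction is applied beyond the fail-fast check
  `segment_length ≥ 2`.
- The contact classifier is distance-only (§1.6).
- The threshold selector assumes at least two genuine domains; on a truly
  single-domain system it returns the degenerate single-cluster partition
  with a warning.
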