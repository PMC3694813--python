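# ecdyn — essential collective dynamics of molecular trajectories

`ecdyn` analyzes molecular-dynamics trajectories by *essential collective
dynamics*: it decomposes short trajectory segments into their dominant
collective motions, maps every atom to a point in a low-dimensional "image"
space built from those motions, and reads off dynamic couplings, per-residue
flexibility, and rigid dynamic domains from distances between atom images.
It also ships an exactly solvable elastic-network trajectory generator used
to validate every stage of the pipeline against analytic ground truth.

## The scientific problem

A protein's function is often carried by a few collective degrees of freedom
— domains swinging about hinges, a lid closing over a binding pocket — that
are hard to see in raw Cartesian trajectories. Two atoms far apart in space
may move as one rigid body; two neighbors may belong to different bodies.
The questions this package answers from a trajectory alone are:

1. Which groups of atoms move as coherent **dynamic domains**, and where are
   the hinges between them?
2. How **flexible** is each residue within the dominant collective motions,
   and does that profile agree with crystallographic B-factors?
3. Which residue pairs form the physical **contact interface** between two
   chains, so that dynamic couplings can be compared with structural contacts?

## Core model

For each trajectory segment *s* (a contiguous window of frames), build the
Cartesian fluctuation covariance of the selected *N* atoms after removing
rigid-body motion by least-squares superposition:

    C = ⟨ (x − ⟨x⟩)(x − ⟨x⟩)ᵀ ⟩            C ∈ ℝ^{3N×3N}

Diagonalize C and keep the smallest number *m* of top eigenvectors
v¹, …, vᵐ whose eigenvalues reach a fraction *f* (default 0.90) of the total
variance — the *essential space* of the segment. Each eigenvector assigns
atom *i* a 3-vector vᵏᵢ; the **image** of atom *i* is the unsigned vector of
modal amplitudes

    ξᵢ = ( |v¹ᵢ|, |v²ᵢ|, …, |vᵐᵢ| ) ∈ ℝᵐ .

Atoms that participate identically in the dominant collective motions have
nearby images, so the dimensionless image distance

    d_ij = ‖ξᵢ − ξⱼ‖

measures dynamic coupling: small d_ij means atoms *i* and *j* move as part
of the same quasi-rigid unit. Averaging d_ij over many independent segments
gives a **correlation map**; single-linkage clustering of the map at a
threshold d_c yields **dynamic domains** (the threshold is chosen
automatically by scanning a quantile grid of the observed distances and
maximizing domain count, see `docs/methods.md`). The per-atom
**flexibility**

    F_i = ‖ξᵢ − ξ̄‖ ,   ξ̄ = mean image over all atoms,

reported as mean ± SD across segments, ranks residues by their mobility
within the essential space and can be normalized onto, and correlated with,
experimental B-factors.

The synthetic validator simulates overdamped Langevin dynamics on an
isotropic harmonic network (Hessian = spring-weighted graph Laplacian ⊗ I₃),
whose Gaussian equilibrium covariance kB·T·H⁺ is known in closed form — so
recovered domains, flexibility ranks, and covariance estimates can all be
checked against exact answers.

## Worked example

Simulate the bundled two-block hinge system and analyze it:

```bash
$ ecdyn simulate examples/two_block.json --outdir sim
{
  "trajectory": "sim/trajectory.pdb",
  "ground_truth": "sim/ground_truth.json",
  "spec": "sim/spec.resolved.json"
}

$ ecdyn analyze --topology sim/trajectory.pdb --n-segments 50 --segment-length 40 --outdir analysis
{
  "config": "analysis/config.resolved.json",
  "correlation_map": "analysis/correlation_map.tsv",
  "flexibility": "analysis/flexibility.tsv",
  "domains_tsv": "analysis/domains.tsv",
  "domains_json": "analysis/domains.json"
}
```

The domain report (`analysis/domains.json`) recovers the two blocks exactly,
with the four hinge atoms left unassigned:

```json
{
  "n_domains": 2,
  "largest_fraction": 0.5909090909090909,
  "n_unassigned": 4,
  "summary": [
    {"rank": 0, "size": 26, "fraction": 0.591, "ranges": ["A:15-40 (26 residues)"]},
    {"rank": 1, "size": 14, "fraction": 0.318, "ranges": ["A:1-14 (14 residues)"]}
  ]
}
```

(the generated system has a 14-atom block, a 26-atom block, and a 4-atom
hinge chain; `sim/ground_truth.json` records the true labels). The
per-residue flexibility table looks like:

```
chain  resid  resname  mean_flex   sd_flex
A      1      ALA      0.34497209  0.060988263
A      2      ALA      0.30484115  0.065515246
A      3      ALA      0.32726857  0.073908877
...
```

Other subcommands: `ecdyn flexibility` (profile + optional SVG plot),
`ecdyn domains`, `ecdyn contacts` (interface contact classification between
two atom selections), `ecdyn compare-bfactors` (normalize a flexibility
profile onto a crystallographic reference and report Pearson/Spearman
agreement). All commands accept `--help`.

The same pipeline runs from Python:

```python
import ecdyn

spec = ecdyn.make_block_system(n_blocks=2, seed=7)
traj = ecdyn.generate_enm_trajectory(spec)
ens = ecdyn.segment_trajectory(traj, n_segments=50, segment_length=40, take="tail")
sel = ecdyn.select_atoms(traj, "name CA")
cmap = ecdyn.correlation_map(ens, sel, sel)
choice = ecdyn.select_threshold(cmap.values)
domains = ecdyn.cluster_domains(cmap.values, threshold=choice["threshold"])
```

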