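# Methods

## The model

A soluble globular protein is idealized as a "fuzzy oil drop": hydrophobicity
density shaped like a 3D Gaussian, maximal at the molecular center and near
zero at the surface. For a unit of N residues, three discrete distributions
are compared, each normalized to sum to 1:

- **T (theoretical)** — the Gaussian evaluated at each residue's *effective
  atom* (the mean position of its heavy atoms), in the unit's principal
  frame:
  `T~_i = exp(-x_i²/2σx²) · exp(-y_i²/2σy²) · exp(-z_i²/2σz²)`,
  `T_i = T~_i / Σ_j T~_j`.
- **O (observed)** — hydrophobicity collected from pairwise inter-residue
  interactions. Each pair (i, j) with effective-atom distance `r_ij ≤ c`
  contributes `(H_i + H_j) · w(r_ij/c)` to residue i, where `H` is the
  intrinsic hydrophobicity of the amino-acid type and
  `w(t) = 1 − ½(7t² − 9t⁴ + 5t⁶ − t⁸)` is a smooth soft-sphere contact
  weight with `w(0) = 1`, `w(1) = 0`, and `w ≡ 0` beyond the cutoff. There
  is no self-term.
- **R (uniform)** — `1/N` per residue: no core at all.

Distances between distributions are Kullback–Leibler divergences in bits
(`0·log 0 ≡ 0`), combined into the relative distance

```
RD = D_KL(O‖T) / (D_KL(O‖T) + D_KL(O‖R))
```

RD < 0.5 means the observed distribution sits closer to the idealized core
than to featureless uniformity — the unit has a buried hydrophobic core and
a polar surface, the organization that supports solubility. RD > 0.5 marks
exposed hydrophobicity or a missing core: aggregation-prone, membrane-
compatible, or complexation-ready surfaces. RD is invariant to rigid motion
of the coordinates, to residue reordering, to positive rescaling of the
hydrophobicity scale, and to the logarithm base (the individual divergences
are reported in bits and are base-dependent).

When both divergences are exactly zero — possible only in degenerate
symmetric units where T itself is uniform — RD is defined as 0 (the unit is
trivially accordant). A unit of one residue has T = O = R = [1].

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| interaction cutoff `c` | 9.0 | Å | range of the pairwise hydrophobicity collection |
| contact cutoff | 5.0 | Å | any-heavy-atom distance defining interface and ligand-pocket membership |
| sigma rule | max abs. principal-frame coordinate / 3 | Å | puts the whole unit within 3σ of the Gaussian center |
| sigma floor | 1.0 | Å | guards near-planar or near-linear units |
| RD threshold | 0.5 | — | hydrophobic-core / no-core boundary |
| hydrophobicity scale | Kyte–Doolittle, min–max normalized to [0,1] | — | intrinsic per-type H feeding O |

The Gaussian envelope is fitted jointly with the frame: effective atoms are
centered on their mean, rotated to the principal axes of their covariance
(largest variance along x), and each axis width is the maximum absolute
coordinate along that axis divided by 3. Frame and widths must be computed
together — any fixed-frame σ rule would break rotation invariance.

**Envelope source.** A chain can be scored as an individual (`self`: the
Gaussian and the pairwise interactions are computed on the chain alone) or
as a part of its assembly (`parent`: both are computed on the enclosing
complex, restricted to the chain's residues, and renormalized). The two
readings answer different questions — "could this chain live alone in
water?" versus "does this chain fit the complex's shared core?" — and both
are first-class throughout the API and CLI.

**Restricted RD.** Subsets (interface residues, ligand pockets,
secondary-structure classes, post-elimination remainders) are scored by
restricting the full unit's raw T and O values to the subset and
renormalizing, with R = 1/|subset|. The alternative — refitting the
Gaussian on the subset — is available by scoring the subset as its own unit
with `rd_score`; restriction is the default because the question posed is
how the subset behaves inside the geometry it actually occupies.

**Greedy elimination.** Iteratively removes the residue with the largest
|O_i − T_i| on the renormalized remaining subset, recomputing deviations
after every removal (renormalization shifts them); ties break to the lowest
residue index for determinism. Stops when restricted RD drops below the
threshold or fewer than 3 residues would remain. A fixed-initial-ranking
variant is available behind `adaptive=False` for comparison.

## Structure input

Parsing is delegated to gemmi (PDB and mmCIF). The effective atom averages
all heavy atoms — backbone plus side chain — because crystal structures
rarely carry hydrogens; a side-chain-only switch exists
(`include_backbone=False`) since usage in the literature varies. Residues
with missing side-chain atoms are averaged over the atoms present (with a
warning) rather than dropped, keeping N and hence R stable. Only the first
model of multi-model entries is read; alternate locations resolve to the
highest-occupancy copy, first on ties; waters are discarded; other HETATM
entities are kept for ligand-pocket detection. Secondary structure is taken
from file header records (HELIX/SHEET or their mmCIF categories), not
recomputed. Residue ranges use author numbering with insertion codes.

## The synthetic generator

The generator produces the organization the model is about — not folded
chains. Residues are single effective atoms (written as CA-only alanines),
placed with seeded rejection sampling under a 3.5 Å spacing floor;
hydrophobicity is carried in a sidecar override table so it is controlled
independently of residue identity while the PDB stays standard-parseable.

- **micelle / inverted_micelle** — residues on concentric spherical shells
  (shell spacing ≈ the packing floor, counts ∝ shell area, so volume
  density is near-uniform), with intrinsic hydrophobicity following the
  Gaussian ideal `H(r) = exp(−4.5 (r/R)²)` — near 1 at the core, near 0 at
  the surface — or its inversion. A `contrast` knob interpolates between
  this profile and a flat 0.5; mean RD decreases monotonically with
  contrast. Defaults: 60 residues, 18 Å radius.
- **uniform** — identical hydrophobicity everywhere, uniform placement in a
  ball.
- **two_domain** — two micelle globules whose centers sit 5 radii apart,
  joined by a sparse, polar, extended linker (10% of the residues). Each
  domain is core-ordered alone; the whole chain is not — the multi-domain
  signature. The linker gap was sized so this ordering holds essentially
  always, not just on average.
- **fibril_stack** — one globule template repeated along an axis as
  separate chains: an elongated assembly with no common core.
- **planted_outliers** — ground truth for the elimination procedure: a
  slightly softened hollow-shell globule (innermost shell at 0.55 R — a
  residue at the exact Gaussian peak carries an irreducible observed
  deficit that would contaminate the ground truth) plus k surface residues
  at H = 1.0 forming a tight mutually-interacting patch protruding at
  1.3 R. The patch members keep each other's observed excess high, so all
  k removals are needed before RD recovers, and they are too far from the
  globule to inflate its residues' observed values.

What the generator does *not* emulate: backbone connectivity, side-chain
geometry, secondary structure, realistic packing anisotropy, or any
physical folding. Passing tests on these fixtures demonstrates that the
statistic and the decomposition procedures behave as designed on controlled
hydrophobicity geometry; they say nothing about agreement with any
particular deposited structure, which is what the benchmark manifest is
for.

## Benchmark harness

The packaged manifest encodes the analysis units of the published RD survey
(whole chains, two-domain splits, in-complex chains under the parent
envelope, the two-chain interface domain, and ligand/interface partitions
for hemoglobin) together with the printed reference values. `oildrop
report` scores whatever structures are present in a local cache and
tabulates computed RD, the reference, and the absolute deviation; with
`--fetch` (explicit opt-in, never implicit) missing entries are downloaded
by accession. Because the original survey does not state its
hydrophobicity scale or σ calibration, printed values are expected to be
reproduced only approximately; the qualitative orderings (domains below
the full two-domain chain, individual hemoglobin chains below the complex,
the interface domain below its dimer) are scale-independent and are the
stronger check.

## Numerical notes

- Distributions are renormalized after every restriction; Σ = 1 is
  enforced to 1e−9 in the profile invariants.
- `D_KL` raises on `p > 0` where `q = 0`; T is strictly positive so O‖T is
  always defined, and O‖R is always defined.
- If no residue pair falls within the interaction cutoff, O falls back to
  R with a warning rather than dividing by zero.
- Elimination and restricted scoring reuse the full unit's raw T/O vectors
  (restriction commutes with renormalization), so a full elimination run
  is O(N²) once plus O(N) per step.
- Problem sizes in the test suite (globules of 60–120 residues, 50–100
  seeded replicates per study) were chosen as the smallest at which the
  regime separations are stable across independent seed ranges.

## Known limitations

- The restricted-RD reading of "status without a subset" is one of two
  defensible conventions (restrict-then-renormalize vs. refit); both are
  exposed, results differ, and comparisons across publications should
  check which was used.
- Printed reference values from the survey depend on an unstated
  hydrophobicity scale; exact reproduction is not guaranteed under any
  packaged scale.
- Interface and pocket detection is purely geometric (distance cutoff); no
  buried-surface-area or energetic criterion.
- Secondary-structure classes come from deposition headers and inherit
  their inconsistencies.
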