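# Methods

This note records the model, the parameter choices, the numerical
decisions, and the limits of what the synthetic tests demonstrate.

## Elastic network model

Structures are coarse-grained to Cα nodes plus four pseudo-nodes per
complete heme group (CHA/CHB/CHC/CHD; residue names HEM/HEC/HEA/HEB are
recognised, configurable).  Heme pseudo-nodes are ordinary network members
with the same spring constant as Cα nodes and participate in scoring and in
the DSS averages.  Node order is deterministic — chains in file order,
Cα nodes in residue order, then that chain's heme nodes — because mode
vectors are indexed positionally.

The ANM Hessian uses the distance-normalised projector convention
H_ij = −(γ/d²)·outer(r_ij, r_ij) with uniform γ = 1 and a 15 Å cutoff.
The DSS is invariant to this convention (each per-residue vector is
normalised before scoring), so γ and the super-element normalisation are
fixed purely to make eigenvalues testable; the two-node analytic eigenvalue
is exactly 2γ.

Slow modes come from a dense symmetric eigendecomposition when 3N ≤ 900 and
otherwise from a shift-invert Lanczos solver (`scipy.sparse.linalg.eigsh`,
σ = −10⁻⁴ × max |H_ii|, which is safely negative-definite to factorise and
targets the smallest eigenvalues).  Exactly six eigenvalues must fall below
10⁻⁸ × the largest computed eigenvalue; any other count aborts with a
disconnected-network error, which is the dominant real-data failure mode
(fragmented chains, detached ligands).  Restricting modes to a chain drops
node components without re-normalising, so exported amplitudes remain those
of the assembly mode.

## Superposition

Pairs are placed in a common frame by a sequence-guided iterative Kabsch
fit: a global Needleman–Wunsch alignment (match 1, mismatch 0, gap −0.5 on
one-letter codes; traceback ties prefer diagonal, then up) seeds the
correspondence; twenty iterations of least-squares fitting keep seed pairs
within a linearly shrinking cutoff (8 → 4 Å); the transform with the best
TM-score over iterations wins.  TM-score is normalised by the shorter
structure's Cα count so a single symmetric scalar exists per pair; d0 is
floored at 0.5 Å.  This is a deliberate design choice for a tool whose
stated domain is homologous, structurally similar proteins — it does not
attempt sequence-independent or flexible alignment, and collapse of the
correspondence below three pairs is reported as a superposition failure
rather than patched over.  Rotation matrices from external alignment tools
can be imported from a three-row `t r1 r2 r3` text layout.

## Mode alignment and the DSS

The per-cell score is cosine(u, v) − C, clamped to −1 beyond R_c = 10 Å
when distance constraints are on (the default; a flag disables them for
non-homologous comparisons).  C defaults to 0.7 **in cosine units**
(≈ 45.6°): the score is a cosine minus a threshold bounded by 0 ≤ C ≤ 1,
so a threshold in radians would not type-check against the formula.

Match extraction is gapless by construction — with no insertions allowed,
Smith–Waterman dynamic programming reduces exactly to per-diagonal maximal
positive segments, which the greedy kernel finds in O(N²) per step via
prefix sums (numba-compiled).  The greedy rule: repeatedly take the
highest-scoring diagonal segment of unmasked cells with length ≥ 7 and
total score > 0 (ties: smallest (i₀, j₀), then shortest), mask its rows and
columns, stop at 200 matches per matrix.  "Non-overlapping" therefore means
a residue of either protein belongs to at most one match per mode-pair
matrix, which is what makes "best S_ij per residue per mode combination"
well defined downstream.  The 200-match cap is per matrix, not global.

Mode signs are arbitrary, so each mode pair is aligned twice (v and −v) and
the orientation whose best single match scores higher is kept (ties keep
+1); comparing summed match scores instead is available via
`AlignParams(sign_rule="total")`.

The top 2n matches are selected from the **global pool** across all n²
mode combinations (a per-combination quota is the other defensible reading
of the procedure; the global pool is implemented because "top 2n (best
scores)" describes one ranked list).  Selection ties break lexicographically
by (k, l, i₀, j₀).  Negative cells inside a selected positive-total match
are kept as-is, so per-residue contributions can be negative.  Uncovered
residues contribute 0.

Exact argument-order symmetry: lexicographic tie-breaking is not
transpose-equivariant when exact score ties occur (they do occur in
self-comparisons, whose (k, l) and (l, k) matrices are transposes), so
`compute_dss` canonicalises its argument order internally — by node count,
then coordinate and mode bytes — and swaps profiles and match indices back.
DSS(A, B) and DSS(B, A) are therefore bit-identical while the documented
tie rules hold within the canonical orientation.

Zero deformation vectors (a node exactly at a mode's node) score −1,
keeping S_ij bounded; the event has measure zero and is not observed on
the fixtures.

## Dataset pipeline

For each unordered pair the compared scopes are superposed, the Hessian is
built on A's transformed coordinates (modes of a rotated structure are the
rotated modes, so building after transforming keeps the fields in the
common frame), modes are restricted to chain scopes, and the DSS computed
once per pair.  Superposition failures yield flagged missing values, later
imputed at the maximum distance with a logged warning, rather than aborting
a long run.

The distance transform is d = DSS_max − DSS (affine, strictly
rank-reversing, non-negative); 1/(1+DSS) is available behind
`to_distance(..., transform="reciprocal")`.  Clustering defaults to
complete linkage (the default of the classic `hclust` interface), with
average and single available.  Newick branch lengths are
(h_parent − h_child)/2, making leaf depths half the merge height
(ultrametric for complete linkage).

The mode-count scan computes the DSS matrix for n = 2, 4, …, 20, flattens
strict upper triangles and reports the Pearson correlation between
successive n, each row labelled by the larger n.  The correlation input is
the upper-triangle entry vector; zero-variance vectors are flagged NaN.
Superposition and modes are computed once per pair at the largest n and
sliced, which is exactly equivalent because mode identity does not depend
on how many are kept.  The reference map takes the arithmetic mean DSS of
every entry against two reference label sets, excluding self-pairs.

## Synthetic testbed

The generator produces canonical α-helical Cα traces (rise 1.5 Å, twist
100°, radius 2.3 Å, ~3.8 Å Cα–Cα), anti-parallel bundles on a packing
circle, rigid multimers, seeded Gaussian perturbations and planar heme
quadrilaterals.  The two-family clustering testbed uses six perturbed
copies of a 3 × 12-residue monomeric bundle against six chains of the same
bundle dimerised at 18 Å spacing, with σ = 0.3 Å coordinate noise — small
enough to represent crystal-form variability among near-identical
structures, large enough to break the bundle's symmetry degeneracies.
Problem sizes throughout the tests (30–300 nodes, 6–12-entry datasets, 12
modes) are chosen so the full pipeline is exercised end to end at desk
scale.

What these fixtures do **not** emulate: real side-chain packing, sequence
divergence (all fixtures are poly-ALA, so the superposition seed alignment
is identity-dominated), flexible or multi-domain motion, and experimental
coordinate error structure.  Passing tests demonstrate the algorithmic
contracts — exact scoring, greedy-extraction optimality, invariances,
planted-structure recovery — not biological clustering accuracy on real
families, which additionally depends on dataset curation and assembly
assignment.

## Known limitations

- Superposition requires recognisable sequence similarity to seed; for
  remote homologues import an external alignment matrix instead.
- Biological units are the caller's responsibility: the tool applies
  user-supplied assembly transforms but does not fetch or infer them.
- Near-degenerate slow modes mix freely between perturbed copies of
  symmetric structures; the all-pairs mode matching absorbs most but not
  all of this, slightly depressing within-family DSS for symmetric folds.
- DSS values are comparable within a parameter setting (C, R_c, n,
  min_len) but have no absolute scale across settings.
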