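# Methods

This note records the model, the numerical choices, and the design
decisions behind `morphpro`, in the package's own words.

## Model and procedure

A protein conformation is reduced to its C-alpha trace: an ordered
`(n, 3)` coordinate matrix with per-residue identity. Morphing between two
conformations proceeds in three stages.

**Preprocessing.** If the two inputs differ in length, their sequences are
aligned globally (Needleman–Wunsch; BLOSUM62, gap open −10, gap extend −1)
and both traces are restricted to the aligned positions. Restriction can
juxtapose residues that were not consecutive in the original start
structure; such positions are flagged (`broken_edge` per bond,
`broken_angle` per vertex, termini always flagged) and their bond/angle
windows are treated as free downstream — no physical virtual bond exists
there. Discontinuity is judged from the *start* structure only (chain id,
residue numbering, and original adjacency); the end structure's numbering
does not set flags. The end structure is then superposed onto the start by
the Kabsch algorithm (SVD with reflection correction), once, before
morphing.

**Iteration.** With `C_0` the (aligned, superposed) start and `E` the end,
step `k` of `K` forms the interpolation target
`T_k = (1 − α_k)·C_{k−1} + α_k·E` with `α_k = 1/(K − k + 2)`, then sets
`C_k = Proteinize(T_k)`. This "remaining-gap" schedule spaces the targets
evenly and makes the final corrected frame land adjacent to the end
structure. The exact step rule of the original description is not fully
specified, so the schedule is a reconstruction; the alternative reading —
fixed `α_k = k/(K+1)` applied to the original endpoints — is available as
`MorphConfig(schedule="fixed")`.

**Correction (Proteinize).** Around each target point a local cubic
lattice of candidate positions is built; a dynamic program selects one
vertex per lattice so that the resulting sequence is protein-like:
consecutive distances in `[a − ε, a + ε]` (a = 3.8 Å, ε = 0.1 Å), interior
pseudo-bond angles in `[70°, 120°]`, and no non-consecutive pair closer
than z = 2.0 Å. The objective is the summed squared displacement from the
targets, plus a steric penalty term (below). *cis*-proline bonds (~2.9 Å)
violate the equidistance premise and are out of scope.

## Scores and the three strategies

- `EScore(u, w)` = 0 iff `d(u, w) ∈ [3.7, 3.9]` Å (or the edge is flagged
  broken), else ∞.
- `AScore(p1, p2, p3)` = 0 iff the vertex angle at `p2` is in
  `[70°, 120°]` (or flagged), else ∞. The defining text describes the
  "minor angle between the lines", which is confined to `[0°, 90°]` and
  cannot meet a 120° ceiling; the quantity actually windowed is therefore
  the standard `[0°, 180°]` vertex (pseudo-bond) angle. Both readings are
  exported (`vertex_angle`, `line_angle`).
- `VScore(v_j)` = `d(v_j, c_j)²` where `c_j` is the lattice centre
  (the interpolated point), plus the steric penalty
  `100·Σ_{m ≤ j−2} d(v_j, c_m)⁻²` when `v_j` comes within z of any earlier
  centre. The literal piecewise condition in the source formula branches
  on the distance to the vertex's *own* centre, which never exceeds half
  the lattice diagonal (≤ 1.74 Å), i.e. the penalty branch would fire for
  every vertex; since the stated intent is to penalize vertices close to
  *other* lattices, the default trigger is proximity to an earlier centre
  (`ScoreParams.clash_mode="proximity"`), with the literal branch kept as
  `clash_mode="literal"`. The penalty compares against lattice *centres*,
  not against the vertices actually chosen there — a deliberate weakness
  of the heuristic that keeps `VScore` path-independent.

Strategies:

- **basic** — bond window only. Standard per-vertex recurrence
  `PATH(v_{i,j}) = VScore + min_h {PATH(v_{h,j−1}) + EScore}`; exact for
  its objective, `O(nQ²)`.
- **advanced** — all constraints, exact. The state is the pair (current
  vertex, previous vertex), so the angle at `j−1` is evaluated against the
  true grand-predecessor: `O(nQ³)` time, `O(Q²)` memory. Practical for
  small lattices / short chains; for `n = 2` it reduces to the basic
  recurrence (no angles exist).
- **simplified** (default) — all constraints in `O(nQ²)`: the angle at
  `j−1` is checked against the single predecessor stored on the best path
  into each vertex of lattice `j−1`. Any structure produced satisfies all
  constraints, but the greedy history can dead-end: the strategy may be
  suboptimal or fail on instances the advanced one solves (the test-suite
  pins one such instance). It is the strategy used by the full pipeline by
  default, matching the variant the original experiments used.

Infinities are IEEE `inf` throughout (never large finite sentinels), so
`min` and `+` propagate them exactly; feasibility is `isfinite(score)`.
Ties in `argmin` resolve to the lowest vertex index in the lattice's
lexicographic (x, y, z) vertex order, making every strategy fully
deterministic. All window comparisons are closed intervals with a 1e−9
numerical slack.

An exhaustive oracle (`brute_force_oesp`) scores every one of the `Q^n`
lattice paths by direct tensor summation and is used in the tests to
verify both exact strategies; it refuses instances beyond 10⁷ paths.

## Lattice parameters

Density is fixed at 6 grid points per linear Å (216 per Å³); coarser or
finer grids are configurable but 6/Å is the default the pipeline is tuned
for. The per-frame edge schedule is 1.0 → 1.5 → 2.0 Å: each frame is first
corrected on the smallest lattice and only escalates if infeasible (the
retry is per-frame, not global, so one hard frame does not inflate Q for
the whole morph). With inclusive endpoints an edge of 1.0 Å gives 7 points
per axis (Q = 343) and 2.0 Å gives 13 (Q = 2197); "6 points per Å" is read
as linear density with inclusive grid endpoints — the simplest reading
consistent with a centred grid.

A centred grid requires `edge × density` to be an even integer, and
1.5 × 6 = 9 is odd: the 1.5 Å entry of the standard schedule cannot be
realized exactly at density 6. `build_lattice` therefore minimally
enlarges such grids to the next even step count (1.5 Å → effective 5/3 Å,
11³ vertices), preserving the exact density and centre symmetry;
`pad_to_even=False` raises instead for callers that want the strict
precondition.

## K selection

`K = max(1, round(max_j ‖start_j − end_j‖))`, rounding half away from zero
(15.2 Å → 15). The floor keeps sub-Ångström motions from producing an
empty morph. Truncation (`rounding="truncate"`) is exposed because the
reported GroEL morph (largest displacement 34.8 Å, 34 intermediates) is
consistent only with truncation, while the worked 15.2 → 15 example is
neutral between the two; half-away is the default as the more conventional
rule.

## Synthetic data

The `synthetic` module generates the fixtures all tests run on; nothing in
the package requires downloads.

- `generate_chain` grows a self-avoiding chain with *exact* consecutive
  spacing (default 3.8 Å), vertex angles uniform in a window (default
  80–110°, comfortably inside the 70–120° criterion), free dihedrals, and
  rejection sampling against a steric clearance (default 2.2 Å, strictly
  above the 2.0 Å clash limit so generated chains sit in the interior of
  the feasible region and score exactly 0 under Proteinize).
- `perturb_chain` adds isotropic per-coordinate Gaussian noise
  (σ in Å). This emulates the *displacement structure* of raw
  linear-interpolation artifacts — small, dense, direction-free errors —
  which is the regime Proteinize is designed to repair. σ = 0.3 Å breaks
  the ±0.1 Å bond window almost surely while remaining within reach of
  the 1.0 Å lattice.
- `make_morph_pair` produces a hinge motion: the segment past an interior
  pivot is rotated rigidly about the virtual bond entering the pivot.
  That axis choice preserves every internal distance and angle exactly
  (it is a pure torsion), so the only possible violation is an arm-arm
  clash, handled by re-drawing the base chain.

What these fixtures do **not** emulate: secondary structure, realistic
radius of gyration, correlated (collective) displacement fields, or
full-backbone/side-chain geometry. Passing tests demonstrate the
algorithmic contracts (feasibility, optimality, constraint satisfaction,
determinism) — not that morphs of real proteins are biophysically accurate
trajectories.

## Problem sizes used in the tests

The exact strategies are verified against the enumeration oracle on tiny
instances (n ≤ 4, density 2, edge 1.0 Å, Q = 27 — small enough for the
oracle's Q⁴ = 531 441 paths); the constraint-guarantee and idempotence
checks run the production lattice (Q = 343) on 30-residue chains; morph
contracts run on 24-residue hinge fixtures with K ≤ 5. The advanced
strategy's O(nQ³) cost is the reason its full-density checks use short
chains (n = 6); at production sizes the simplified strategy is the
intended tool, which mirrors how the method is meant to be deployed.

## Known limitations

- Linear interpolation with local corrections cannot follow motions whose
  true path leaves the interpolation corridor by more than the largest
  lattice reach (≈ 1.7 Å per point per frame); such morphs fail cleanly
  with `MorphInfeasibleError`.
- The steric term is a soft penalty against lattice centres, not a hard
  pairwise constraint between chosen vertices; pathological inputs could
  in principle yield a frame with a residual clash (none observed in the
  seeded test battery — every feasible output of the simplified strategy
  passes the full validator).
- Chain-break flags are derived from the start structure only, so an end
  structure with different internal gaps is trusted to share the start's
  topology.
- C-alpha only: no backbone reconstruction, side chains, or energy model.
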