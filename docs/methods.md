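# Methods

## Model and knockout semantics

The network is a first-order linear discrete dynamical system
`x(t+1) = M x(t)` over gene concentrations, `M = I + Δt·A` with `A` the
regulation matrix (rates per unit real time) and `Δt` the real time per
discrete step.  State transitions are independent across genes; sparsity of
`A` (few parents per gene) is what makes the path machinery effective.
`M[j, i]` is the per-step multiplier from source `i` to destination `j`
(columns index sources); gene indices are 0-based internally and model
files carry gene names, never indices.  Initial concentrations are
required nonnegative — the negative-path argument and the vertex-cover
construction both rest on it.

A knockout `s` (binary, `s[g] = 1` for the target `g`) is applied as
`M(s) = D M D` and `x0(s) = D x0` with `D = diag(s)`: a deleted gene's row,
column *and* initial concentration are zeroed.  Zeroing only the row (or
only the column) gives the same value for the target's trajectory when
`s[g] = 1`, but the symmetric convention is the unique one under which the
matrix-power objective agrees *identically* with the path polynomial in
which a path's monomial carries every gene the path visits, its source
included; that identity is what the oracle-equivalence tests assert at
1e-9 relative.

The exact objective `[M(s)^T x0(s)]_g` is computed by `T` masked
matrix-vector products (`O(T n²)`), batched across knockout vectors for the
exhaustive oracle (`objective_exact_many`), never by forming `M(s)^T`.

## Path algebra and the filtering pass

A path `(j_0, …, j_T)` with `j_T = g` has weight `Π_t M[j_{t+1}, j_t]` and
contribution `weight · x0[j_0]`.  Summing contributions over all paths with
the same set of unique visited genes produces the multilinear objective
`f(s) = Σ_k c_k Π_{i∈G_k} s_i`, evaluable on all of `[0,1]^n`.

The builder sweeps backward from the horizon over *suffix buckets*: the
entries at (gene `i`, time `t`) are partial paths from `i` at `t` to the
target at `T`, each carrying its weight and visited-gene set.  One layer
extends every suffix through the nonzero in-entries of its gene's matrix
row.  Two controls keep the sweep tractable:

* **Merging.**  Suffixes sharing (gene, visited set) are merged by summing
  weights.  Merged suffixes have identical monomial futures, so merging is
  exactness-preserving (a test toggles it off and compares term-for-term);
  it is what bounds the blow-up on sparse models.
* **Pruning.**  Within each bucket and separately for each sign class,
  entries are removed greedily in ascending |weight| while the cumulative
  removed |weight| stays at most `ε` times the |weight| total of the
  retained entries of that sign.  An entry exactly on the boundary is
  retained (prefer accuracy); once one entry is retained all heavier ones
  are.  Pruning runs after each backward extension.  `ε = 0` reproduces the
  exact enumeration term for term — *exactly*, not merely to tolerance —
  and the empirical relative error at the all-intact point decreases with
  `ε` (asserted as a median over a seeded ensemble; per-instance
  monotonicity is not guaranteed and not claimed).

Full enumeration guards itself with an estimated path count (indicator
matrix powers, default cap 1e7) and refers callers to the filtered builder
beyond it.  Coefficients below 1e-15 after collapsing are dropped as
numerical noise.  The number of *path terms* surviving the sweep is
recorded in the objective's metadata; it is the quantity the
pruning-behaviour study tracks, since collapsed monomial counts can stay
unchanged even when suffixes were discarded.

## Candidate restriction and the relaxation

Only genes appearing in a negative-coefficient term are deletion
candidates (`G⁻`): the objective is affine and nondecreasing in every other
gene's variable, so those genes stay intact at some optimum.  The
restriction is asserted lossless against unrestricted exhaustive search on
seeded ensembles.  Note `G⁻` is computed from the *collapsed* terms: a
negative path cancelled exactly by a positive path with the same gene set
contributes no candidate, which only shrinks the set and remains sound.

Because `f` is multilinear, its maximum over `[0,1]^d` is attained at a
vertex; the solver therefore searches the box and rounds.  Differential
evolution (rand/1/bin) runs on the objective *restricted* to `G⁻` (terms
collapsed onto the decision coordinates — a large constant-factor saving),
with population = 10 × d (within the usual 2–50× guidance, configurable),
weight factor 0.8, crossover probability 0.9, at most 300 generations,
stopping when the best value improves by less than 1e-8 over 50
consecutive generations, 3 restarts from independently spawned seeds.
Trial coordinates are clipped to the box — equivalent, on a box
constraint, to rejecting infeasible trials but without wasting them.  All
randomness flows through one seeded generator per restart
(`SeedSequence(seed).spawn`), making results bit-reproducible.

Vertex rounding does coordinate passes: the restriction of `f` to one
coordinate is affine `a·s_i + b`; set `s_i = 1` if `a ≥ 0` (zero slope
keeps the gene — the biologically cheaper choice) else `0`, repeating
until a pass changes nothing.  Each move is non-decreasing, so the vertex
value is ≥ the fractional value.

The final answer is always re-evaluated with the exact matrix-power
objective — the pruned polynomial is only a search surrogate and never the
reported value — and the all-intact baseline competes alongside the
restart results.  Ties (equal exact value) resolve toward fewer deletions,
then lexicographic gene order; the exhaustive oracle enumerates subsets in
that same preference order so both routes break ties identically.

## Vertex-cover reduction

For a graph on `n` vertices the reduction builds a `2n+2`-gene instance
(vertex genes, relay genes, target, one inert all-zero padding gene kept to
mirror the block structure), horizon 2, all-ones initial state: edge
`{i,j}` ↦ symmetric weight +2 between vertex genes; vertex `i` → relay `i`
weight 1; relay → target weight 2; vertex → target weight −1; target
self-loop 1.  An intact vertex gene then contributes +2 (via its relay) and
−1 (directly); an edge with both endpoints intact contributes two paths
totalling −4; relay-origin and target-origin paths add the constant
`2n + 1`.  For a deletion set `S` among the vertex genes the objective is

    3n + 1 − |S| − 4 · (# edges uncovered by S),

so an uncovered edge always costs more than any extra deletion saves and
the maximizers are exactly the minimum vertex covers (the subset↔knockout
bijection deletes precisely the subset's vertex genes).  The integer
constants are the smallest satisfying those per-path contributions; they
are certified by the double-oracle sweep over every labeled graph on ≤ 5
vertices rather than assumed.

## Synthetic ensembles and what they do (not) show

The generator emulates the benchmarking regime for the heuristic: each
gene regulated by `k` other genes (`k` uniform in `1..max_parents`,
default ≤ 2; self-persistence is already the identity part of
`M = I + Δt·A`, so self-parents are excluded — a sole self-parent on the
target would degenerate the instance to a single path), weights i.i.d.
uniform on [−1, 1], `Δt = 1`, horizon 10, unit initial concentrations,
first gene as target.  Passing tests on these ensembles show the
*algorithmic* claims — exact path algebra, lossless restriction, vertex
optimality, heuristic-matches-oracle — under sparse signed linear
dynamics.  They do not show robustness to features of real regulatory
networks the generator omits: degree heterogeneity (hubs), correlated
edge signs, mass conservation, saturation or any nonlinearity, or noise in
an estimated `A`.  Linear DDS dynamics can also diverge geometrically over
long horizons; the studies use horizons 8–10 where magnitudes stay
moderate.

## Validation problem sizes

The self-validation battery (tests/test_acceptance.py and
scripts/acceptance.py) uses: 50 × 10-gene models × 200 random knockouts
for the oracle-equivalence check (1e-9 relative); 3 × 10-gene plus
3 × 20-gene models for the heuristic-vs-exhaustive comparison (`ε = 1e-3`,
the 20-gene reference restricted to `G⁻`, which is lossless); all 1099
labeled graphs on ≤ 5 vertices for the reduction; 50 × 8-gene models ×
10,000 fractional points for vertex optimality; 50 × 10-gene models for
restriction soundness; 20 × 15-gene models for pruning accuracy (median
relative error < 1e-2 at `ε = 1e-3`; exact at 0).  These sizes keep every
study deterministic from one seed and exercise the same code paths as
arbitrarily larger runs.

## Numerical choices and limitations

Validation tolerances default to 1e-9 (relative/absolute); model
consistency (`M` vs `I + Δt·A`) uses the same default.  Coefficient noise
floor 1e-15.  Exhaustive search compares values strictly, relying on the
preference-ordered enumeration for ties.  Known limitations: path/term
counts still grow exponentially for dense matrices or long horizons (the
enumeration guard refuses, and pruning error is only controlled
empirically — the relative error bound is not asserted per instance); the
pruned surrogate can in principle misidentify `G⁻` near cancellation
boundaries, in which case the heuristic remains sound (never beats the
oracle) but may miss the optimum; no side-effect constraints on the rest
of the transcriptome are modeled.
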