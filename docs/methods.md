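# Methods

## Problem and data model

The package reconstructs phylogenies for genomes described by *gene order*:
each genome is a signed permutation of a shared set of `g` genes on a single
linear chromosome, with the sign encoding strand.  The only mutation
modelled is the inversion (reversal), which reverses a contiguous block of
genes and flips its signs.  Under maximum parsimony (MP) the target is a
tree topology together with ancestral gene orders at the internal vertices
minimizing the total number of inversions implied across all edges.

Scoring even a single topology is hard for gene-order data: the optimal
internal labeling has no known polynomial algorithm, and the building block
— the inversion *median* of three genomes — is NP-hard.  Exhaustive search
over the `(2n-5)!!` unrooted topologies is hopeless beyond a dozen genomes.
The pipeline implemented here attacks both problems with a spectral
disk-covering method (DCM): recursively bipartition the genome set into
(possibly overlapping) disks down to at most three genomes, solve the tiny
disks exactly, and merge sub-topologies upward, using the MP score to choose
among the few candidate merges at every step.

## Inversion distance

`inversion_distance` implements the Hannenhalli–Pevzner theory.  One genome
is re-expressed in the coordinate frame of the other, the breakpoint graph
is built over the `2g+2` unsigned gene endpoints framed by `0` and `2g+1`,
and

```
d = (g + 1) − cycles + hurdles + fortress
```

Hurdles are unoriented components that are minimal under span containment,
plus the greatest component (whose span contains every other unoriented
component) when it exists; the fortress correction adds one when the hurdle
count is odd and every hurdle is a superhurdle (deleting it promotes a
protected component into a new hurdle).  The implementation is `O(g)` in the
common case and `O(g²)` when a nontrivial cycle lacks an oriented gray edge;
superhurdle detection simulates deletion, which is ample at `g = 100`.
Correctness is pinned by a breadth-first-search oracle over all inversion
moves for `g ≤ 6` (hundreds of random pairs plus curated hurdle-rich
permutations).

The neighbor scan used by the median search exploits a structural shortcut:
if the breakpoint graph has no unoriented component and an inversion's two
cut points fall in different cycles, the move merges the cycles and the
distance increases by exactly one (a single inversion changes the distance
by at most one, so no hurdle can appear).  Such neighbors cost `O(1)`, which
removes the large majority of the `3 · g(g+1)/2` distance evaluations per
scan.  All kernels are numba-compiled over `int32` arrays.

## Inversion medians

`inversion_median` is exact-with-budget.  Stages:

1. **Incumbents.**  Each input genome seeds a steepest-descent walk (best
   strictly improving inversion, with up to 24 equal-score sideways steps
   guarded by a visited set).
2. **Geodesic stage** (only when the incumbent exceeds the half-perimeter
   lower bound `⌈(d_ab+d_ac+d_bc)/2⌉` by ≥ 2): walk a greedy shortest
   reversal path between the two non-start inputs, at each step choosing the
   sorting reversal closest to the third genome.  Along such a path the sum
   of distances to the two endpoints is constant, so the best median
   candidate on the path is its closest approach to the third genome — for
   near-additive data this lands at or within a step or two of the optimum,
   far outside the reach of local descent.
3. **Branch and bound.**  DFS from the input with the smallest distance sum,
   expanding only children at depth `t+1` from the start (shortest-path
   completeness) and pruning with
   `bound(v) = t + ⌈(d(v,B)+d(v,C)+d(B,C))/2⌉ ≥ incumbent`.  Children are
   expanded best-bound-first.  A node budget (default 2000 expansions) caps
   hard instances; when the incumbent sits more than 3 above the lower bound
   the proof is out of reach and only a token budget is spent.  Budget
   exhaustion returns the incumbent flagged `exact=False`.

Random small triples are checked against an exhaustive oracle (minimum over
every signed permutation, distances by BFS).  On near-additive instances at
`g = 100` the solver routinely proves optimality at the half-perimeter bound
without expanding a node.

## Scoring a topology

`score_topology` is the classic gene-order MP loop: sweep internal vertices
(BFS order from the lowest leaf), replace each label with the median of its
three neighbours when that strictly lowers the score, and repeat until a
pass changes nothing.  Two escalations, both strictly score-non-increasing:

* **Plateau moves** — a bounded number of equal-score relabelings (the
  median differs from the current label at the same local cost), which lets
  the coordinate descent slide off shallow ridges.
* **Joint edge moves** — after vertex-wise convergence, for each internal
  edge `(u, v)` with outer neighbours `(a, b)` and `(c, d)`, candidate
  labels for `u` are seeded from medians that bypass `v`
  (`median(a,b,c)`, `median(a,b,d)`), `v` is re-solved against each
  candidate, and the pair is accepted when the five affected edges get
  strictly cheaper.  Adjacent labels frequently lock into a mutual local
  minimum 2–3 inversions above what the ground-truth labeling achieves;
  these two-vertex moves closed that gap exactly in every traced replicate.

A vertex is skipped when its local cost already meets the half-perimeter
bound of its neighbours (provably optimal), which makes re-scoring converged
regions nearly free; distances and medians are memoized on genome content.

## Spectral disk decomposition

For a disk with distance matrix `d` (restricted from the one global matrix —
the metric is pairwise, so sub-disks are slices):

* Gaussian similarity `w_ij = exp(−d_ij²/(2σ²))` with `σ = α·d_max`,
  `α = 0.125` by default and `d_max` the disk's own maximum distance
  (re-computed per disk: the bandwidth should track the disk's scale).
* Fiedler vector of the random-walk Laplacian `D⁻¹(D−W)`, computed via the
  symmetric Laplacian (dense, deterministic `eigh`) and transformed by
  `D^(−1/2)`; unit norm; sign fixed so the largest-magnitude entry is
  positive, ties to the lowest index.  The random-walk normalization is
  chosen because boundary genomes should get small magnitudes regardless of
  how many close neighbours they have — magnitudes are the confidence signal.
* Initial split by entry sign (exact zeros go to the overlap — zero
  confidence); the gap between smallest positive and largest negative entry
  decides whether the split stands alone.  Thresholds scale as `θ/√n`
  because the eigenvector is unit-normalized.  Defaults `θ₁ = 0.5`,
  `θ₂ = 0.25` were set once from the split-gap geometry of additive test
  matrices and are exposed as configuration; the compatibility property
  suite validates them across all four simulation regimes.
* If the gap is below `θ₁/√n`, genomes walk outward from the boundary into
  the overlap until the gap between consecutive sorted entries exceeds
  `θ₂/√n` (so very close genomes are not split), capped by
  `max_overlap_fraction` (default 0.5) and never consuming a whole side.
* **Big-overlap avoidance**: when two long edges isolate two small outlying
  groups, all central genomes get near-zero entries and would flood the
  overlap.  Each child disk is therefore probed with a second decomposition;
  if a child splits cleanly with one part holding the entire parent overlap,
  the *other* part becomes one partition and the rest the other, with no
  overlap.
* Degenerate disks (all pairwise distances zero) fall back to an arbitrary
  balanced split; identical genomes are deduplicated before the pipeline and
  re-attached as zero-length cherries at the end.

Recursion stops at disks of ≤ 3 genomes, yielding the binary disk tree.

## Merging

*Non-overlapping disks*: the closest pair of genomes across the two trees —
internal reconstructed ancestors included — is found; for that pair, every
edge incident to one endpoint is bridged to every edge incident to the
other by subdividing both and joining the new vertices: at most 3 × 3 = 9
candidates (fewer when an endpoint is a leaf; the union over all tied pairs
when the minimum distance ties).  New vertices are initialized with the
median of the attached genome and the two already-labeled neighbours — the
merge order guarantees close, already-reconstructed genomes are available,
which is the decisive advantage over initializing from distant leaves.

*Overlapping disks*: each tree is restricted to the overlap leaves; edges
whose overlap bipartitions are incompatible with the other tree are
contracted.  The second tree's exclusive subtrees are then grafted onto the
first tree, positioned by their overlap bipartitions (grafts land on the
unique admissible edge, or on an existing vertex when the genome distances
make the position ambiguous — the resulting multifurcation is expanded into
every binary resolution, `(2k−5)!!` per degree-`k` vertex, capped at 10,000
candidates with a logged warning).  A single-genome overlap attaches the
whole second tree beside the shared leaf and resolves the multifurcation.
All candidates are scored; the lowest parsimony score wins.

Every merge returns its full candidate set.  The pipeline pools candidates
across the tied sub-topology variants of both children (up to 4 tied
variants propagate upward), re-refines tied finalists once, and breaks
remaining score ties by the total breakpoint-distance of the labeled tree —
ties proved to be where topology errors originate, and the breakpoint
criterion is the natural secondary signal for gene orders.  The final tree
receives a bounded-plateau NNI hill climb (strict score improvements only),
which compensates for the deliberately narrow merge enumeration when a
strictly better tree sits an interchange or two away.

## Simulators

* `uniform_random_tree`: sequential random leaf addition (uniform over
  unrooted binary topologies — verified by chi-square at `n = 5`); integer
  edge lengths uniform on {0..16} by default.  Zero-length edges are allowed
  and are collapsed before accuracy comparison.
* `birth_death_tree`: pure-birth process (default rate 0.001, death 0) run
  until `n` tips; the waiting-time structure matches the Yule closed form.
  Topology keeps its time-lengths until a length regime replaces them.
* `skew_and_scale`: per-edge multiplier `2^s`, `s ~ U(−2, 2)` (a raw uniform
  multiplier on (−2, 2) could be negative; the exponentiated form is the
  standard log-uniform reading and yields the intended right-skew), then one
  global rescale to diameter `1·g` or `2·g` and rounding to nonnegative
  integers.
* `evolve_genomes`: ancestor = identity permutation; exactly `length`
  inversions per edge in preorder; inversion length `L ~ U{1..g}` drawn
  first, then the start uniform among fitting positions (drawing an interval
  uniformly instead would give triangular lengths); a gamma length option
  takes explicit shape/scale parameters.  All internal genomes are retained,
  so the true labeling's parsimony score is available as an oracle.

All randomness flows from one `numpy` Generator; a seed fixes the model
tree, the length draws and the inversion draws.

What the simulations do *not* emulate about real data: unequal gene content
(insertions, deletions, duplications), transpositions and translocations,
rate variation across lineages beyond the skew regime, and any form of
ascertainment in gene selection.  Passing tests therefore speak to the
method's behaviour under its own model — inversion-only evolution on a
fixed gene set — not to robustness against model violation.

## Accuracy metrics

`fp_fn` counts internal-edge bipartitions only: FP = splits of the
reconstruction absent from the model, FN = model splits absent from the
reconstruction; `(FP+FN)/2` is half the Robinson–Foulds distance for binary
pairs.  Edges shorter than 0.5 are contracted first (reconstruction edge
lengths are the inversion distances between endpoint labels, so an edge
whose endpoints carry equal genomes claims no split; integer-length model
trees lose exactly their length-0 edges).

`classify_decomposition` calls a decomposition compatible when some model
edge separates the two exclusive regions — equivalently, when their
spanning subtrees in the model tree are vertex-disjoint.  Overlap genomes
are ignored.  The recoverability probe replays the merge on the model
tree's induced (ground-truth-labeled) sub-topologies and asks whether the
candidate set contains the model topology: an incompatible decomposition is
recoverable exactly when it does not exclude the true tree from the search
space.

## Problem sizes and defaults

The shipped experiment sizes are desk-scale choices: accuracy regimes use
10 replicates of 20 genomes with 100 genes; the compatibility suite spans
four regimes at `n ∈ {10, 20, 40}`; exhaustive-equivalence checks run at
`n ≤ 7` where all `(2n−5)!!` topologies can be scored.  Key defaults:
`alpha = 0.125`, `theta1 = 0.5`, `theta2 = 0.25`,
`max_overlap_fraction = 0.5`, median node budget 2000, candidate cap
10,000, `max_passes = 50`.

## Known limitations

* Median exactness is budget-bounded; saturated-distance triples return
  heuristic medians (flagged).  Everything downstream treats scores as
  upper bounds, which is safe for candidate ranking but means reported
  parsimony scores are not certified minima at large divergence.
* The overlapping-disk graft places ambiguous subtrees by genome-distance
  keys; with non-additive distances a graft can land one position off, and
  only multifurcation resolution (when triggered) re-opens the choice.
* Genomes are linear, unichromosomal, fully signed, equal gene content; no
  distance corrections for saturation are applied (a no-op correction hook
  exists).
* MP itself can prefer a wrong topology when parallel mutations make it
  genuinely more parsimonious than the truth; the pipeline reports what the
  criterion selects.
* Disk decompositions are almost always compatible with the generating tree,
  but not unconditionally: when a simulated tree's diameter far exceeds the
  distance saturation point (`d` caps near `g+1`), a disk can contain groups
  whose mutual distances carry no information about their separation.  In
  that regime an occasional incompatible — and, signal being absent,
  irrecoverable — decomposition is expected from any distance-driven
  splitter; raising the overlap thresholds does not remove it.
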