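# Methods

## Multiplex model

A multiplex over `L` layers and the sorted union node universe of size `n`
assigns every gene one copy per layer.  The supra-adjacency matrix is
`(n·L) × (n·L)` with layer-major copy ordering (copy `(i, l)` at flat index
`l·n + i`).  Diagonal block `l` is layer `l`'s weighted adjacency over the
union ordering; off-diagonal block `(l, k)` holds the interlayer virtual
edges.  Two coupling modes are supported:

* **presence** (default): a gene's copies are coupled only between layers
  whose edge lists contain the gene.  A copy in a layer missing the gene has
  no virtual edges and no intra-layer edges, i.e. it is retained as an
  isolated, unreachable copy.  We keep the matrix dimension fixed at `n·L`
  rather than dropping absent copies; indexing stays uniform and the walk
  never visits them.
* **union**: all `L` copies of every gene are coupled (full identity
  off-diagonal blocks).  This guarantees that mass placed on any copy can
  reach every layer and matches the convention of earlier multiplex RWR
  software; it is also the mode in which no dangling columns can arise from
  absent copies.

## Transition matrix

The walk uses the column-stochastic matrix `T` built directly from the
per-layer adjacencies: for copy `(i, l)` with intra-layer strength
`s_il = Σ_j w_ij(l)` and `c_i` coupled copies,

* to each intra-layer neighbour `j`: `(1 − δ) · w_ij(l) / s_il`,
* to each coupled copy: `δ / c_i`.

Degenerate copies fall back gracefully: with no coupled copies the intra
factor becomes 1 (all mass stays in the layer); with no intra edges the
interlayer entries become `1 / c_i` (all mass crosses); copies with neither
are left as explicit zero columns and handled at walk time.  `δ ∈ [0, 1]`
is a single global scalar (default 0.5); `δ = 0` makes `T` block-diagonal.
Intra-layer probabilities are proportional to edge weights, generalizing
the `1/degree` rule of unweighted graphs; for directed layers columns are
normalized by out-strength.

Construction can parallelize the per-layer block assembly across threads
(`n_workers`), but blocks are always assembled in manifest order, so the
output is bit-identical for any worker count.

## Walk, seeds and tau

The iteration `p ← (1 − r)·T·p + r·p₀` starts at `p = p₀` and stops when
the L1 change drops below `tol = 1e-10` (cap 1000 iterations; at `r = 0.7`
convergence typically takes ~20 iterations since the error contracts by
`1 − r` per step).  Mass flowing into dangling (zero) columns is redirected
to `p₀` each step — the standard teleport treatment — so total probability
is conserved to machine precision at every iteration.

The seed vector places raw mass `weight(g) · τ_l` on seed `g`'s copy in
every layer `l` that contains `g`, then normalizes to sum 1.  `τ` is
constrained to `Σ τ_l = L` and rescaled with a warning otherwise.  This is
deliberately the *per-layer* semantics: each layer's seed copies scale with
that layer's τ, so down-weighting a layer demotes genes reachable only
through it.  (The alternative — scaling each seed equally across all layers
— cancels out after normalization and makes τ inert.)  Seeds absent from
every layer are dropped with a warning; if none remain, or τ zeroes all
remaining mass, construction fails loudly.

Per-gene scores sum the stationary copy probabilities over layers.
Non-seed genes are ranked by descending score with competition ("min")
ranking — tied genes share the smallest rank of their group; seeds are
flagged and left unranked, so cross-validation ranks of held-out genes are
ranks among non-seeds.

## Cross-validation

`kfold` draws a seeded random partition into `K` near-equal folds (sizes
differ by at most one); `loo` holds out one gene per fold; `singletons`
trains on a single gene per fold.  Per fold, the training genes seed the
walk and all non-seed genes are ranked.  Metrics treat held-out genes as
positives and every other ranked gene as negative: AUROC through the
rank-sum (Mann–Whitney) identity with midrank tie correction (all-tied
scores give 0.5), AUPRC by stepwise precision–recall summation, and
precision/recall at cutoffs `k ∈ {10, 50, 100}` by default.

`meanrank` averages a gene's rank over the folds in which it was ranked:
held-out seeds average their held-out folds, background genes all folds.
`rerank` is the competition rank of meanrank across all ranked genes, so
tie groups produce the 1,1,1,1,1,6,… pattern.  All fold randomness flows
from one integer seed; a report is reproducible bit for bit.

## Layer statistics and tau calibration

Edge-set similarity ignores weights and direction (edges are unordered
endpoint pairs): `jaccard = |A∩B| / |A∪B|`, `overlap = |A∩B| / min(|A|,|B|)`.
Layer diameter is the longest finite shortest-path length — the maximum
over connected components — so disconnected layers still report a finite
value.  `calculate_tau` maps per-layer similarity to a gold-standard
reference into `τ_l = L·s_l / Σ_k s_k`; the proportional rule is the
simplest form consistent with "weight layers by their overlap with the
reference", and degrades to uniform τ (with a warning) when every
similarity is zero.

## Shortest paths and aggregation

Shortest paths are computed on the unweighted union of all layers (hop
metric), and each path edge is emitted once per layer carrying it with
`weight_norm = w / total edge weight of the layer` — for an unweighted
layer of `m` edges, `1/m`, so weight_norm sums to 1 over a layer.
`path_length` counts nodes (a two-edge path has length 3).  When several
equally short paths exist one deterministic representative is returned (the
lexicographically smallest node sequence); `all_paths=True` enumerates all
of them.  Aggregation offers the multigraph form (one row per pair and
layer) and the edge-count monoplex (one row per pair, weight = summed layer
weights, i.e. the number of carrying layers for unweighted inputs).

## Null models

`rewire_multiplex` randomizes each layer independently and rebuilds the
matrices.  The default performs degree-preserving double-edge swaps
(`10·|E|` attempted swaps per layer), which preserves node set, edge count
*and* degree sequence; `method="er"` resamples each layer as a uniform
random graph with the same node set and edge count only.  Rewired layers
are emitted unweighted.

The choice matters for calibration.  In a planted-module multiplex the
module genes carry systematically higher degree, and RWR scores correlate
with degree; a degree-preserving null therefore retains part of the signal
(measured mean cross-validation AUROC ≈ 0.67 on the benchmark below), while
the count-only ER null destroys it (≈ 0.50).  The calibration experiment in
`scripts/acceptance.py` uses the count-only null, matching the guarantee it
is stated to provide — node and edge counts preserved; the degree-preserving
variant remains the stricter structural null for topology-controlled
analyses.

## Synthetic benchmark

The planted-module generator emulates functionally cohesive gene sets:
10 modules of 20 genes inside a 500-gene universe, connected with
probability `p_in = 0.3` within modules and `p_out = 0.01` elsewhere,
independently in each of 3 layers (delta 0.5, restart 0.7, 5-fold CV,
50 rewired replicates — sizes chosen so the whole experiment runs on a
laptop in seconds while leaving Monte-Carlo error on mean AUROC near
0.002).  The generator produces independent homogeneous layers with
Poisson-like degrees; it does not emulate the heavy-tailed degree
distributions, inter-layer edge correlation, or heterogeneous layer sizes
of real multi-omic networks, so passing the calibration shows correctness
of the machinery, not biological fidelity of any particular network.

## Numerical choices and limitations

* Convergence tolerance 1e-10 (L1), `max_iter` 1000; non-convergence
  returns a flagged result with a warning rather than raising.
* Duplicate edges in inputs collapse to the first occurrence (warning); a
  summing policy is available.  Self-loops are dropped.
* Score ties rank by the competition rule; ordering within a tie group in
  tabular output is by gene identifier for determinism.
* Archives are zip files with canonical edge lists, JSON metadata and
  optional cached sparse matrices; fixed internal timestamps make archives
  byte-identical across runs.  Matrices are recomputed when absent.
* Gene identifiers are opaque case-sensitive strings; no identifier
  mapping, orthology, or species logic is included.
* Heterogeneous (multi-node-type) networks, per-layer-pair delta, and
  approximate/truncated propagation are out of scope.
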