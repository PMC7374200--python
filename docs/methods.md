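# Methods

## Network model

The input is a prescription table: for each of `n_conditions` conditions
(diseases), an ordered set of at most `max_size` entities (acupoints; the
motivating data keeps the 10 most frequently prescribed per disease).  The
acupoint–disease network (ADN) is the one-mode projection of this bipartite
incidence onto entities: nodes are the union of all prescription entities,
and `w_ij` is the number of conditions whose prescription contains both `i`
and `j`.  Consequences that the code treats as invariants: each condition
induces a clique (`w ≥ 1` within a prescription), `0 ≤ w_ij ≤ n_conditions`,
the weight matrix is symmetric with zero diagonal, and weights are integers.
A pair appearing twice in one condition's rows still contributes 1 — the
model counts diseases, not record mentions — so duplicated input rows are
deduplicated with a warning.  Nodes are held in lexicographic order
throughout so adjacency matrices, selections and serialized artifacts are
bit-reproducible.

Communities are an *input attribute* (in the motivating domain: the 14
meridians plus the extraordinary points, 15 groups), never detected from
topology.  Entities present only in the community map are dropped from the
network; entities missing from the map are a hard error.  Disconnected
networks can be built and serialized, but every operation whose definition
needs finite distances (closeness, diameter, the influence index, the
evaluation metrics) refuses them with an error that lists the components.

## Distances and the influence index

All shortest-path distances, and hence the diameter `D`, are **unweighted
hop counts**; edge weights enter only through the adjacency powers, the
weighted degree, and the weight-reduction benchmark.  The influence profile
is defined from the literal matrix power:

    θ_i^k = Σ_{m≠i} A^k[i,m],   θ^k = ½ Σ_{n≠m} A^k[n,m],   k = 1..D,

so `A^k[i,m]` sums the product of edge weights over every length-`k` walk
from `i` to `m` (walks may revisit nodes; the verbal notion of "weight
accumulation over paths" is ambiguous, but only the walk-product reading is
consistent with using matrix powers, so that is what is implemented and
what the brute-force oracle in the tests enumerates).  The score

    Key_node(v_i) = Σ_{k=1..D} θ_i^k / θ^k

is dimensionless; the percentage form is 100×.  Because off-diagonal row
sums of a symmetric matrix total twice the half-sum, `Σ_i Key_node = 2D`
exactly — the test suite asserts this identity at 1e−9 relative tolerance
on random connected weighted graphs, and it is the cheapest end-to-end
check that the power accumulation is right.  `A^k` is built by repeated
multiplication in float64; for the intended scale (N ≈ 135, integer weights
≤ 50, D ≈ 3–4) entries stay far below the 2^53 integer-exactness limit.

## Mining pipeline

Stage 1 selects, per community, the `min(4, community size)` nodes with the
highest closeness; stage 2 selects, per community, the `min(2, candidates)`
candidates with the highest Key_node (scored on the full network, ranked
within the slate).  Baselines in the fair-comparison protocol rank each
community directly by their own score with the same quota and **no**
closeness pre-filter — the pre-filter is part of the proposed method, not of
the comparison harness.  Ties at any stage break by higher weighted degree,
then lexicographic entity id; the rule is total, so identical inputs give
identical selections.  Communities with no network nodes contribute nothing
(with a warning) rather than erroring.

## Evaluation metrics

*Resolution.*  Scores are grouped into equal-value classes after rounding
to 10 significant digits — without the rounding, floating-point noise would
split analytically tied centralities into spurious classes and overstate
granularity.  `f = 1 − ΣN_i²/(R·n²)`, `Δ = 1 − f`.  `f` is invariant under
strictly monotone transforms of the scores and maximal (`1 − 1/n²`) exactly
when all scores are distinct.

*Deletion loss.*  `DLOS` sums `1/d` over unordered pairs with at least one
deleted endpoint; `ILOS` sums `1/d` over surviving pairs that removal
disconnects.  Both use distances in the **original** network — after
deletion the severed distances are infinite and the quotient would be
meaningless.  `C = 4·TLOS/((N−1)(N+2))` normalizes by the star-center
maximum; `C(star center) = 1` for every size is asserted as the
normalization anchor.  For node *sets* the metric is not uniquely pinned
down by its single-node definition; this package deletes the set
simultaneously, counts each deleted–deleted pair once, and keeps the
single-node normalizer, which makes set losses comparable across methods on
the same network.  Sequential deletion or a set-specific normalizer would
be defensible alternatives; the choice is fixed here and tested for
consistency (`C({v}) = C(v)`).

*Benchmark accuracy.*  The weight-reduction reference sets every edge
length to 2, re-sets edges incident to the focal node to 1, and takes
`l_v` as the mean shortest-path length over **all** unordered pairs (not
just pairs through `v`); `W(v) = s_v / l_v` with `s_v` the weighted degree
in the *original* network — the benchmark probes the original interaction
strengths, only the location term uses the reduced lengths.  Distances are
computed with Dijkstra on the modified length matrix (scipy); a brute-force
simple-path oracle checks `l_v` on small graphs.  Rank agreement uses
Kendall τ-b: both rankings contain ties (k-shell drastically so), so a
tie-aware variant is mandatory; τ is computed on full-network score
vectors, not on the 30-node key sets, matching how the resolution
comparison scores all nodes.

## Baselines

Degree and weighted degree are raw counts/strengths (no normalization —
rankings are what matter).  Closeness is `(N−1)/Σd` on hops; betweenness is
pair-normalized shortest-path betweenness on hops; k-shell is the classic
unweighted core decomposition.  Eigenvector centrality is a power iteration
on `A + I` (the shift leaves eigenvectors unchanged and guarantees a
dominant eigenvalue even on bipartite graphs, where iteration on `A` alone
oscillates), tolerance 1e−10, at most 10 000 iterations, L2-normalized and
nonnegative.  CLD ("clustered local degree") has no universally fixed
formula; the default — sum of unweighted neighbor degrees divided by
`1 + local clustering coefficient` — implements the idea of neighbor
connectivity tempered by clustering and is pluggable, so an alternative
definition can be injected without touching callers.

## Synthetic data

The generator emulates the *shape* of the motivating data source, not its
values: 50 conditions, a 135-entity pool in 15 communities, 10 entities per
prescription, and Zipf-skewed entity popularity (exponent 1.0 by default)
over a seeded random permutation, independent of community labels.  The
induced networks are dense overlapping-clique graphs with a heavy-tailed
weighted-degree distribution — the hub structure the method assumes.  What
the generator does **not** reproduce: the real network's exact degree
sequence, edge list, or published per-node scores (unavailable in
machine-readable form), and any anatomical/spatial structure.  Passing
tests therefore demonstrate the algorithmic claims (cardinalities,
identities, metric definitions, determinism) on data with the right
statistical shape, not a numerical replication of the original study's
per-acupoint tables.

Community sizes: `"auto"` mimics the meridian system's spread with two
deliberately small communities (2 and 3 entities — mirroring meridians
that contribute only a couple of prescription acupoints) and the remaining
13 near-balanced; `"balanced"` splits evenly; an explicit size list is also
accepted.  Because Zipf sampling can leave low-popularity pool entities
unprescribed, the induced network may have fewer nodes than the pool
(N ≤ 135).  Two post-conditions are enforced by bounded rejection-resampling
(50 retries): connectivity (finally restored, if needed, by adding explicit
bridging conditions over component representatives — logged), and an
optional `min_community_nodes` quota used when an analysis requires every
community to hold at least a given number of prescription nodes (e.g. the
full 4-candidates/2-keys configuration in all 15 communities).  An
infeasible quota raises rather than silently degrading.

Where a share of the entity pool is reported (e.g. "30 key nodes ≈ 22.2%
of 135"), the denominator is the configured pool size, the emulated study's
scale, rather than the possibly smaller induced node count.

## Problem sizes and determinism

The test suite runs the full pipeline at study scale (50×135×15) in the
acceptance tests and uses a reduced table (16 conditions, 48 entities, 6
communities) for the per-module end-to-end checks; property suites use the
sizes stated alongside each identity (100 random graphs with N ≤ 40 for the
score-sum identity; N ≤ 6, k ≤ 3 for walk enumeration; N ≤ 8 for the
benchmark oracle).  Everything downstream of a seed is deterministic:
the generator uses a single `numpy` Generator, selections are totally
ordered, and serialization is sorted, so a manifest (inputs, parameters,
seed, versions) reproduces a run bit-identically.

## Known limitations

- The set-deletion loss convention (above) is one consistent reading among
  several; comparisons should only be made within one convention.
- CLD's default formula is a faithful but not canonical rendering of the
  cited idea; use the pluggable hook for a specific published variant.
- Whether closeness in the motivating study used hop or weighted distances
  cannot be determined from the available material; this package uses hops
  everywhere distances appear, which is the only reading consistent with an
  unweighted diameter bound on the walk lengths.
- The generator's heavy-tail check is a sanity bound (mean/median and
  max/median ratios), not a formal power-law fit; no claim of scale-freeness
  is tested.
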