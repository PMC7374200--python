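# acunet

Toolkit for mining key acupoints from weighted acupoint co-occurrence
networks.

Clinical acupuncture summaries record, for each common disease, the set of
acupoints most frequently prescribed for it.  `acunet` turns such a
prescription table into a weighted undirected *acupoint–disease network*
(ADN): each disease induces a clique over its prescribed acupoints, and the
weight `w_ij` counts how many diseases acupoints `i` and `j` co-treat.  With
nodes partitioned into fixed communities (the 14 meridians plus the
extraordinary points), the toolkit selects a compact set of *key acupoints*
— nodes with high influence on the global topology, balanced across
meridians — and evaluates the selection against six classical centrality
baselines.  The intended users are researchers analysing acupuncture
prescription data with network methods, and anyone mining influential nodes
in small weighted co-occurrence networks with a fixed community partition.

## The influence index

For a connected network with weighted adjacency matrix `A` and (unweighted
hop) diameter `D`, define the walk influence of node `v_i` at length `k`

    θ_i^k = Σ_{m≠i} A^k[i, m],        θ^k = ½ Σ_{n≠m} A^k[n, m],

where `A^k` accumulates the edge-weight products of all length-`k` walks.
The key-node score is the node's share of total walk influence over all
lengths up to the diameter:

    Key_node(v_i) = Σ_{k=1..D} θ_i^k / θ^k.

`θ_i^1` is the weighted degree; longer walks reward nodes whose heavy edges
lie on many indirect routes.  The scores satisfy `Σ_i Key_node(v_i) = 2D`
exactly on every connected network.

Mining is two-staged and community-constrained: per community, the top 4
nodes by closeness centrality form the candidate slate (≤ 60 candidates for
15 communities; smaller communities contribute all their nodes), then the
top 2 candidates by `Key_node` become key nodes (30 keys for 15 communities
with ≥ 2 candidates each).

Rankings are evaluated three ways: **resolution** `f = 1 − ΣN_i²/(R·N²)`
over the `R` equal-score classes (Δ = 1 − f, smaller is better);
**node-deletion loss** `C = 4·TLOS/((N−1)(N+2))`, the reciprocal-distance
connectivity loss of deleting a node set, normalized by the star-center
maximum; and **accuracy**, the Kendall τ-b correlation against the
weight-reduction benchmark `W(v) = s_v / l_v`.

## Worked example

```
$ acunet run --seed 9 --out-dir demo
pipeline complete; artifacts in demo
```

simulates a study-shaped prescription table (50 conditions × up to 10 of
135 entities in 15 communities), builds the network, scores it, mines key
nodes and writes the comparison tables.  On this seed the run log reports

```
INFO acunet: build: N=117 M=1347 connected=True
INFO acunet: mine: 57 candidates, 30 key nodes
```

117 of the 135 pool entities were prescribed at least once; the default
community layout keeps two deliberately small communities (2 and 3
entities), so the candidate set has 2 + 3 + 13×4 = 57 members rather than
the 60-cap, and every community still yields two key nodes.
`demo/evaluation.csv` then contains one row per method (values rounded
here):

```
method,delta,granularity,c_set,tau,key_set_size
key_node,0.000100,106,0.6189,0.8317,30
degree,0.004833,31,0.6199,0.9786,30
closeness,0.002778,34,0.6201,0.9460,30
betweenness,0.001768,76,0.6202,0.9682,30
eigenvector,0.000100,106,0.6189,0.8289,30
k_shell,0.053296,7,0.6189,0.8191,30
cld,0.000109,103,0.6201,0.8829,30
```

Read: the walk-influence index distinguishes 106 of 117 nodes (Δ ≈ 1e−4,
as fine-grained as eigenvector centrality and finer than CLD; k-shell
manages only 7 classes); deleting its 30-node key set removes about 62% of
the star-bound connectivity loss, on par with the degree and closeness
sets; and its full-network ranking correlates with the weight-reduction
benchmark at τ ≈ 0.83.

Every subcommand (`simulate`, `build`, `score`, `mine`, `eval`, `run`) is a
thin wrapper over the library; see `acunet --help` and the API in
`acunet/`.

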