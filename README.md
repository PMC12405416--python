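# rtcnspace

Tools for comparing **ranked tree-child networks (RTCNs)** — rooted
phylogenetic networks whose speciation and hybridization events are ordered
in time — and their arc-weighted counterparts, **equidistant tree-child
networks (ETCNs)**, in which every root-to-leaf path has the same total
length.

Who it is for: phylogeneticists and method developers who need distances
between reticulate evolutionary histories that respect event order, e.g. to
compare posterior samples of dated networks or to embed network estimates in
a common metric space.

## The encoding and the distances

Fix a taxon set `X` with `n = |X| ≥ 2`. A binary RTCN on `X` is written as a
**maximal chain of cluster systems**

```
{{x} : x ∈ X} = C_1 ⊢ C_2 ⊢ … ⊢ C_n = {X}
```

where each step replaces, in the current collection of taxon subsets, either

- two clusters `A, B` by `A ∪ B` (a **join**, i.e. a speciation event), or
- three clusters `A, B, C` by `A ∪ B` and `B ∪ C` (a **reticulation**, with
  `B` the hybrid cluster).

Every cluster in every level keeps a *private* taxon that appears in no other
cluster of that level, which is exactly what makes the chain decodable: the
map chain → network is a bijection, implemented here as `decode_binary` /
`encode`.

On top of the encoding the package provides:

- **Ranked Robinson–Foulds analogue** `rf_distance`: the symmetric
  difference `|{C_i(N)} Δ {C_i(N')}|` of the two chains as sets of levels.
- **rNNI / rNNI\* distances** `bfs_distance`: two networks are one move
  apart when their chains differ in exactly one position; shortest move
  sequences are found by exact bidirectional BFS, and `detangle_to_tree`
  constructively walks any network chain to a ranked tree.
- **The chain poset**: all cluster systems occurring in maximal chains,
  ordered by co-occurrence (`is_member`, `precedes`, `grade`,
  `enumerate_maximal_chains`), graded by `n − |C|`.
- **The orthant space of ETCNs**: a point is a sparse map
  `ω : T(X) − {{X}} → R≥0` whose support forms a chain; one Euclidean orthant
  per maximal chain, glued along shared coordinates. The space is CAT(0), so
  geodesics are unique; `geodesic_distance` computes the exact geodesic
  length

  ```
  δ(ω, ω')² = Σ_shared (ω − ω')²  +  Σ_i (‖A_i‖ + ‖B_i‖)²
  ```

  over the optimal ordered block partition `(A_1…A_k; B_1…B_k)` of the two
  disjoint support parts, found by successive refinement with exact
  min-weight vertex covers (max-flow/min-cut) on bipartite incomparability
  graphs — a geodesic-treepath algorithm whose compatibility notion is poset
  comparability. `point_to_network` / `point_from_network` convert between
  points and arc-weighted networks; `geodesic_point` evaluates the geodesic
  at any arc-length fraction.

## Worked example

```python
import rtcnspace as r

ex = r.worked_examples()

# A four-taxon chain with one reticulation: decode it and round-trip.
chain = ex["hybrid_chain"]          # singletons ⊢ {ab,c,d} ⊢ {abc,cd} ⊢ {abcd}
net = r.decode_binary(chain)
print(r.encode(net) == chain)       # True
print(r.to_enewick(net))
# (((a[r=1],b[r=1])[r=2],(c[r=1])#H1[r=3])[r=3],(#H1[r=3],d[r=1])[r=3])[r=4];

# Two five-taxon ranked trees one move apart.
t1, t2 = ex["tree_pair"]
print(r.rf_distance(t1, t2))                      # 2
print(r.bfs_distance(t1, t2, move_set="tree")[0]) # 1

# A weighted point: one reticulation, rank differences 1.3, 2.0, 1.9, 0.8.
p = ex["weighted_point"]
net, w = r.point_to_network(p)       # every root-to-leaf path sums to 6.0
back = r.point_from_network(net, w)
print(back.coords[r.system([["a","b"],["b","c"],["d"],["e"]])])  # 2.0

# Geodesic to an ultrametric-tree point.
q = r.make_point(t1, (1.0, 0.5, 1.0, 1.0))
print(f"{r.geodesic_distance(p, q).distance:.12g}")  # 4.38256134809
```

The printed eNewick string shows the single hybrid vertex (`#H1`, the `c`
lineage) with its two parents; `[r=k]` labels are vertex ranks. The distance
`4.38256…` is the cone-path length here because the two supports fall into a
single mutually incomparable block.

The same operations are available from the shell via the `rtcnspace` command
(`encode`, `decode`, `build`, `validate`, `simulate`, `dist-rf`,
`dist-rnni`, `dist-geodesic`, `enumerate`, `fixtures`); all structured data
is canonical JSON, extended Newick is export-only.

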