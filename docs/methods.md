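# Methods

This note records the models implemented by `rtcnspace`, the choices made
where the mathematics leaves freedom, and what the tests do and do not
establish.

## Chains as the canonical coordinates

All structures are stored as chains of cluster systems, never primarily as
graphs. A maximal chain on `n` taxa has `n` levels, level `i` holding
`n − i + 1` clusters; a step is a join (two clusters replaced by their
union) or a reticulation (three clusters `A, B, C` replaced by `A ∪ B` and
`B ∪ C`). The package enforces the *size law* — each step removes exactly
one cluster net — and raises a `DegenerateStepError` when a union would
collide with an existing cluster; such collisions cannot occur in systems
satisfying the private-element property, but the step operations accept
arbitrary systems and must fail loudly.

Witness reporting (`relation`) is brute force over all decompositions rather
than a set-difference shortcut: for systems with the private-element
property the removed/added set differences determine the witness uniquely,
but for arbitrary systems exotic decompositions exist (e.g. a "join" with
`B ⊆ A` removes only one cluster), and the contract is to report every
decomposition whose application yields the target. Reticulation witnesses
collapse the `A ↔ C` symmetry by canonical order.

Canonical forms: clusters serialize as sorted label lists, systems as lists
of clusters sorted by `(min label, size, lexicographic)`. This fixes
hashing, deduplication and byte-stable JSON; the underlying objects are
unordered sets and no semantics is attached to the order.

## The poset and its decision procedures

Membership of a system in some maximal chain, and comparability of two
systems, are decided by breadth-first search over the one-step successor
relation, starting from the singleton partition. Two exact prunings keep
this cheap at desk scale: along any chain every later cluster is a union of
earlier clusters, so intermediate systems incompatible with the target in
that sense are cut; and the private-element property is a necessary
condition used as a fast negative filter. No polynomial-time
characterization of membership is assumed anywhere; search doubles as an
unimpeachable oracle for the property tests. Results are memoized per
process.

Exhaustive chain enumeration is capped at six taxa by default (the count is
`∏_{k=3..n} [C(k,2) + 3·C(k,3)]`: 6 chains at `n = 3`, 108 at `n = 4`, 4,320
at `n = 5`, ≈ 400k at `n = 6`); the cap is an explicit argument, not an
environment switch.

## Networks

`decode_binary` replays the generative process guided by step witnesses;
`build_network` implements the general three-phase per-level construction
(identify frontier vertices with equal destination sets; wire each
single-destination vertex into every multi-destination vertex containing its
destination, creating hybrids; add stems above out-degree ≥ 2 frontier
vertices). The two constructions are independent code paths and are checked
against each other by graph isomorphism on all 108 four-taxon chains.

For chains skipping levels, the constructed network is *the* canonical
representative of the chain; other ranked tree-child networks realizing the
same chain exist but are out of scope, as is any encoding of arbitrary
non-binary ranked networks. One consequence worth stating explicitly: when
an interior level contains two overlapping clusters (e.g. `{a,b,c}` and
`{b,c,d}` over four taxa), the construction identifies the stems of the
shared taxa in its first phase, so the canonical representative carries a
single hybrid vertex with two children rather than one hybrid per shared
taxon. Rank assignment in non-binary networks follows the construction
verbatim (heads of level-`i` arcs get rank `i`); the binary "rank tie iff
hybrid arc" rule is enforced only for binary networks.

eNewick export is deterministic: children ordered by the canonical key of
their hardwired cluster, hybrid tags `#Hk` numbered in traversal order,
ranks as `[r=k]` labels, weights as branch lengths. Parsing third-party
eNewick is deliberately unsupported (networks always come from chains), so
the writer is covered by exact expected-string tests rather than a
round-trip through an external parser.

## Move distances

`star_neighbors` generates the rNNI\* neighborhood by replacing one interior
level with any system sandwiched between its neighbors; `tree_neighbors`
restricts to partition-only chains. Exact distances use bidirectional BFS
with canonical hashing, capped at six taxa by default because the state
space is the full set of maximal chains and the complexity of the distance
is open. `detangle_to_tree` follows the constructive connectivity argument:
repeatedly take the lowest reticulation level, restrict the chain above it
to one private representative per cluster (smallest label — any choice is
valid, one is fixed for determinism), walk the restricted ranked tree by
tree moves to a canonical caterpillar whose rank-2 cherry pairs the
representatives of the two hybrid products (the cherry is the only
requirement; the caterpillar shape is free), lift each move back, and
replace the reticulation level by a plain join. The inner tree walk uses
tree-move BFS rather than a polynomial rNNI router — correctness over speed
at desk scale; the call site is the single swap-in point if a router is ever
added.

## The orthant space and geodesics

A point is a sparse map from cluster systems (excluding `{X}`) to positive
reals whose support, plus both endpoints, is totally ordered. Validation
sorts candidate supports by grade: distinct comparable systems always have
distinct grades, so grade-sorting plus consecutive comparability is a
complete check. Zero values are allowed at construction and simply drop a
level from the support; the origin (empty support) is a valid boundary
point.

`point_to_network` weights each arc by the total rank difference it spans,
which forces equidistance; `point_from_network` inverts this by recovering
per-rank heights, validating path-independence of depths, equal leaf depths
and rank-consistency to a tolerance of `1e-9`, and clamping rank differences
within tolerance of zero.

`geodesic_distance` adapts the geodesic-treepath algorithm with
compatibility defined as poset comparability. Its soundness rests on the
flagness of the poset (pairwise comparable systems lie in a common chain),
which is itself a tested property. Coordinates shared by both supports
contribute a pure Euclidean term because every shared system is comparable
with everything in either support chain. The disjoint parts start as one
cone block; a block splits while the minimum-weight vertex cover of its
bipartite incomparability graph — vertex weights `(value/‖block‖)²`, solved
exactly by max-flow/min-cut — has weight below 1. Support systems with no
incomparable partner on the other side are peeled into one-sided blocks by
the same mechanics and contribute independently, matching the standard
treatment of such coordinates. Block norm ratios are asserted non-decreasing
at termination. The geodesic is evaluated at parameter `s` by the standard
leg formula (block coordinates scale by `((1−s)‖A_j‖ − s‖B_j‖)/‖A_j‖`,
clamped at 0, and symmetrically for the B side; shared coordinates
interpolate linearly), which is arc-length parameterization; the midpoint
property is verified numerically in the tests. The numeric tolerance for
ratio ordering, cover comparisons and midpoint checks is `1e-9` throughout.

The test oracle enumerates *all* ordered block partitions satisfying the two
path-space conditions and minimizes the length formula directly; it shares
no code with the refinement algorithm beyond the comparability predicate.

## Synthetic data

`random_maximal_chain` samples the generative process directly: at each
level with `k ≥ 3` clusters a reticulation happens with probability `p_ret`
(uniform over the `3·C(k,3)` witness choices: middle cluster first, then the
unordered outer pair), otherwise a join uniform over the `C(k,2)` pairs; two
clusters force the final join. `random_point` drops interior levels of a
random maximal chain with probability `p_skip` (the endpoints are never
dropped, so the singleton level always carries weight) and draws surviving
rank differences from an exponential with mean `rate`.

Defaults (`n = 5`, `p_ret = 0.25`, `p_skip = 0.3`, `rate = 1.0`) are chosen
once as a realistic desk-scale regime: five taxa matches the running
examples, a quarter reticulation rate yields a mix of zero-, one- and
multi-hybrid networks without saturating the chain, moderate skipping
exercises boundary orthants, and unit-mean exponentials give
scale-free-ish weights. A single seeded stream with fixed choice order makes
seeds portable.

What the generator does *not* emulate: any biological realism beyond the
combinatorics — no coalescent or birth–death timing, no uniform
distribution over networks (the process is not uniform; uniform sampling is
available only through exhaustive enumeration at ≤ 6 taxa), no inference
noise. Passing tests therefore establish correctness of the combinatorial
and metric machinery, not statistical behavior on estimated networks.

## Known limitations

- Poset membership/comparability and exact move distances are search-based;
  practical up to roughly seven taxa (the intended regime), not beyond.
- Only the canonical network representative of a non-maximal chain is
  constructed.
- `encode` is guaranteed to return a chain only for networks produced by the
  package's constructions; hand-built non-binary networks pass validation
  but have no such guarantee.
- No Fréchet means, principal components or confidence sets on the orthant
  space; the geodesic machinery is the intended foundation for such
  extensions.
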