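"""The CAT(0) orthant space of equidistant tree-child networks.

A point of the space is a sparse non-negative map from chain-realizable
cluster systems to rank-difference weights whose support, together with the
singleton partition and ``{X}``, is totally ordered in the chain poset.  Each
point corresponds to an equidistant tree-child network: the support chain is
realized as a ranked network and every arc is weighted by the total rank
difference it spans, so that all root-to-leaf paths have equal length.

The geodesic distance between two points is computed exactly by a
successive-refinement algorithm of geodesic-treepath type: coordinates
shared by both supports contribute a Euclidean term, and the two disjoint
support parts are split into an ordered partition of blocks by repeatedly
solving a minimum-weight vertex cover (via max-flow/min-cut) on the
bipartite incomparability graph of each block.  Compatibility of two
coordinate axes is poset comparability; a set of pairwise comparable systems
always lies in a common chain, which is what makes the orthant structure and
the algorithm sound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .chains import (
    Chain,
    ClusterSystem,
    TaxonSet,
    singleton_partition,
    system_key,
    system_union,
)
from . import poset
from .networks import RankedNetwork, build_network, encode, validate_network

#: Numeric tolerance for ratio ordering, cover weights and path sums.
TOL = 1e-9


@dataclass(frozen=True)
class EtcnPoint:
    """A point of the orthant space: sparse positive coordinates on a chain."""

    taxa: TaxonSet
    coords: dict  # ClusterSystem -> positive float

    @property
    def support(self) -> frozenset:
        return frozenset(self.coords)

    def value(self, sys_: ClusterSystem) -> float:
        return self.coords.get(sys_, 0.0)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EtcnPoint)
            and self.taxa == other.taxa
            and self.coords == other.coords
        )

    def __hash__(self) -> int:
        return hash((self.taxa, frozenset(self.coords.items())))


@dataclass(frozen=True)
class GeodesicResult:
    """Distance plus the ordered block partition realizing it."""

    distance: float
    blocks: tuple  # ((A_i systems...), (B_i systems...)) per block
    common: tuple  # (system, coordinate difference p - q) per shared system


def validate_point(p: EtcnPoint) -> None:
    """Raise if the support does not form a chain of poset members."""
    x = frozenset(p.taxa.labels)
    for sys_, val in p.coords.items():
        if val <= 0:
            raise ValueError("stored coordinates must be positive")
        if system_union(sys_) != x:
            raise ValueError(f"system {system_key(sys_)} is not on the taxon set")
        if len(sys_) == 1:
            raise ValueError("{X} carries no coordinate")
        if not poset.is_member(sys_):
            raise ValueError(f"system {system_key(sys_)} occurs in no maximal chain")
    support_chain(p)  # raises if not totally ordered


def support_chain(p: EtcnPoint) -> Chain:
    """The support plus both endpoints, sorted into a chain by grade."""
    taxa = p.taxa
    systems = set(p.coords) | {singleton_partition(taxa), frozenset((frozenset(taxa.labels),))}
    by_grade = sorted(systems, key=lambda s: taxa.n - len(s))
    for a, b in zip(by_grade, by_grade[1:]):
        if len(a) == len(b):
            raise ValueError("support contains two distinct systems of equal grade")
        if not poset.precedes(a, b):
            raise ValueError("support systems are not totally ordered")
    return tuple(by_grade)


def make_point(
    chain: Sequence[ClusterSystem], values: Sequence[float]
) -> EtcnPoint:
    """Assign rank-difference ``values`` to the first ``t - 1`` chain levels.

    Zero values are permitted and simply leave the level out of the support
    (a boundary point of the orthant).
    """
    chain = tuple(chain)
    verdict = poset.is_chain(chain)
    if not verdict:
        raise ValueError(f"not a chain: {verdict.reason}")
    if len(values) != len(chain) - 1:
        raise ValueError(
            f"expected {len(chain) - 1} values for a chain of length {len(chain)}, "
            f"got {len(values)}"
        )
    if any(v < 0 for v in values):
        raise ValueError("rank differences must be non-negative")
    taxa = TaxonSet(tuple(system_union(chain[-1])))
    coords = {chain[i]: float(v) for i, v in enumerate(values) if v > 0}
    return EtcnPoint(taxa, coords)


def point_to_network(p: EtcnPoint) -> tuple[RankedNetwork, dict]:
    """Realize the point as a ranked network with an equidistant weighting.

    Each arc is weighted by the sum of the rank differences it spans, so all
    root-to-leaf path weights equal the total height of the point.
    """
    validate_point(p)
    chain = support_chain(p)
    values = [p.value(chain[i]) for i in range(len(chain) - 1)]
    net = build_network(chain)
    weights = {
        (u, v): sum(values[net.rank[v] - 1 : net.rank[u] - 1])
        for (u, v) in net.graph.edges()
    }
    return net, weights


def point_from_network(
    net: RankedNetwork, arc_weights: Mapping[tuple[int, int], float]
) -> EtcnPoint:
    """Recover rank differences from an equidistant, rank-consistent weighting.

    Inverse of :func:`point_to_network` on its image.  Raises a validation
    error naming a violating arc or leaf when the weighting is not
    equidistant or not consistent with the ranks.
    """
    verdict = validate_network(net)
    if not verdict:
        raise ValueError(f"invalid network: {verdict.reason}")
    g = net.graph
    depth: dict[int, float] = {net.root: 0.0}
    for u in nx.topological_sort(g):
        for v in g.successors(u):
            w = arc_weights[(u, v)]
            if w < 0:
                raise ValueError(f"negative weight on arc {(u, v)}")
            d = depth[u] + w
            if v in depth and abs(depth[v] - d) > TOL:
                raise ValueError(
                    f"weighting is not equidistant: paths to vertex {v} disagree"
                )
            depth[v] = d
    leaf_depths = {v: depth[v] for v in net.leaves}
    height_total = next(iter(leaf_depths.values()))
    for v, d in leaf_depths.items():
        if abs(d - height_total) > TOL:
            raise ValueError(f"weighting is not equidistant: leaf {v} differs")
    t = net.rank[net.root]
    height_by_rank: dict[int, float] = {}
    for v in g:
        h = height_total - depth[v]
        r = net.rank[v]
        if r in height_by_rank and abs(height_by_rank[r] - h) > TOL:
            raise ValueError(
                f"weighting is not rank-consistent: vertices of rank {r} disagree"
            )
        height_by_rank.setdefault(r, h)
    diffs = []
    for j in range(1, t):
        d = height_by_rank[j + 1] - height_by_rank[j]
        if d < -TOL:
            raise ValueError(f"weighting is not rank-consistent at rank {j}")
        diffs.append(max(d, 0.0))
    chain = encode(net)
    coords = {chain[j - 1]: diffs[j - 1] for j in range(1, t) if diffs[j - 1] > TOL}
    return EtcnPoint(net.taxa, coords)


def _norm(values: Sequence[float]) -> float:
    return math.sqrt(sum(v * v for v in values))


def _min_weight_cover(
    a_items: Sequence[tuple[ClusterSystem, float]],
    b_items: Sequence[tuple[ClusterSystem, float]],
    edges: set[tuple[int, int]],
) -> tuple[float, set[int], set[int]]:
    """Exact min-weight vertex cover of a bipartite graph via min-cut.

    Weights are the items' second components; ``edges`` are (a-index,
    b-index) pairs that must be covered.  Returns (weight, covered a-indices,
    covered b-indices).
    """
    g = nx.DiGraph()
    for i, (_, w) in enumerate(a_items):
        g.add_edge("s", ("a", i), capacity=w)
    for j, (_, w) in enumerate(b_items):
        g.add_edge(("b", j), "t", capacity=w)
    for i, j in edges:
        g.add_edge(("a", i), ("b", j), capacity=float("inf"))
    cut, (source_side, sink_side) = nx.minimum_cut(g, "s", "t")
    cover_a = {i for i in range(len(a_items)) if ("a", i) in sink_side}
    cover_b = {j for j in range(len(b_items)) if ("b", j) in source_side}
    return cut, cover_a, cover_b


def _refine_blocks(
    a_items: list[tuple[ClusterSystem, float]],
    b_items: list[tuple[ClusterSystem, float]],
) -> list[tuple[list, list]]:
    """Successive refinement of the single-block (cone) partition.

    A block splits while the min-weight vertex cover of its bipartite
    incomparability graph, with normalized squared weights, has weight
    strictly below one.
    """
    incompatible = {
        (sa, sb)
        for sa, _ in a_items
        for sb, _ in b_items
        if not poset.comparable(sa, sb)
    }
    blocks: list[tuple[list, list]] = [(list(a_items), list(b_items))]
    while True:
        new_blocks: list[tuple[list, list]] = []
        changed = False
        for a_blk, b_blk in blocks:
            edges = {
                (i, j)
                for i, (sa, _) in enumerate(a_blk)
                for j, (sb, _) in enumerate(b_blk)
                if (sa, sb) in incompatible
            }
            if not a_blk or not b_blk or not edges:
                cover_w: float = 0.0
                cover_a: set[int] = set()
                cover_b: set[int] = set()
            else:
                na = _norm([v for _, v in a_blk])
                nb = _norm([v for _, v in b_blk])
                aw = [(s, (v / na) ** 2) for s, v in a_blk]
                bw = [(s, (v / nb) ** 2) for s, v in b_blk]
                cover_w, cover_a, cover_b = _min_weight_cover(aw, bw, edges)
            if cover_w < 1.0 - TOL and (a_blk and b_blk):
                c1 = [a_blk[i] for i in sorted(cover_a)]
                c2 = [a_blk[i] for i in range(len(a_blk)) if i not in cover_a]
                d2 = [b_blk[j] for j in sorted(cover_b)]
                d1 = [b_blk[j] for j in range(len(b_blk)) if j not in cover_b]
                new_blocks.append((c1, d1))
                new_blocks.append((c2, d2))
                changed = True
            else:
                new_blocks.append((a_blk, b_blk))
        blocks = [blk for blk in new_blocks if blk[0] or blk[1]]
        if not changed:
            return blocks


def geodesic_distance(p: EtcnPoint, q: EtcnPoint) -> GeodesicResult:
    """The exact CAT(0) geodesic distance between two points."""
    if p.taxa != q.taxa:
        raise ValueError("points are on different taxon sets")
    validate_point(p)
    validate_point(q)
    shared = sorted(p.support & q.support, key=system_key)
    common = tuple((s, p.coords[s] - q.coords[s]) for s in shared)
    a_items = sorted(
        ((s, p.coords[s]) for s in p.support - q.support),
        key=lambda sv: system_key(sv[0]),
    )
    b_items = sorted(
        ((s, q.coords[s]) for s in q.support - p.support),
        key=lambda sv: system_key(sv[0]),
    )
    blocks = _refine_blocks(list(a_items), list(b_items))
    sq = sum(d * d for _, d in common)
    ratios = []
    for a_blk, b_blk in blocks:
        na = _norm([v for _, v in a_blk])
        nb = _norm([v for _, v in b_blk])
        sq += (na + nb) ** 2
        if a_blk and b_blk:
            ratios.append(na / nb)
    assert all(r1 <= r2 + TOL for r1, r2 in zip(ratios, ratios[1:])), (
        "block ratios must be non-decreasing"
    )
    out_blocks = tuple(
        (tuple(s for s, _ in a_blk), tuple(s for s, _ in b_blk))
        for a_blk, b_blk in blocks
    )
    return GeodesicResult(math.sqrt(sq), out_blocks, common)


def geodesic_point(p: EtcnPoint, q: EtcnPoint, s: float) -> EtcnPoint:
    """The point at arc-length fraction ``s`` along the unique geodesic."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("the fraction must lie in [0, 1]")
    if p.taxa != q.taxa:
        raise ValueError("points are on different taxon sets")
    if s == 0.0:
        return p
    if s == 1.0:
        return q
    result = geodesic_distance(p, q)
    coords: dict = {}
    for sys_, _ in result.common:
        val = (1 - s) * p.coords[sys_] + s * q.coords[sys_]
        if val > 0:
            coords[sys_] = val
    for a_syss, b_syss in result.blocks:
        na = _norm([p.coords[sys_] for sys_ in a_syss])
        nb = _norm([q.coords[sys_] for sys_ in b_syss])
        shrink = (1 - s) * na - s * nb
        if shrink > TOL and na > 0:
            for sys_ in a_syss:
                coords[sys_] = p.coords[sys_] * shrink / na
        grow = s * nb - (1 - s) * na
        if grow > TOL and nb > 0:
            for sys_ in b_syss:
                coords[sys_] = q.coords[sys_] * grow / nb
    out = EtcnPoint(p.taxa, coords)
    validate_point(out)
    return out


def lower_and_upper_bounds(p: EtcnPoint, q: EtcnPoint) -> tuple[float, float]:
    """Coordinate-wise lower bound and cone-path upper bound on the geodesic.

    The lower bound treats every non-shared coordinate independently; the
    upper bound is the two-segment path through the shared face.
    """
    if p.taxa != q.taxa:
        raise ValueError("points are on different taxon sets")
    shared = p.support & q.support
    sq_common = sum((p.coords[s] - q.coords[s]) ** 2 for s in shared)
    a_vals = [p.coords[s] for s in p.support - q.support]
    b_vals = [q.coords[s] for s in q.support - p.support]
    lower = math.sqrt(sq_common + sum(v * v for v in a_vals) + sum(v * v for v in b_vals))
    upper = math.sqrt(sq_common + (_norm(a_vals) + _norm(b_vals)) ** 2)
    return lower, upper
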