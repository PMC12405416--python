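"""Ranked tree-child networks as DAGs: decoding, encoding, validation, export.

Binary RTCNs are decoded from maximal chains by replaying the generative
process (merge two frontier vertices for a join step, wire a hybrid for a
reticulation step); the inverse map reads the cluster system at every rank
level off the network.  General chains -- where intermediate levels may be
skipped -- are realized by a three-phase construction per level that merges
frontier vertices with equal "destination" sets, wires hybrids, and adds
stems.  Networks are always derived from chains; the chain is the canonical
coordinate of a network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .chains import (
    Chain,
    ChainVerdict,
    Cluster,
    ClusterSystem,
    TaxonSet,
    cluster_key,
    is_maximal_chain,
    relation,
    singleton_partition,
    sorted_clusters,
    system_union,
)
from . import poset


@dataclass
class RankedNetwork:
    """A rooted DAG with ranked vertices and bijectively labeled leaves."""

    graph: nx.DiGraph
    root: int
    leaf_label: dict[int, str]
    rank: dict[int, int]

    @property
    def taxa(self) -> TaxonSet:
        return TaxonSet(tuple(self.leaf_label.values()))

    @property
    def leaves(self) -> list[int]:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    @property
    def arcs(self) -> list[tuple[int, int]]:
        return sorted(self.graph.edges())

    def hybrid_vertices(self) -> list[int]:
        return sorted(v for v in self.graph if self.graph.in_degree(v) >= 2)

    def is_binary(self) -> bool:
        g = self.graph
        if g.out_degree(self.root) != 2 or g.in_degree(self.root) != 0:
            return False
        for v in g:
            if v == self.root or g.out_degree(v) == 0:
                continue
            deg = (g.in_degree(v), g.out_degree(v))
            if deg not in ((1, 2), (2, 1)):
                return False
        return True

    def copy(self) -> "RankedNetwork":
        return RankedNetwork(
            self.graph.copy(), self.root, dict(self.leaf_label), dict(self.rank)
        )


class _Builder:
    """Shared plumbing for constructing networks level by level."""

    def __init__(self, taxa: TaxonSet):
        self.g = nx.DiGraph()
        self.leaf_label: dict[int, str] = {}
        self.rank: dict[int, int] = {}
        self._next = 0
        # frontier: cluster -> in-degree-0 stem vertex above that cluster
        self.frontier: dict[Cluster, int] = {}
        for x in taxa.labels:
            leaf = self.new_vertex()
            self.leaf_label[leaf] = x
            self.rank[leaf] = 1
            stem = self.new_vertex()
            self.g.add_edge(stem, leaf)
            self.frontier[frozenset((x,))] = stem

    def new_vertex(self) -> int:
        v = self._next
        self._next += 1
        self.g.add_node(v)
        return v

    def merge(self, stems: Sequence[int]) -> int:
        """Identify in-degree-0 stems into one vertex keeping all children."""
        children = [c for s in stems for c in self.g.successors(s)]
        self.g.remove_nodes_from(stems)
        u = self.new_vertex()
        for c in children:
            self.g.add_edge(u, c)
        return u

    def add_stem(self, v: int) -> int:
        t = self.new_vertex()
        self.g.add_edge(t, v)
        return t

    def finish_root(self, t: int) -> RankedNetwork:
        stems = sorted(self.frontier.values())
        root = self.merge(stems)
        self.rank[root] = t
        return RankedNetwork(self.g, root, self.leaf_label, self.rank)


def decode_binary(chain: Sequence[ClusterSystem]) -> RankedNetwork:
    """The unique binary RTCN whose level-by-level encoding is ``chain``.

    Each step applies the generative move named by the step witness; the
    frontier vertices taking part are identified through the clusters of the
    witness, which the private-element property makes unambiguous.
    """
    chain = tuple(chain)
    verdict = is_maximal_chain(chain)
    if not verdict:
        raise ValueError(
            f"not a maximal chain (step {verdict.step}): {verdict.reason}"
        )
    taxa = TaxonSet(tuple(system_union(chain[-1])))
    n = taxa.n
    b = _Builder(taxa)
    for i in range(n - 2):  # interior steps produce chain[i + 1], rank i + 2
        r = i + 2
        w = relation(chain[i], chain[i + 1])[0]
        if w.kind == "join":
            a, bb = w.clusters
            u = b.merge([b.frontier.pop(a), b.frontier.pop(bb)])
            b.rank[u] = r
            b.frontier[a | bb] = b.add_stem(u)
        else:
            a, mid, c = w.clusters
            u = b.frontier.pop(a)
            v = b.frontier.pop(mid)
            wv = b.frontier.pop(c)
            b.g.add_edge(u, v)
            b.g.add_edge(wv, v)
            b.rank[u] = b.rank[v] = b.rank[wv] = r
            b.frontier[a | mid] = b.add_stem(u)
            b.frontier[mid | c] = b.add_stem(wv)
    return b.finish_root(n)


def build_network(chain: Sequence[ClusterSystem]) -> RankedNetwork:
    """Realize a (possibly non-maximal) chain as a ranked tree-child network.

    Level ``i`` runs three phases: frontier vertices whose clusters have
    equal destination sets ``H(A) = {B in next level : A <= B}`` are
    identified; every frontier vertex with a singleton destination set
    contained in a multi-destination set sends an arc into the latter's
    vertex, creating hybrids; and every in-degree-0 vertex of out-degree at
    least two receives a fresh stem.  On maximal chains the result coincides
    with :func:`decode_binary`.
    """
    chain = tuple(chain)
    verdict = poset.is_chain(chain)
    if not verdict:
        raise ValueError(f"not a chain (step {verdict.step}): {verdict.reason}")
    taxa = TaxonSet(tuple(system_union(chain[-1])))
    t = len(chain)
    b = _Builder(taxa)
    for i in range(1, t - 1):  # build level chain[i], rank r = i + 1
        r = i + 1
        prev_sys, cur_sys = chain[i - 1], chain[i]
        dest = {a: frozenset(d for d in cur_sys if a <= d) for a in prev_sys}
        groups: dict[frozenset, list[Cluster]] = {}
        for a in sorted_clusters(prev_sys):
            groups.setdefault(dest[a], []).append(a)
        # Phase 1: identify frontier vertices with equal destination sets.
        rep: dict[frozenset, int] = {}
        for h, members in groups.items():
            stems = [b.frontier.pop(a) for a in members]
            rep[h] = b.merge(stems) if len(stems) > 1 else stems[0]
        # Phase 2: wire hybrids.
        order = sorted(rep, key=lambda h: min(cluster_key(d) for d in h))
        for h in order:
            if len(h) < 2:
                continue
            u = rep[h]
            for h2 in order:
                if len(h2) == 1 and h2 <= h:
                    b.g.add_edge(rep[h2], u)
            b.rank[u] = r
        # Phase 3: stems above in-degree-0 vertices of out-degree >= 2.
        new_frontier: dict[Cluster, int] = {}
        for h in order:
            v = rep[h]
            if b.g.in_degree(v) > 0:
                continue
            if b.g.out_degree(v) >= 2:
                b.rank[v] = r
                v = b.add_stem(v)
            cv = _cluster_below(b.g, v, b.leaf_label)
            if cv not in cur_sys:
                raise ValueError(
                    f"construction produced frontier cluster {sorted(cv)} "
                    "outside the chain level; the input is not a valid chain"
                )
            new_frontier[cv] = v
        if set(new_frontier) != set(cur_sys):
            raise ValueError("frontier does not match the chain level")
        b.frontier = new_frontier
    return b.finish_root(t)


def _cluster_below(g: nx.DiGraph, v: int, leaf_label: Mapping[int, str]) -> Cluster:
    reach = nx.descendants(g, v) | {v}
    return frozenset(leaf_label[u] for u in reach if u in leaf_label)


def hardwired_clusters(net: RankedNetwork) -> dict[int, Cluster]:
    """The cluster of leaf labels reachable from each vertex."""
    return {v: _cluster_below(net.graph, v, net.leaf_label) for v in net.graph}


def encode(net: RankedNetwork) -> Chain:
    """Read the chain of cluster systems off a validated ranked network.

    Level ``i`` collects the hardwired clusters of all arc heads whose arc
    spans rank ``i``; the final level is ``{X}``.
    """
    verdict = validate_network(net)
    if not verdict:
        raise ValueError(f"invalid network: {verdict.reason}")
    t = net.rank[net.root]
    cv = hardwired_clusters(net)
    levels = []
    for i in range(1, t):
        levels.append(
            frozenset(
                cv[v]
                for (u, v) in net.graph.edges()
                if net.rank[u] > i >= net.rank[v]
            )
        )
    levels.append(frozenset((cv[net.root],)))
    return tuple(levels)


@dataclass(frozen=True)
class NetworkVerdict:
    ok: bool
    reason: str = ""
    vertices: tuple[int, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def validate_network(net: RankedNetwork) -> NetworkVerdict:
    """Check acyclicity, unique root, leaf labeling, tree-child, rank rules."""
    g = net.graph
    if not nx.is_directed_acyclic_graph(g):
        return NetworkVerdict(False, "graph has a directed cycle")
    roots = [v for v in g if g.in_degree(v) == 0]
    if roots != [net.root]:
        return NetworkVerdict(False, "root is not the unique in-degree-0 vertex",
                              tuple(roots))
    leaves = [v for v in g if g.out_degree(v) == 0]
    if set(leaves) != set(net.leaf_label):
        return NetworkVerdict(False, "leaves and leaf labels do not coincide")
    labels = list(net.leaf_label.values())
    if len(set(labels)) != len(labels):
        return NetworkVerdict(False, "leaf labels are not pairwise distinct")
    missing = [v for v in g if v not in net.rank]
    if missing:
        return NetworkVerdict(False, "vertex without a rank", tuple(missing))
    for v in leaves:
        if net.rank[v] != 1:
            return NetworkVerdict(False, "leaf with rank other than 1", (v,))
    t = net.rank[net.root]
    if t != max(net.rank.values()):
        return NetworkVerdict(False, "root does not carry the maximum rank")
    for (u, v) in g.edges():
        if net.rank[u] < net.rank[v]:
            return NetworkVerdict(False, "rank monotonicity violated", (u, v))
    for v in g:
        if g.out_degree(v) == 0:
            continue
        if not any(g.in_degree(c) <= 1 for c in g.successors(v)):
            return NetworkVerdict(False, "tree-child condition violated", (v,))
    if net.is_binary():
        for (u, v) in g.edges():
            hybrid = g.in_degree(v) >= 2
            if (net.rank[u] == net.rank[v]) != hybrid:
                return NetworkVerdict(
                    False, "binary rank tie must mark exactly the hybrid arcs", (u, v)
                )
    return NetworkVerdict(True)


def _is_partition(sys_: ClusterSystem) -> bool:
    clusters = list(sys_)
    return all(
        not (clusters[i] & clusters[j])
        for i in range(len(clusters))
        for j in range(i + 1, len(clusters))
    )


def is_ranked_tree(obj) -> bool:
    """Whether a maximal chain (or network) describes a binary ranked tree."""
    if isinstance(obj, RankedNetwork):
        return not obj.hybrid_vertices()
    chain = tuple(obj)
    verdict = is_maximal_chain(chain)
    if not verdict:
        raise ValueError(f"not a maximal chain: {verdict.reason}")
    return all(tag == "join" for tag in verdict.tags) and all(
        _is_partition(s) for s in chain
    )


def to_enewick(
    net: RankedNetwork, weights: Mapping[tuple[int, int], float] | None = None
) -> str:
    """Deterministic extended-Newick export.

    Hybrid vertices appear as two stubs sharing a ``#Hk`` tag, assigned in
    canonical traversal order; ranks are emitted as ``[r=<rank>]`` labels and
    weights as branch lengths when provided.  Children are ordered by the
    canonical key of their hardwired cluster.
    """
    verdict = validate_network(net)
    if not verdict:
        raise ValueError(f"invalid network: {verdict.reason}")
    g = net.graph
    cv = hardwired_clusters(net)
    hybrid_tag: dict[int, int] = {}
    seen: set[int] = set()

    def fmt(v: int, parent: int | None) -> str:
        label = net.leaf_label.get(v, "")
        rank_part = f"[r={net.rank[v]}]"
        weight_part = ""
        if weights is not None and parent is not None:
            weight_part = ":" + format(weights[(parent, v)], ".12g")
        if g.in_degree(v) >= 2:
            if v not in hybrid_tag:
                hybrid_tag[v] = len(hybrid_tag) + 1
            tag = f"#H{hybrid_tag[v]}"
            if v in seen:
                return f"{tag}{rank_part}{weight_part}"
            seen.add(v)
            inner = _children(v)
            return f"({inner}){label}{tag}{rank_part}{weight_part}"
        seen.add(v)
        if g.out_degree(v) == 0:
            return f"{label}{rank_part}{weight_part}"
        return f"({_children(v)}){label}{rank_part}{weight_part}"

    def _children(v: int) -> str:
        kids = sorted(g.successors(v), key=lambda c: cluster_key(cv[c]))
        return ",".join(fmt(c, v) for c in kids)

    return fmt(net.root, None) + ";"
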