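"""Discrete distances on binary ranked tree-child networks.

Two networks on the same taxon set are compared through their maximal
chains: the ranked Robinson-Foulds analogue is the symmetric difference of
the two chains viewed as sets of cluster systems, and a ranked nearest
neighbor interchange (rNNI on ranked trees, rNNI* on networks) replaces a
single interior system of the chain.  Shortest move sequences are found by
exact bidirectional breadth-first search; the move graph is connected, and a
constructive procedure transforms any network into a ranked tree by
eliminating reticulation steps one at a time from the bottom up.
"""

from __future__ import annotations

from typing import Sequence

from .chains import (
    Chain,
    ClusterSystem,
    cluster_key,
    is_maximal_chain,
    private_elements,
    relation,
    successors,
    system_union,
)
from .networks import is_ranked_tree, _is_partition

#: Default cap on the taxon count for breadth-first search over chains.
BFS_CAP = 6

MoveSequence = tuple  # tuple[Chain, ...]


def _check_chain(chain: Sequence[ClusterSystem]) -> Chain:
    chain = tuple(chain)
    verdict = is_maximal_chain(chain)
    if not verdict:
        raise ValueError(f"not a maximal chain: {verdict.reason}")
    return chain


def rf_distance(c1: Sequence[ClusterSystem], c2: Sequence[ClusterSystem]) -> int:
    """Symmetric difference of the two chains as sets of cluster systems."""
    c1, c2 = _check_chain(c1), _check_chain(c2)
    if system_union(c1[-1]) != system_union(c2[-1]):
        raise ValueError("chains are on different taxon sets")
    return len(set(c1) ^ set(c2))


def star_neighbors(chain: Sequence[ClusterSystem]) -> set[Chain]:
    """All chains differing from ``chain`` in exactly one interior position."""
    chain = _check_chain(chain)
    n = len(chain)
    out: set[Chain] = set()
    for i in range(1, n - 1):
        for cand in successors(chain[i - 1]):
            if cand != chain[i] and relation(cand, chain[i + 1]):
                out.add(chain[:i] + (cand,) + chain[i + 1 :])
    return out


def tree_neighbors(chain: Sequence[ClusterSystem]) -> set[Chain]:
    """Star neighbors restricted to ranked-tree (partition-only) chains."""
    chain = _check_chain(chain)
    if not is_ranked_tree(chain):
        raise ValueError("tree moves require a ranked-tree chain")
    return {
        nb for nb in star_neighbors(chain) if all(_is_partition(s) for s in nb)
    }


def _neighbor_fn(move_set: str):
    if move_set == "star":
        return star_neighbors
    if move_set == "tree":
        return tree_neighbors
    raise ValueError(f"unknown move set {move_set!r}")


def bfs_distance(
    c1: Sequence[ClusterSystem],
    c2: Sequence[ClusterSystem],
    move_set: str = "star",
    cap: int = BFS_CAP,
) -> tuple[int, MoveSequence]:
    """Exact shortest move count between two chains, with one witness walk.

    Bidirectional breadth-first search over the move graph; refuses taxon
    sets above ``cap`` because the state space is the full set of maximal
    chains.
    """
    c1, c2 = _check_chain(c1), _check_chain(c2)
    if system_union(c1[-1]) != system_union(c2[-1]):
        raise ValueError("chains are on different taxon sets")
    n = len(c1)
    if n > cap:
        raise ValueError(
            f"breadth-first search over {n} taxa exceeds the cap of {cap}; "
            "pass a larger cap explicitly to override"
        )
    neighbors = _neighbor_fn(move_set)
    if move_set == "tree" and not (is_ranked_tree(c1) and is_ranked_tree(c2)):
        raise ValueError("tree moves require ranked-tree chains")
    if c1 == c2:
        return 0, (c1,)

    parent_fwd: dict[Chain, Chain | None] = {c1: None}
    parent_bwd: dict[Chain, Chain | None] = {c2: None}
    frontier_fwd, frontier_bwd = {c1}, {c2}

    def path_through(meet: Chain) -> MoveSequence:
        left: list[Chain] = []
        node: Chain | None = meet
        while node is not None:
            left.append(node)
            node = parent_fwd[node]
        left.reverse()
        node = parent_bwd[meet]
        while node is not None:
            left.append(node)
            node = parent_bwd[node]
        return tuple(left)

    while frontier_fwd and frontier_bwd:
        # expand the smaller frontier
        if len(frontier_fwd) <= len(frontier_bwd):
            frontier, parents, others = frontier_fwd, parent_fwd, parent_bwd
            forward = True
        else:
            frontier, parents, others = frontier_bwd, parent_bwd, parent_fwd
            forward = False
        nxt: set[Chain] = set()
        for node in sorted(frontier):
            for nb in neighbors(node):
                if nb in parents:
                    continue
                parents[nb] = node
                if nb in others:
                    walk = path_through(nb)
                    return len(walk) - 1, walk
                nxt.add(nb)
        if forward:
            frontier_fwd = nxt
        else:
            frontier_bwd = nxt
    raise RuntimeError("move graph unexpectedly disconnected")


def _caterpillar_with_cherry(labels: Sequence[str], y: str, z: str) -> Chain:
    """The ranked-tree chain on ``labels`` whose rank-2 cherry is ``{y, z}``."""
    rest = sorted(x for x in labels if x not in (y, z))
    systems = [frozenset(frozenset((x,)) for x in labels)]
    grown = frozenset((y, z))
    cur = (systems[0] - {frozenset((y,)), frozenset((z,))}) | {grown}
    systems.append(cur)
    for x in rest:
        grown = grown | {x}
        cur = (cur - {frozenset((x,)), frozenset(grown - {x})}) | {grown}
        systems.append(cur)
    return tuple(systems)


def detangle_to_tree(chain: Sequence[ClusterSystem]) -> MoveSequence:
    """A move sequence from ``chain`` to a ranked-tree chain.

    While a reticulation step remains, take the lowest one in time order
    (the maximal step index); pick one private representative per cluster of
    the level it produced; restrict the upper part of the chain to those
    representatives, giving a ranked tree; walk that tree, by rNNI moves, to
    a caterpillar whose rank-2 cherry pairs the representatives of the two
    hybrid-product clusters; lift each move back to the full chain; and
    finally replace the reticulation level by the plain join of its first two
    clusters.  Every round removes one reticulation step.
    """
    chain = _check_chain(chain)
    n = len(chain)
    seq: list[Chain] = [chain]
    cur = chain
    while True:
        ret_index = None
        witness = None
        for j in range(n - 2, -1, -1):
            ws = relation(cur[j], cur[j + 1])
            rets = [w for w in ws if w.kind == "ret"]
            joins = [w for w in ws if w.kind == "join"]
            if rets and not joins:
                ret_index = j + 1  # position of the reticulation level
                witness = rets[0]
                break
        if ret_index is None:
            break
        i = ret_index
        a, b, c = witness.clusters
        priv = private_elements(cur[i])
        rep = {cl: min(priv[cl]) for cl in cur[i]}
        x_prime = sorted(rep.values())
        xp = frozenset(x_prime)

        def restrict(sys_: ClusterSystem) -> ClusterSystem:
            return frozenset(cl & xp for cl in sys_ if cl & xp)

        t1 = tuple(restrict(cur[k]) for k in range(i, n))
        y, z = rep[a | b], rep[b | c]
        t2 = _caterpillar_with_cherry(x_prime, y, z)
        _, walk = bfs_distance(t1, t2, move_set="tree", cap=len(x_prime))

        base = cur[i]

        def lift(sys_: ClusterSystem, base=base, rep=rep) -> ClusterSystem:
            return frozenset(
                frozenset().union(*(cl for cl in base if rep[cl] in d))
                for d in sys_
            )

        for step in walk[1:]:
            cur = cur[:i] + tuple(lift(s) for s in step)
            seq.append(cur)
        # replace the reticulation level by the join of A and B
        joined = (cur[i - 1] - {a, b}) | {a | b}
        cur = cur[:i] + (joined,) + cur[i + 1 :]
        seq.append(cur)
        if not is_maximal_chain(cur):
            raise RuntimeError("detangling produced an invalid chain")
    return tuple(seq)
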