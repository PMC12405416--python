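"""The graded poset of chain-realizable cluster systems.

The elements are all cluster systems on ``X`` that occur in some maximal
chain; one system precedes another when some maximal chain passes through
both, in that order.  The poset is bounded by the singleton partition below
and ``{X}`` above, and graded by ``n - |system|``.

Membership and comparability are decided by memoized breadth-first search
over the single-step successor relation, pruned by a structural necessary
condition: along any chain every later cluster is a union of earlier
clusters, so an intermediate system can only lead to a target if each of its
clusters sits inside a target cluster and each target cluster is covered by
the intermediate clusters it contains.  The private-element property serves
as a fast negative filter.  Search is exact at the desk scales this package
is meant for; no polynomial-time characterization is assumed.
"""

from __future__ import annotations

from typing import Iterator, Sequence

from .chains import (
    Chain,
    ChainVerdict,
    ClusterSystem,
    TaxonSet,
    cluster_key,
    has_private_elements,
    singleton_partition,
    successors,
    system_key,
    system_union,
)

#: Default cap on the taxon count for exhaustive chain enumeration.
ENUMERATION_CAP = 6

_member_cache: dict[ClusterSystem, bool] = {}
_reach_cache: dict[tuple[ClusterSystem, ClusterSystem], bool] = {}


def _compatible_with_target(sys_: ClusterSystem, target: ClusterSystem) -> bool:
    """Necessary condition for ``target`` to be reachable from ``sys_``."""
    for c in sys_:
        if not any(c <= d for d in target):
            return False
    for d in target:
        if frozenset().union(*(c for c in sys_ if c <= d)) != d:
            return False
    return True


def _reachable(start: ClusterSystem, target: ClusterSystem) -> bool:
    """Whether iterated single steps lead from ``start`` to ``target``."""
    if start == target:
        return True
    key = (start, target)
    if key in _reach_cache:
        return _reach_cache[key]
    found = False
    if len(start) > len(target) and _compatible_with_target(start, target):
        frontier = {start}
        while frontier:
            nxt_frontier: set[ClusterSystem] = set()
            for s in frontier:
                for nxt in successors(s):
                    if nxt == target:
                        found = True
                        break
                    if len(nxt) > len(target) and _compatible_with_target(nxt, target):
                        nxt_frontier.add(nxt)
                if found:
                    break
            if found:
                break
            frontier = nxt_frontier
    _reach_cache[key] = found
    return found


def is_member(sys_: ClusterSystem, taxa: TaxonSet | None = None) -> bool:
    """Whether ``sys_`` occurs in some maximal chain on its taxon set."""
    union = system_union(sys_)
    if taxa is not None and union != frozenset(taxa.labels):
        return False
    if len(union) < 2:
        return False
    if sys_ in _member_cache:
        return _member_cache[sys_]
    if not has_private_elements(sys_):
        _member_cache[sys_] = False
        return False
    start = frozenset(frozenset((x,)) for x in union)
    ok = _reachable(start, sys_)
    _member_cache[sys_] = ok
    return ok


def precedes(lo: ClusterSystem, hi: ClusterSystem) -> bool:
    """Whether some maximal chain contains ``lo`` and then ``hi`` (reflexive)."""
    if system_union(lo) != system_union(hi):
        return False
    if not is_member(lo):
        return False
    if lo == hi:
        return True
    # Any system reachable from a member extends upward to {X} by joins,
    # so reachability from a member suffices.
    return _reachable(lo, hi)


def comparable(a: ClusterSystem, b: ClusterSystem) -> bool:
    return precedes(a, b) or precedes(b, a)


def grade(sys_: ClusterSystem, taxa: TaxonSet | None = None) -> int:
    """The grade ``n - |sys_|`` of a poset member."""
    if not is_member(sys_, taxa):
        raise ValueError("system is not a member of the chain poset")
    n = len(system_union(sys_)) if taxa is None else taxa.n
    return n - len(sys_)


def is_chain(seq: Sequence[ClusterSystem]) -> ChainVerdict:
    """Check that ``seq`` is a chain in the poset (endpoints included)."""
    seq = tuple(seq)
    if len(seq) < 2:
        return ChainVerdict(False, reason="a chain has at least two systems")
    if len(seq[-1]) != 1:
        return ChainVerdict(False, reason="last system is not {X}")
    x = next(iter(seq[-1]))
    n = len(x)
    if len(seq) > n:
        return ChainVerdict(False, reason=f"a chain on {n} taxa has at most {n} systems")
    if seq[0] != frozenset(frozenset((lbl,)) for lbl in x):
        return ChainVerdict(False, reason="first system is not the singleton partition")
    if len(set(seq)) != len(seq):
        return ChainVerdict(False, reason="chain entries must be pairwise distinct")
    for i in range(len(seq) - 1):
        if not precedes(seq[i], seq[i + 1]):
            return ChainVerdict(
                False, reason="consecutive systems are not comparable in order", step=i + 1
            )
    return ChainVerdict(True)


def enumerate_maximal_chains(
    taxa: TaxonSet, cap: int = ENUMERATION_CAP
) -> Iterator[Chain]:
    """Yield every maximal chain on ``taxa`` once, in canonical order.

    Refuses taxon sets above ``cap`` because the number of chains grows as
    the product of per-level step counts (already ~400k at seven taxa).
    """
    if taxa.n > cap:
        raise ValueError(
            f"enumeration over {taxa.n} taxa exceeds the cap of {cap}; "
            "pass a larger cap explicitly to override"
        )

    def rec(prefix: list[ClusterSystem]) -> Iterator[Chain]:
        cur = prefix[-1]
        if len(cur) == 1:
            yield tuple(prefix)
            return
        for nxt in sorted(successors(cur), key=system_key):
            prefix.append(nxt)
            yield from rec(prefix)
            prefix.pop()

    yield from rec([singleton_partition(taxa)])


def clear_caches() -> None:
    _member_cache.clear()
    _reach_cache.clear()
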