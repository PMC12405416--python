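"""Cluster systems and the successor relations encoding ranked tree-child networks.

A binary ranked tree-child network (RTCN) on a taxon set ``X`` can be written
down, rank level by rank level, as a *maximal chain* of cluster systems: the
chain starts at the partition of ``X`` into singletons and ends at ``{X}``,
and each step either joins two clusters (a speciation event) or replaces three
clusters ``A, B, C`` by ``A | B`` and ``B | C`` (a hybridization event, with
``B`` the hybrid cluster).  This module provides the two step operations, the
successor relation and its witnesses, the private-element property that makes
the encoding decodable, and validation of maximal chains.

Clusters are plain ``frozenset`` objects holding taxon labels; cluster systems
are frozensets of clusters.  Canonical sort keys are provided so that all
output involving these unordered collections is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

Cluster = frozenset
ClusterSystem = frozenset
Chain = tuple  # tuple[ClusterSystem, ...]


class DegenerateStepError(ValueError):
    """A step whose result would not have exactly one cluster fewer."""


@dataclass(frozen=True)
class TaxonSet:
    """A finite set of at least two distinct taxon labels.

    Labels are stored in a fixed lexicographic order, which is the canonical
    order used for all deterministic output of the package.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(sorted(self.labels))
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be pairwise distinct")
        if len(labels) < 2:
            raise ValueError("a taxon set must contain at least two labels")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    @classmethod
    def of(cls, labels: Iterable[str]) -> "TaxonSet":
        return cls(tuple(labels))


def cluster(labels: Iterable[str]) -> Cluster:
    c = frozenset(labels)
    if not c:
        raise ValueError("a cluster must be non-empty")
    return c


def system(clusters: Iterable[Iterable[str]]) -> ClusterSystem:
    sys_ = frozenset(cluster(c) for c in clusters)
    if not sys_:
        raise ValueError("a cluster system must be non-empty")
    return sys_


def cluster_key(c: Cluster) -> tuple:
    """Canonical sort key for a cluster: (min label, size, sorted labels)."""
    return (min(c), len(c), tuple(sorted(c)))


def sorted_clusters(sys_: ClusterSystem) -> list[Cluster]:
    return sorted(sys_, key=cluster_key)


def system_key(sys_: ClusterSystem) -> tuple:
    return tuple(cluster_key(c) for c in sorted_clusters(sys_))


def singleton_partition(taxa: TaxonSet) -> ClusterSystem:
    return frozenset(frozenset((x,)) for x in taxa)


def root_system(taxa: TaxonSet) -> ClusterSystem:
    return frozenset((frozenset(taxa.labels),))


def system_union(sys_: ClusterSystem) -> frozenset:
    return frozenset().union(*sys_)


@dataclass(frozen=True)
class Witness:
    """A decomposition certifying that one system succeeds another.

    ``kind`` is ``"join"`` with clusters ``(A, B)`` (unordered, stored in
    canonical order) or ``"ret"`` with clusters ``(A, B, C)`` where ``B`` is
    the hybrid middle cluster and the ``A``/``C`` symmetry is collapsed by
    canonical order.
    """

    kind: str
    clusters: tuple[Cluster, ...]

    def __post_init__(self) -> None:
        if self.kind == "join":
            a, b = self.clusters
            if cluster_key(b) < cluster_key(a):
                object.__setattr__(self, "clusters", (b, a))
        elif self.kind == "ret":
            a, b, c = self.clusters
            if cluster_key(c) < cluster_key(a):
                object.__setattr__(self, "clusters", (c, b, a))
        else:
            raise ValueError(f"unknown witness kind {self.kind!r}")


def _require_member(sys_: ClusterSystem, c: Cluster) -> None:
    if c not in sys_:
        raise ValueError(f"cluster {sorted(c)} is not a member of the system")


def apply_join(sys_: ClusterSystem, a: Cluster, b: Cluster) -> ClusterSystem:
    """Replace clusters ``a`` and ``b`` of ``sys_`` by their union."""
    if a == b:
        raise ValueError(f"join requires two distinct clusters, got {sorted(a)} twice")
    _require_member(sys_, a)
    _require_member(sys_, b)
    out = (sys_ - {a, b}) | {a | b}
    if len(out) != len(sys_) - 1:
        raise DegenerateStepError(
            f"union {sorted(a | b)} collides with an existing cluster"
        )
    return out


def apply_reticulate(
    sys_: ClusterSystem, a: Cluster, b: Cluster, c: Cluster
) -> ClusterSystem:
    """Replace ``a``, ``b``, ``c`` by ``a | b`` and ``b | c`` (``b`` hybrid)."""
    if len({a, b, c}) != 3:
        raise ValueError("reticulation requires three pairwise distinct clusters")
    for x in (a, b, c):
        _require_member(sys_, x)
    out = (sys_ - {a, b, c}) | {a | b, b | c}
    if len(out) != len(sys_) - 1:
        raise DegenerateStepError(
            "reticulation result collides with an existing cluster"
        )
    return out


def apply_witness(sys_: ClusterSystem, w: Witness) -> ClusterSystem:
    if w.kind == "join":
        return apply_join(sys_, *w.clusters)
    return apply_reticulate(sys_, *w.clusters)


def successor_moves(sys_: ClusterSystem) -> Iterator[tuple[Witness, ClusterSystem]]:
    """All (witness, result) pairs of single steps, in canonical order.

    Degenerate applications (where the result would lose more than one
    cluster) are skipped.
    """
    clusters = sorted_clusters(sys_)
    for a, b in combinations(clusters, 2):
        try:
            yield Witness("join", (a, b)), apply_join(sys_, a, b)
        except DegenerateStepError:
            continue
    for b in clusters:
        rest = [c for c in clusters if c != b]
        for a, c in combinations(rest, 2):
            try:
                yield Witness("ret", (a, b, c)), apply_reticulate(sys_, a, b, c)
            except DegenerateStepError:
                continue


def successors(sys_: ClusterSystem) -> set[ClusterSystem]:
    """All distinct systems one step below ``sys_``."""
    if len(sys_) == 1:
        raise ValueError("no successors of {X}: the system is already trivial")
    return {res for _, res in successor_moves(sys_)}


def relation(sys_: ClusterSystem, nxt: ClusterSystem) -> list[Witness]:
    """Every witness whose application to ``sys_`` yields ``nxt``.

    The empty list is the negative answer: ``sys_`` does not precede ``nxt``
    by a single step.
    """
    if len(sys_) == 1 or len(nxt) != len(sys_) - 1:
        return []
    return [w for w, res in successor_moves(sys_) if res == nxt]


def private_elements(sys_: ClusterSystem) -> dict[Cluster, frozenset]:
    """For each cluster, the labels appearing in no other cluster of ``sys_``.

    Systems occurring in maximal chains have a non-empty private set for
    every cluster; an empty value flags a violation of that property.
    """
    out: dict[Cluster, frozenset] = {}
    for c in sys_:
        others = frozenset().union(*(d for d in sys_ if d != c)) if len(sys_) > 1 else frozenset()
        out[c] = c - others
    return out


def has_private_elements(sys_: ClusterSystem) -> bool:
    return all(priv for priv in private_elements(sys_).values())


@dataclass(frozen=True)
class ChainVerdict:
    """Outcome of a chain validation, with per-step tags on success."""

    ok: bool
    tags: tuple[str, ...] = ()
    reason: str = ""
    step: int | None = None  # 1-based index of the first failing step

    def __bool__(self) -> bool:
        return self.ok


def is_maximal_chain(seq: Sequence[ClusterSystem]) -> ChainVerdict:
    """Check that ``seq`` is a maximal chain; report join/ret tags per step."""
    seq = tuple(seq)
    if not seq:
        return ChainVerdict(False, reason="empty sequence")
    if len(seq[-1]) != 1:
        return ChainVerdict(False, reason="last system is not {X}")
    x = next(iter(seq[-1]))
    n = len(x)
    if n < 2:
        return ChainVerdict(False, reason="taxon set must have at least two labels")
    if len(seq) != n:
        return ChainVerdict(False, reason=f"expected {n} systems, got {len(seq)}")
    if seq[0] != frozenset(frozenset((lbl,)) for lbl in x):
        return ChainVerdict(False, reason="first system is not the singleton partition")
    tags = []
    for i in range(len(seq) - 1):
        witnesses = relation(seq[i], seq[i + 1])
        if not witnesses:
            return ChainVerdict(
                False, reason="consecutive systems are not related by a step", step=i + 1
            )
        tags.append("join" if any(w.kind == "join" for w in witnesses) else "ret")
    return ChainVerdict(True, tags=tuple(tags))


def _disjoint_from_rest(sys_: ClusterSystem, c: Cluster) -> bool:
    return all(not (c & d) for d in sys_ if d != c)


def cactus_relation(sys_: ClusterSystem, nxt: ClusterSystem) -> list[Witness]:
    """Witnesses of :func:`relation` satisfying the ranked-cactus restriction.

    A join ``(A, B)`` is kept when ``A`` and ``B`` overlap, or one of them is
    disjoint from every other cluster of ``sys_``.  A reticulation
    ``(A, B, C)`` is kept only when each of the three clusters is disjoint
    from every other cluster of ``sys_``.
    """
    kept = []
    for w in relation(sys_, nxt):
        if w.kind == "join":
            a, b = w.clusters
            if (a & b) or _disjoint_from_rest(sys_, a) or _disjoint_from_rest(sys_, b):
                kept.append(w)
        else:
            if all(_disjoint_from_rest(sys_, c) for c in w.clusters):
                kept.append(w)
    return kept
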