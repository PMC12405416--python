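"""Random generators and small canonical examples.

The chain generator replays the generative process for binary ranked
tree-child networks: at every level with at least three frontier clusters it
performs a reticulation with probability ``p_ret`` (choosing uniformly among
the ``3 * C(k, 3)`` witness choices, i.e. middle cluster first, then the
unordered outer pair), otherwise a join chosen uniformly among the
``C(k, 2)`` pairs.  A single seeded pseudo-random stream drives each call;
the choice order (step type, then witness) is fixed, so seeds are portable
across platforms.

``worked_examples`` returns a handful of small, hand-checkable objects --
chains with zero, one and two hybrids plus a weighted point -- that are used
throughout the test suite and the documentation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

from .chains import (
    Chain,
    TaxonSet,
    apply_join,
    apply_reticulate,
    singleton_partition,
    sorted_clusters,
    system,
)
from .orthant import EtcnPoint, make_point


@dataclass(frozen=True)
class SimConfig:
    """Generator settings: taxon count, event rates and the seed.

    ``p_ret`` is the per-step probability of a reticulation (where one is
    possible), ``p_skip`` the probability that an interior chain level is
    dropped from a point's support, and ``rate`` the mean of the exponential
    draw for surviving rank differences.
    """

    n: int = 5
    p_ret: float = 0.25
    p_skip: float = 0.3
    rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 <= self.p_ret <= 1.0:
            raise ValueError("p_ret must lie in [0, 1]")
        if not 0.0 <= self.p_skip < 1.0:
            raise ValueError("p_skip must lie in [0, 1)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def default_taxa(n: int) -> TaxonSet:
    """Single-letter labels a, b, c, ... for up to 26 taxa."""
    if n > 26:
        raise ValueError("default labels support at most 26 taxa")
    return TaxonSet(tuple("abcdefghijklmnopqrstuvwxyz"[:n]))


def random_maximal_chain(cfg: SimConfig, rng: random.Random | None = None) -> Chain:
    """A random maximal chain drawn from the generative process."""
    rng = rng if rng is not None else random.Random(cfg.seed)
    taxa = default_taxa(cfg.n)
    cur = singleton_partition(taxa)
    out = [cur]
    while len(cur) > 1:
        clusters = sorted_clusters(cur)
        k = len(clusters)
        if k >= 3 and rng.random() < cfg.p_ret:
            mid = clusters[rng.randrange(k)]
            rest = [c for c in clusters if c != mid]
            pairs = list(combinations(range(k - 1), 2))
            i, j = pairs[rng.randrange(len(pairs))]
            cur = apply_reticulate(cur, rest[i], mid, rest[j])
        else:
            pairs = list(combinations(range(k), 2))
            i, j = pairs[rng.randrange(len(pairs))]
            cur = apply_join(cur, clusters[i], clusters[j])
        out.append(cur)
    return tuple(out)


def random_point(cfg: SimConfig, rng: random.Random | None = None) -> EtcnPoint:
    """A random orthant-space point on a random maximal chain.

    Interior levels are dropped with probability ``p_skip`` (the chain
    endpoints are never dropped); surviving levels get independent
    exponential rank differences with mean ``rate``.
    """
    rng = rng if rng is not None else random.Random(cfg.seed)
    chain = random_maximal_chain(cfg, rng)
    values = []
    for j in range(1, len(chain)):  # 1-based positions 1 .. n-1
        if j > 1 and rng.random() < cfg.p_skip:
            values.append(0.0)
        else:
            values.append(rng.expovariate(1.0 / cfg.rate))
    return make_point(chain, values)


def worked_examples() -> dict:
    """Small canonical objects used across the tests and docs.

    - ``hybrid_chain``: four taxa, one reticulation (the smallest network
      chain with overlapping clusters).
    - ``tree_pair``: two five-taxon ranked-tree chains differing in exactly
      one position (a single rNNI apart).
    - ``wide_chain``: a length-4 chain on eight taxa that skips levels,
      yielding a non-binary network.
    - ``nonbinary_chain``: a four-taxon chain whose single interior level
      has two overlapping clusters, forcing a non-binary hybrid vertex.
    - ``weighted_point``: a five-taxon point with one reticulation and
      rank differences (1.3, 2.0, 1.9, 0.8).
    """
    s = system
    hybrid_chain = (
        s([["a"], ["b"], ["c"], ["d"]]),
        s([["a", "b"], ["c"], ["d"]]),
        s([["a", "b", "c"], ["c", "d"]]),
        s([["a", "b", "c", "d"]]),
    )
    tree_a = (
        s([["a"], ["b"], ["c"], ["d"], ["e"]]),
        s([["a", "b"], ["c"], ["d"], ["e"]]),
        s([["a", "b"], ["c"], ["d", "e"]]),
        s([["a", "b", "c"], ["d", "e"]]),
        s([["a", "b", "c", "d", "e"]]),
    )
    tree_b = (
        tree_a[0],
        s([["a"], ["b"], ["c"], ["d", "e"]]),
    ) + tree_a[2:]
    wide_chain = (
        s([[x] for x in "abcdefgh"]),
        s([["a", "b", "c", "d"], ["c", "d", "e"], ["f"], ["g", "h"]]),
        s([["a", "b", "c", "d", "e"], ["f", "g", "h"]]),
        s([list("abcdefgh")]),
    )
    nonbinary_chain = (
        s([["a"], ["b"], ["c"], ["d"]]),
        s([["a", "b", "c"], ["b", "c", "d"]]),
        s([["a", "b", "c", "d"]]),
    )
    weighted_chain = (
        s([["a"], ["b"], ["c"], ["d"], ["e"]]),
        s([["a", "b"], ["b", "c"], ["d"], ["e"]]),
        s([["a", "b", "c"], ["b", "c", "d"], ["e"]]),
        s([["a", "b", "c"], ["b", "c", "d", "e"]]),
        s([["a", "b", "c", "d", "e"]]),
    )
    return {
        "hybrid_chain": hybrid_chain,
        "tree_pair": (tree_a, tree_b),
        "wide_chain": wide_chain,
        "nonbinary_chain": nonbinary_chain,
        "weighted_chain": weighted_chain,
        "weighted_point": make_point(weighted_chain, (1.3, 2.0, 1.9, 0.8)),
    }
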