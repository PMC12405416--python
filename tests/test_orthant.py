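"""Orthant-space points, the equidistant weighting and exact geodesics.

The geodesic implementation is cross-checked against an independent oracle
that enumerates *all* ordered block partitions of the two disjoint support
parts satisfying the path-space conditions (earlier B-blocks comparable with
later A-blocks; non-decreasing norm ratios) and minimizes the path-length
formula directly.
"""

import math
import random
from itertools import combinations, permutations

import pytest

from rtcnspace import (
    EtcnPoint,
    geodesic_distance,
    geodesic_point,
    lower_and_upper_bounds,
    make_point,
    point_from_network,
    point_to_network,
    system,
    validate_point,
)
from rtcnspace.poset import precedes
from rtcnspace.simulate import SimConfig, default_taxa, random_point

TOL = 1e-9


def s(*clusters):
    return system(clusters)


def _ordered_partitions(items):
    """All ordered partitions of ``items`` into non-empty blocks."""
    items = list(items)
    if not items:
        yield ()
        return
    for k in range(1, len(items) + 1):
        for perm in permutations(items):
            for cuts in combinations(range(1, len(items)), k - 1):
                bounds = (0,) + cuts + (len(items),)
                blocks = tuple(
                    frozenset(perm[bounds[i] : bounds[i + 1]]) for i in range(k)
                )
                yield blocks


def oracle_distance(p, q):
    """Brute-force minimum over all valid ordered path-space partitions.

    A support system with no incomparable partner on the other side varies
    independently along any path (it behaves like a shared coordinate with
    opposite value zero) and is removed before the partition search; every
    remaining item then has at least one incomparability constraint.
    """
    shared = p.support & q.support
    sq_common = sum((p.coords[x] - q.coords[x]) ** 2 for x in shared)
    a_all = sorted(p.support - q.support, key=lambda x: sorted(map(sorted, x)))
    b_all = sorted(q.support - p.support, key=lambda x: sorted(map(sorted, x)))
    comparable = {
        (a, b): precedes(a, b) or precedes(b, a) for a in a_all for b in b_all
    }
    a_items = [a for a in a_all if not all(comparable[(a, b)] for b in b_all)]
    b_items = [b for b in b_all if not all(comparable[(a, b)] for a in a_all)]
    sq_common += sum(p.coords[a] ** 2 for a in a_all if a not in a_items)
    sq_common += sum(q.coords[b] ** 2 for b in b_all if b not in b_items)
    if not a_items or not b_items:
        return math.sqrt(
            sq_common
            + sum(p.coords[x] ** 2 for x in a_items)
            + sum(q.coords[x] ** 2 for x in b_items)
        )

    def norm(block, coords):
        return math.sqrt(sum(coords[x] ** 2 for x in block))

    best = None
    a_parts = {
        blocks
        for blocks in _ordered_partitions(a_items)
        if blocks
    }
    b_parts = {
        blocks
        for blocks in _ordered_partitions(b_items)
        if blocks
    }
    for ablocks in a_parts:
        for bblocks in b_parts:
            if len(ablocks) != len(bblocks):
                continue
            # condition (i): earlier B-blocks comparable with later A-blocks
            if any(
                not comparable[(a, b)]
                for i in range(len(ablocks))
                for j in range(i)
                for a in ablocks[i]
                for b in bblocks[j]
            ):
                continue
            # condition (ii): non-decreasing norm ratios
            ratios = [
                norm(a, p.coords) / norm(b, q.coords)
                for a, b in zip(ablocks, bblocks)
            ]
            if any(r1 > r2 + TOL for r1, r2 in zip(ratios, ratios[1:])):
                continue
            length_sq = sum(
                (norm(a, p.coords) + norm(b, q.coords)) ** 2
                for a, b in zip(ablocks, bblocks)
            )
            if best is None or length_sq < best:
                best = length_sq
    return math.sqrt(sq_common + best)


def _random_points(n, count, p_skip=0.4, seed=4):
    rng = random.Random(seed + n)
    cfg = SimConfig(n=n, p_ret=0.35, p_skip=p_skip, seed=0)
    return [random_point(cfg, rng) for _ in range(count)]


class TestPoints:
    def test_printed_weighted_point(self, examples):
        p = examples["weighted_point"]
        assert p.coords[s("ab", "bc", "d", "e")] == 2.0
        assert p.coords[s("abc", "bcd", "e")] == 1.9
        validate_point(p)

    def test_all_zero_values_give_origin(self, examples):
        p = make_point(examples["weighted_chain"], (0, 0, 0, 0))
        assert p.coords == {}

    def test_zero_value_drops_level_from_support(self, examples):
        p = make_point(examples["weighted_chain"], (1.3, 0.0, 1.9, 0.8))
        assert s("ab", "bc", "d", "e") not in p.support
        assert len(p.support) == 3

    def test_negative_value_rejected(self, examples):
        with pytest.raises(ValueError, match="non-negative"):
            make_point(examples["weighted_chain"], (1, -1, 1, 1))

    def test_length_mismatch_rejected(self, examples):
        with pytest.raises(ValueError, match="expected"):
            make_point(examples["weighted_chain"], (1, 1))

    def test_incomparable_support_rejected(self):
        taxa = default_taxa(4)
        bad = EtcnPoint(taxa, {s("ab", "c", "d"): 1.0, s("ac", "b", "d"): 1.0})
        with pytest.raises(ValueError, match="ordered|grade"):
            validate_point(bad)


class TestNetworkConversion:
    def test_printed_point_path_sums(self, examples):
        net, w = point_to_network(examples["weighted_point"])
        total = 1.3 + 2.0 + 1.9 + 0.8
        for leaf in net.leaves:
            import networkx as nx

            for path in nx.all_simple_paths(net.graph, net.root, leaf):
                path_w = sum(w[(u, v)] for u, v in zip(path, path[1:]))
                assert path_w == pytest.approx(total)

    def test_roundtrip_recovers_coordinates(self, examples):
        p = examples["weighted_point"]
        net, w = point_to_network(p)
        back = point_from_network(net, w)
        assert back.support == p.support
        assert back.coords[s("ab", "bc", "d", "e")] == pytest.approx(2.0)
        for sys_, val in p.coords.items():
            assert back.coords[sys_] == pytest.approx(val)

    def test_origin_roundtrip(self, examples):
        p = make_point(examples["weighted_chain"], (0, 0, 0, 0))
        net, w = point_to_network(p)
        assert all(val == 0 for val in w.values())
        assert point_from_network(net, w).coords == {}

    def test_perturbed_weight_rejected(self, examples):
        net, w = point_to_network(examples["weighted_point"])
        arc = max(w, key=lambda a: w[a])
        w[arc] += 0.5
        with pytest.raises(ValueError, match="equidistant|rank-consistent"):
            point_from_network(net, w)

    def test_random_points_roundtrip(self):
        for p in _random_points(5, count=40):
            net, w = point_to_network(p)
            back = point_from_network(net, w)
            assert back.support == p.support
            for sys_, val in p.coords.items():
                assert back.coords[sys_] == pytest.approx(val)


class TestGeodesicDistance:
    def test_zero_at_equal_points(self, examples):
        p = examples["weighted_point"]
        assert geodesic_distance(p, p).distance == 0.0

    def test_single_orthant_euclidean(self):
        taxa = default_taxa(4)
        sys_ = s("ab", "c", "d")
        p = EtcnPoint(taxa, {sys_: 1.0})
        q = EtcnPoint(taxa, {sys_: 3.0})
        assert geodesic_distance(p, q).distance == pytest.approx(2.0)

    def test_incomparable_supports_cone_path(self):
        taxa = default_taxa(4)
        p = EtcnPoint(taxa, {s("ab", "c", "d"): 1.0})
        q = EtcnPoint(taxa, {s("ac", "b", "d"): 1.0})
        res = geodesic_distance(p, q)
        assert res.distance == pytest.approx(2.0)
        lower, upper = lower_and_upper_bounds(p, q)
        assert lower == pytest.approx(math.sqrt(2))
        assert upper == pytest.approx(2.0)

    def test_nested_support_is_euclidean(self):
        for p in _random_points(5, count=10, seed=11):
            sub = dict(list(p.coords.items())[:-1]) if p.coords else {}
            q = EtcnPoint(p.taxa, sub)
            expected = math.sqrt(
                sum(
                    (p.coords.get(x, 0.0) - q.coords.get(x, 0.0)) ** 2
                    for x in p.support | q.support
                )
            )
            assert geodesic_distance(p, q).distance == pytest.approx(expected)

    @pytest.mark.parametrize("n", [4, 5])
    def test_matches_brute_force_oracle(self, n):
        pts = _random_points(n, count=20, seed=99)
        rng = random.Random(n)
        pairs = [rng.sample(pts, 2) for _ in range(30)]
        for p, q in pairs:
            if len(p.support - q.support) > 4 or len(q.support - p.support) > 4:
                continue
            assert geodesic_distance(p, q).distance == pytest.approx(
                oracle_distance(p, q)
            )

    def test_metric_axioms_on_sampled_triples(self):
        pts = _random_points(4, count=15, seed=5) + _random_points(5, count=15, seed=6)
        rng = random.Random(1)
        for _ in range(200):
            group = pts[:15] if rng.random() < 0.5 else pts[15:]
            p, q, r = rng.sample(group, 3)
            dpq = geodesic_distance(p, q).distance
            assert dpq == pytest.approx(geodesic_distance(q, p).distance)
            assert dpq >= 0 and (dpq < TOL) == (p == q)
            assert dpq <= geodesic_distance(p, r).distance + geodesic_distance(
                r, q
            ).distance + 1e-8

    def test_bound_sandwich(self):
        pts = _random_points(5, count=25, seed=13)
        rng = random.Random(2)
        for _ in range(60):
            p, q = rng.sample(pts, 2)
            lower, upper = lower_and_upper_bounds(p, q)
            d = geodesic_distance(p, q).distance
            assert lower - 1e-9 <= d <= upper + 1e-9

    def test_taxon_mismatch(self, examples):
        p = examples["weighted_point"]
        q = EtcnPoint(default_taxa(4), {})
        with pytest.raises(ValueError, match="taxon"):
            geodesic_distance(p, q)


class TestGeodesicPoint:
    def test_endpoints(self, examples):
        p = examples["weighted_point"]
        q = _random_points(5, count=1, seed=8)[0]
        assert geodesic_point(p, q, 0.0) == p
        assert geodesic_point(p, q, 1.0) == q

    def test_midpoint_halves_distance(self):
        pts = _random_points(5, count=16, seed=21)
        rng = random.Random(9)
        for _ in range(25):
            p, q = rng.sample(pts, 2)
            d = geodesic_distance(p, q).distance
            m = geodesic_point(p, q, 0.5)
            assert geodesic_distance(p, m).distance == pytest.approx(d / 2)
            assert geodesic_distance(m, q).distance == pytest.approx(d / 2)

    def test_cone_midpoint_is_origin(self):
        taxa = default_taxa(4)
        p = EtcnPoint(taxa, {s("ab", "c", "d"): 1.0})
        q = EtcnPoint(taxa, {s("ac", "b", "d"): 1.0})
        assert geodesic_point(p, q, 0.5).coords == {}

    def test_support_containment(self):
        pts = _random_points(5, count=12, seed=30)
        rng = random.Random(12)
        for _ in range(20):
            p, q = rng.sample(pts, 2)
            for frac in (0.25, 0.5, 0.75):
                m = geodesic_point(p, q, frac)
                assert m.support <= p.support | q.support
                validate_point(m)

    def test_tree_points_stay_trees(self):
        """Geodesics between ultrametric-tree points stay in tree space."""

        def is_partition_point(pt):
            return all(
                not (c1 & c2)
                for sys_ in pt.support
                for c1, c2 in combinations(sys_, 2)
            )

        rng = random.Random(17)
        cfg = SimConfig(n=5, p_ret=0.0, p_skip=0.3, seed=0)
        pts = [random_point(cfg, rng) for _ in range(14)]
        assert all(is_partition_point(p) for p in pts)
        for _ in range(20):
            p, q = rng.sample(pts, 2)
            for frac in (0.2, 0.5, 0.8):
                assert is_partition_point(geodesic_point(p, q, frac))

    def test_fraction_out_of_range(self, examples):
        p = examples["weighted_point"]
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            geodesic_point(p, p, 1.5)
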