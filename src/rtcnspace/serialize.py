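"""Canonical JSON interchange for chains, networks, points and move walks.

Every writer emits clusters as sorted label lists and systems as lists of
clusters sorted by (min label, size, lexicographic), so output is
deterministic and byte-stable under read/write round trips.  Readers
validate structure (distinct taxa, clusters over the taxon set, no duplicate
clusters) and raise ``ValueError`` with a descriptive message on malformed
input.
"""

from __future__ import annotations

import json
from typing import Any, Mapping, Sequence

import networkx as nx

from .chains import (
    Chain,
    ClusterSystem,
    TaxonSet,
    cluster,
    cluster_key,
    sorted_clusters,
    system,
    system_union,
)
from .networks import RankedNetwork
from .orthant import EtcnPoint


def dumps(obj: Any) -> str:
    return json.dumps(obj, indent=2) + "\n"


def system_to_obj(sys_: ClusterSystem) -> list[list[str]]:
    return [sorted(c) for c in sorted_clusters(sys_)]


def system_from_obj(obj: Sequence[Sequence[str]], taxa: TaxonSet) -> ClusterSystem:
    clusters = [cluster(c) for c in obj]
    for c in clusters:
        if not c <= frozenset(taxa.labels):
            raise ValueError(f"cluster {sorted(c)} is not a subset of the taxa")
    if len(set(clusters)) != len(clusters):
        raise ValueError("duplicate clusters in a system")
    return system(obj)


def chain_to_obj(chain: Sequence[ClusterSystem]) -> dict:
    taxa = sorted(system_union(chain[-1]))
    return {"taxa": taxa, "systems": [system_to_obj(s) for s in chain]}


def chain_from_obj(obj: Mapping) -> Chain:
    taxa = TaxonSet(tuple(obj["taxa"]))
    return tuple(system_from_obj(s, taxa) for s in obj["systems"])


def network_to_obj(
    net: RankedNetwork, weights: Mapping[tuple[int, int], float] | None = None
) -> dict:
    out = {
        "vertices": sorted(net.graph.nodes()),
        "arcs": [list(e) for e in net.arcs],
        "root": net.root,
        "leaves": {str(v): net.leaf_label[v] for v in sorted(net.leaf_label)},
        "rank": {str(v): net.rank[v] for v in sorted(net.rank)},
    }
    if weights is not None:
        out["weights"] = [[u, v, weights[(u, v)]] for (u, v) in net.arcs]
    return out


def network_from_obj(obj: Mapping) -> tuple[RankedNetwork, dict | None]:
    g = nx.DiGraph()
    g.add_nodes_from(obj["vertices"])
    g.add_edges_from((u, v) for u, v in obj["arcs"])
    net = RankedNetwork(
        g,
        obj["root"],
        {int(k): v for k, v in obj["leaves"].items()},
        {int(k): v for k, v in obj["rank"].items()},
    )
    weights = None
    if "weights" in obj:
        weights = {(u, v): w for u, v, w in obj["weights"]}
    return net, weights


def point_to_obj(p: EtcnPoint) -> dict:
    entries = sorted(
        p.coords.items(), key=lambda kv: (-len(kv[0]), tuple(cluster_key(c) for c in sorted_clusters(kv[0])))
    )
    return {
        "taxa": list(p.taxa.labels),
        "coords": [
            {"system": system_to_obj(s), "value": v} for s, v in entries
        ],
    }


def point_from_obj(obj: Mapping) -> EtcnPoint:
    taxa = TaxonSet(tuple(obj["taxa"]))
    coords = {}
    for entry in obj["coords"]:
        s = system_from_obj(entry["system"], taxa)
        v = float(entry["value"])
        if v < 0:
            raise ValueError("coordinates must be non-negative")
        if v > 0:
            coords[s] = v
    return EtcnPoint(taxa, coords)


def moveseq_to_obj(seq: Sequence[Sequence[ClusterSystem]]) -> dict:
    taxa = sorted(system_union(seq[0][-1]))
    return {
        "taxa": taxa,
        "chains": [[system_to_obj(s) for s in chain] for chain in seq],
    }


def moveseq_from_obj(obj: Mapping) -> tuple:
    taxa = TaxonSet(tuple(obj["taxa"]))
    return tuple(
        tuple(system_from_obj(s, taxa) for s in chain) for chain in obj["chains"]
    )
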