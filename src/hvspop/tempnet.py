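"""Temporal haplotype networks.

Each time period is a *layer*: sequences are collapsed into haplotypes by
exact identity (an ``N`` matches any base when the carrying sequence has at
most two Ns and everything else agrees), the within-layer topology is the
minimum spanning network (all co-minimal edges of any minimum spanning
tree, so ties are retained) weighted by nucleotide differences, and
identical haplotypes in different layers are joined by cross-layer identity
edges.  This layered construction makes haplotype continuity across time
directly readable: a haplotype persisting from an older to a younger layer
is a vertical edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .core import SequenceBlock, sequence_distance

__all__ = ["TemporalNetwork", "build_tempnet", "shared_haplotype_report"]

#: Maximum N count for missing-data-tolerant identity collapse.
MAX_N_FOR_IDENTITY = 2


@dataclass
class TemporalNetwork:
    """Layered haplotype network.

    ``graph`` nodes are ``(layer_label, haplotype_index)`` with attributes
    ``layer``, ``age_bp``, ``count``, ``sequence`` and ``members``; edges
    carry ``kind`` ("within" weighted by differences, or "identity") .
    """

    layers: list[tuple[str, float]]
    graph: nx.Graph

    def layer_nodes(self, label: str) -> list[tuple[str, int]]:
        return [n for n, d in self.graph.nodes(data=True) if d["layer"] == label]

    def cross_layer_edges(self) -> list[tuple]:
        return [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d["kind"] == "identity"
        ]

    def shared_counts(self) -> dict[tuple[str, str], int]:
        """Number of haplotypes of layer a also present in layer b."""
        out: dict[tuple[str, str], int] = {}
        for (la, _), (lb, _) in self.cross_layer_edges():
            for key in ((la, lb), (lb, la)):
                out[key] = out.get(key, 0) + 1
        return out


def _identical(a: str, b: str) -> bool:
    """N-tolerant identity: equal everywhere except N positions, and the
    N-carrying sequence has at most MAX_N_FOR_IDENTITY Ns."""
    if a == b:
        return True
    na, nb = a.count("N"), b.count("N")
    if min(na, nb) > MAX_N_FOR_IDENTITY and max(na, nb) > MAX_N_FOR_IDENTITY:
        return False
    if not (na <= MAX_N_FOR_IDENTITY or nb <= MAX_N_FOR_IDENTITY):
        return False
    if len(a) != len(b):
        return False
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def _collapse_layer(block: SequenceBlock) -> list[dict]:
    """Group a layer's sequences into haplotypes (N-tolerant)."""
    groups: list[dict] = []
    exact: dict[str, int] = {}
    for label, seq in zip(block.labels, block.sequences):
        gi = exact.get(seq)
        if gi is None:
            for i, g in enumerate(groups):
                if _identical(seq, g["sequence"]):
                    gi = i
                    break
        if gi is None:
            gi = len(groups)
            groups.append({"sequence": seq, "members": []})
            exact[seq] = gi
        g = groups[gi]
        g["members"].append(label)
        if "N" in g["sequence"] and "N" not in seq:
            g["sequence"] = seq  # prefer an N-free representative
    return groups


def _msn_edges(distances: dict[tuple[int, int], int], n: int) -> list[tuple[int, int, int]]:
    """Minimum spanning network: all edges co-minimal with some MST.

    Kruskal by weight class: an edge of weight w is kept iff its endpoints
    lie in different components of the graph restricted to weights < w.
    """
    edges = sorted(distances.items(), key=lambda kv: kv[1])
    import networkx as nx

    uf = nx.utils.UnionFind(range(n))
    kept: list[tuple[int, int, int]] = []
    i = 0
    while i < len(edges):
        w = edges[i][1]
        tier = []
        while i < len(edges) and edges[i][1] == w:
            tier.append(edges[i][0])
            i += 1
        crossing = [(u, v) for u, v in tier if uf[u] != uf[v]]
        for u, v in crossing:
            kept.append((u, v, w))
        for u, v in crossing:
            uf.union(u, v)
    return kept


def build_tempnet(
    blocks: Sequence[tuple[SequenceBlock, str, float]],
) -> TemporalNetwork:
    """Build a temporal network from ``(block, layer_label, age_bp)`` layers.

    Layers must share one alignment window; layers are ordered by age.
    """
    if len(blocks) < 2:
        raise ValueError("need at least two layers")
    windows = {b.window for b, _, _ in blocks}
    if len(windows) != 1:
        raise ValueError(f"layers use mismatched windows: {sorted(windows)}")

    ordered = sorted(blocks, key=lambda t: -t[2])
    graph = nx.Graph()
    layer_groups: dict[str, list[dict]] = {}
    layers: list[tuple[str, float]] = []
    for block, label, age in ordered:
        if label in layer_groups:
            raise ValueError(f"duplicate layer label {label!r}")
        layers.append((label, age))
        groups = _collapse_layer(block)
        layer_groups[label] = groups
        for i, g in enumerate(groups):
            graph.add_node(
                (label, i),
                layer=label,
                age_bp=age,
                count=len(g["members"]),
                members=list(g["members"]),
                sequence=g["sequence"],
            )
        # within-layer minimum spanning network
        dists = {
            (i, j): sequence_distance(groups[i]["sequence"], groups[j]["sequence"])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        }
        for i, j, w in _msn_edges(dists, len(groups)):
            graph.add_edge((label, i), (label, j), kind="within", weight=w)

    # cross-layer identity edges
    for a in range(len(layers)):
        for b in range(a + 1, len(layers)):
            la, lb = layers[a][0], layers[b][0]
            for i, gi in enumerate(layer_groups[la]):
                for j, gj in enumerate(layer_groups[lb]):
                    if _identical(gi["sequence"], gj["sequence"]):
                        graph.add_edge((la, i), (lb, j), kind="identity", weight=0)
    return TemporalNetwork(layers=layers, graph=graph)


def shared_haplotype_report(net: TemporalNetwork) -> pd.DataFrame:
    """One row per haplotype (identity class across layers) with per-layer
    counts, sorted by number of layers present (descending) then ID."""
    # connected components over identity edges define global haplotypes
    id_graph = nx.Graph()
    id_graph.add_nodes_from(net.graph.nodes)
    id_graph.add_edges_from(net.cross_layer_edges())
    layer_order = [label for label, _ in net.layers]
    rows = []
    for comp in nx.connected_components(id_graph):
        counts = {label: 0 for label in layer_order}
        members: list[str] = []
        for node in comp:
            data = net.graph.nodes[node]
            counts[data["layer"]] += data["count"]
            members.extend(data["members"])
        rows.append(
            {
                "haplotype": min(members),
                "n_layers": sum(1 for v in counts.values() if v > 0),
                **{f"n_{label}": counts[label] for label in layer_order},
                "layers": ",".join(l for l in layer_order if counts[l] > 0),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["n_layers", "haplotype"], ascending=[False, True]
    ).reset_index(drop=True)


def to_node_edge_tables(net: TemporalNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export the network as delimited node/edge tables."""
    nodes = pd.DataFrame(
        [
            {
                "node": f"{layer}:{idx}",
                "layer": data["layer"],
                "age_bp": data["age_bp"],
                "count": data["count"],
                "members": ",".join(data["members"]),
            }
            for (layer, idx), data in net.graph.nodes(data=True)
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "source": f"{u[0]}:{u[1]}",
                "target": f"{v[0]}:{v[1]}",
                "kind": d["kind"],
                "weight": d["weight"],
            }
            for u, v, d in net.graph.edges(data=True)
        ]
    )
    return nodes, edges


def to_dot(net: TemporalNetwork) -> str:
    """DOT export (layers as node attributes)."""
    lines = ["graph tempnet {"]
    for (layer, idx), data in net.graph.nodes(data=True):
        lines.append(
            f'  "{layer}:{idx}" [layer="{layer}", age_bp={data["age_bp"]}, '
            f'count={data["count"]}];'
        )
    for u, v, d in net.graph.edges(data=True):
        style = "dashed" if d["kind"] == "identity" else "solid"
        lines.append(
            f'  "{u[0]}:{u[1]}" -- "{v[0]}:{v[1]}" '
            f'[weight={d["weight"]}, style={style}];'
        )
    lines.append("}")
    return "\n".join(lines)
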