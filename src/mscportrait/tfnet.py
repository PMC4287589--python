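"""Evidence-weighted TF-TF protein-interaction network assembly."""

from __future__ import annotations

import networkx as nx
import pandas as pd


def build(tf_list, ppi_edges: pd.DataFrame) -> nx.Graph:
    """Undirected network over the given TFs.

    Edges are kept only when both endpoints are in ``tf_list``; duplicate
    rows for a pair sum into an integer ``evidence`` weight; TFs without any
    retained edge are not added as nodes.
    """
    tfs = set(tf_list)
    g = nx.Graph()
    for row in ppi_edges.itertuples(index=False):
        a, b, ev = row.tf_a, row.tf_b, int(row.evidence)
        if a not in tfs or b not in tfs:
            continue
        if g.has_edge(a, b):
            g[a][b]["evidence"] += ev
        else:
            g.add_edge(a, b, evidence=ev)
    for n in g.nodes:
        g.nodes[n]["paralog_added"] = False
    return g


def add_paralogs(net: nx.Graph, paralogy: pd.DataFrame, tf_list) -> nx.Graph:
    """Add unconnected TFs that are paralogs of a connected node.

    Added nodes are isolated and flagged ``paralog_added``; no edges are
    ever added.
    """
    g = net.copy()
    connected = set(net.nodes)
    tfs = set(tf_list)
    pairs = set()
    for row in paralogy.itertuples(index=False):
        pairs.add((row.tf, row.paralog_of))
        pairs.add((row.paralog_of, row.tf))
    for tf, other in sorted(pairs):
        if tf in tfs and tf not in connected and other in connected:
            g.add_node(tf, paralog_added=True)
    return g


def summarize(net: nx.Graph) -> dict:
    degrees = dict(net.degree())
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_paralog_nodes": sum(1 for n in net.nodes if net.nodes[n].get("paralog_added")),
        "total_evidence": int(sum(d["evidence"] for _, _, d in net.edges(data=True))),
        "degrees": degrees,
    }


def write_sif(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, d in sorted(net.edges(data=True)):
            fh.write(f"{a}\tpp\t{b}\t{d['evidence']}\n")
        for n in sorted(nx.isolates(net)):
            fh.write(f"{n}\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
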