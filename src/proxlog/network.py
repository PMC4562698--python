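"""Contact networks from reconciled encounter records.

An encounter record (dyadic or single, each counted once) contributes one
unit of edge weight to its tag pair when the record's combined maximum RSSI
clears the chosen threshold.  Two conventional thresholds bracket the social
scale: RSSI >= 0 (proximity within ~5 m) and RSSI >= 40 (body contact,
within ~0.1 m); the 40+ network is always nested inside the 0+ network.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_network", "network_density", "export_network", "import_network"]


def build_network(
    records: pd.DataFrame,
    rssi_threshold: int,
    nodes: Optional[Iterable[int]] = None,
    node_attrs: Optional[Dict[int, dict]] = None,
    time_window: Optional[tuple] = None,
) -> nx.Graph:
    """Symmetric weighted contact network at a max-RSSI threshold.

    Records should already be uptime-restricted.  ``nodes`` fixes the node
    set (isolated tags included); ``node_attrs`` attaches attributes such as
    sex.  Edge weights are encounter counts (non-negative integers).
    """
    g = nx.Graph(rssi_threshold=int(rssi_threshold))
    if time_window is not None:
        g.graph["window_start"], g.graph["window_end"] = map(int, time_window)
    if nodes is not None:
        g.add_nodes_from(int(n) for n in nodes)
    if len(records):
        g.add_nodes_from(int(t) for t in records["tag_a"])
        g.add_nodes_from(int(t) for t in records["tag_b"])
        hits = records.loc[records["max_rssi"] >= rssi_threshold]
        for r in hits.itertuples(index=False):
            a, b = int(r.tag_a), int(r.tag_b)
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    for n, attrs in (node_attrs or {}).items():
        if g.has_node(int(n)):
            g.nodes[int(n)].update(attrs)
    return g


def network_density(net: nx.Graph) -> float:
    """Proportion of possible tag pairs connected by >= 1 encounter."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return net.number_of_edges() / (n * (n - 1) / 2)


def _matrix(net: nx.Graph) -> pd.DataFrame:
    ids = sorted(net.nodes)
    m = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for a, b, w in net.edges(data="weight", default=1):
        m.loc[a, b] = w
        m.loc[b, a] = w
    return m


def export_network(net: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Write a network as ``edgelist`` CSV, ``graphml`` or ``matrix`` CSV.

    All three round-trip losslessly through :func:`import_network`
    (including node attributes for GraphML).
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = [
            (min(a, b), max(a, b), w)
            for a, b, w in net.edges(data="weight", default=1)
        ]
        df = pd.DataFrame(sorted(rows), columns=["tag_a", "tag_b", "weight"])
        nodes = ",".join(str(n) for n in sorted(net.nodes))
        with open(path, "w") as fh:
            fh.write(f"# nodes={nodes}\n")
            df.to_csv(fh, index=False)
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "matrix":
        _matrix(net).to_csv(path, index_label="tag_id")
    else:
        raise ValueError(f"unknown network format '{fmt}'")


def import_network(path, fmt: str = "edgelist") -> nx.Graph:
    path = Path(path)
    if fmt == "edgelist":
        with open(path) as fh:
            first = fh.readline().strip()
            nodes = []
            if first.startswith("# nodes="):
                nodes = [int(x) for x in first.split("=", 1)[1].split(",") if x]
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for r in df.itertuples(index=False):
            g.add_edge(int(r.tag_a), int(r.tag_b), weight=int(r.weight))
        return g
    if fmt == "graphml":
        g = nx.read_graphml(path, node_type=int)
        for _, _, d in g.edges(data=True):
            d["weight"] = int(d.get("weight", 1))
        return g
    if fmt == "matrix":
        m = pd.read_csv(path, index_col=0)
        m.columns = m.columns.astype(int)
        arr = m.to_numpy()
        if not np.array_equal(arr, arr.T) or np.any(np.diag(arr) != 0):
            raise ValueError("matrix CSV must be symmetric with zero diagonal")
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in m.index)
        ids = list(m.index)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if arr[i, j] > 0:
                    g.add_edge(int(a), int(ids[j]), weight=int(arr[i, j]))
        return g
    raise ValueError(f"unknown network format '{fmt}'")
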