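"""Machine-readable exports: edge-list CSVs, GraphML, JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import ClusterAssignment
from .clpn import TemporalNetwork
from .ggm import ContemporaneousNetwork

CSV_FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def contemporaneous_to_graphml(net: ContemporaneousNetwork,
                               clusters: ClusterAssignment | None,
                               path: str | Path) -> None:
    g = nx.Graph()
    for node in net.node_labels:
        cluster = clusters.cluster_of(node) if clusters else None
        g.add_node(node, cluster=cluster or "none")
    iu = np.triu_indices_from(net.pcor, 1)
    for i, j in zip(*iu):
        w = float(net.pcor[i, j])
        if w != 0.0:
            g.add_edge(net.node_labels[i], net.node_labels[j], weight=w)
    nx.write_graphml(g, path)


def temporal_to_graphml(net: TemporalNetwork,
                        clusters: ClusterAssignment | None,
                        path: str | Path) -> None:
    g = nx.DiGraph()
    for node in net.node_labels:
        cluster = clusters.cluster_of(node) if clusters else None
        g.add_node(node, cluster=cluster or "none")
    p = net.B.shape[0]
    for i in range(p):
        for j in range(p):
            w = float(net.B[i, j])
            if w != 0.0:
                g.add_edge(net.node_labels[i], net.node_labels[j], weight=w)
    nx.write_graphml(g, path)


def contemporaneous_metadata(net: ContemporaneousNetwork) -> dict:
    return {
        "wave": net.wave_label,
        "n_used": net.n_used,
        "gamma": net.gamma,
        "lambda_selected": net.lambda_selected,
        "lambda_path": net.lambda_path,
        "ebic_path": net.ebic_path,
        "edge_counts": net.edge_counts,
        "n_edges": net.n_edges,
        "node_labels": list(net.node_labels),
        "pcor": net.pcor,
    }


def temporal_metadata(net: TemporalNetwork) -> dict:
    return {
        "n_used": net.n_used,
        "gamma": net.gamma,
        "node_labels": list(net.node_labels),
        "B": net.B,
        "per_node": [
            {"node": net.node_labels[j],
             "lambda_selected": sel.lambda_selected,
             "k_selected": sel.k_selected,
             "ebic_min": float(np.min(sel.ebic_path))}
            for j, sel in enumerate(net.selections)
        ],
    }


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
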