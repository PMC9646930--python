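"""Bridge centrality for contemporaneous networks and cross-construct
predictability for temporal networks.

Clusters are declared, not inferred: symptom nodes form one cluster,
cognition nodes the other, and covariates belong to none (they stay in the
estimation as confounding adjustments but carry no bridge statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clpn import TemporalNetwork
from .data_model import PanelDataset, VariableSpec, standardize
from .ggm import ContemporaneousNetwork

SYMPTOM_CLUSTER = "symptom-cluster"
COGNITION_CLUSTER = "cognition-cluster"


class CentralityError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterAssignment:
    """node -> cluster mapping; ``None`` marks unassigned (covariate) nodes."""

    assignment: Mapping[str, str | None]

    def __post_init__(self) -> None:
        clusters = set(v for v in self.assignment.values() if v is not None)
        if clusters != {SYMPTOM_CLUSTER, COGNITION_CLUSTER}:
            raise CentralityError("both named clusters need at least one node; "
                                  f"got {sorted(clusters)}")

    @classmethod
    def from_roles(cls, variables: Sequence[VariableSpec]) -> "ClusterAssignment":
        mapping: dict[str, str | None] = {}
        for v in variables:
            if v.role == "symptom":
                mapping[v.name] = SYMPTOM_CLUSTER
            elif v.role == "cognition":
                mapping[v.name] = COGNITION_CLUSTER
            else:
                mapping[v.name] = None
        return cls(mapping)

    def cluster_of(self, node: str) -> str | None:
        if node not in self.assignment:
            raise CentralityError(f"node {node!r} has no cluster assignment entry")
        return self.assignment[node]

    def opposite_nodes(self, node: str) -> list[str]:
        own = self.cluster_of(node)
        if own is None:
            raise CentralityError(f"node {node!r} is not assigned to a cluster")
        other = COGNITION_CLUSTER if own == SYMPTOM_CLUSTER else SYMPTOM_CLUSTER
        return [n for n, c in self.assignment.items() if c == other]

    def assigned_nodes(self) -> list[str]:
        return [n for n, c in self.assignment.items() if c is not None]


def bridge_ei1(net: ContemporaneousNetwork, clusters: ClusterAssignment,
               node: str) -> float:
    """Signed sum of the node's edge weights into the opposite cluster."""
    i = net.node_labels.index(node)
    idx = [net.node_labels.index(k) for k in clusters.opposite_nodes(node)]
    return float(np.sum(net.pcor[i, idx]))


def bridge_ei2(net: ContemporaneousNetwork, clusters: ClusterAssignment,
               node: str) -> float:
    """Two-step bridge expected influence: the one-step value plus the
    edge-weighted one-step values of all cluster-assigned neighbours."""
    i = net.node_labels.index(node)
    total = bridge_ei1(net, clusters, node)
    for other in clusters.assigned_nodes():
        if other == node:
            continue
        j = net.node_labels.index(other)
        w = net.pcor[i, j]
        if w != 0.0:
            total += w * bridge_ei1(net, clusters, other)
    return float(total)


def _standardized_waves(data: PanelDataset) -> tuple[np.ndarray, np.ndarray]:
    z = data if data.standardized else standardize(data)
    return z.wave_matrix(z.wave_labels[0]), z.wave_matrix(z.wave_labels[1])


def in_prediction(tnet: TemporalNetwork, data: PanelDataset,
                  clusters: ClusterAssignment, node: str) -> float:
    """Share of the node's wave-2 variance explained by selected wave-1
    predictors from the opposite cluster (R-squared, clamped to [0, 1])."""
    j = tnet.node_labels.index(node)
    opp = [tnet.node_labels.index(k) for k in clusters.opposite_nodes(node)]
    sel = [i for i in opp if tnet.B[i, j] != 0.0]
    if not sel:
        return 0.0
    X1, X2 = _standardized_waves(data)
    y = X2[:, j]
    yhat = X1[:, sel] @ tnet.B[sel, j]
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / float(np.sum(y ** 2))
    return float(np.clip(r2, 0.0, 1.0))


def out_prediction(tnet: TemporalNetwork, data: PanelDataset,
                   clusters: ClusterAssignment, node: str) -> float:
    """Total variance the wave-1 node accounts for across the opposite
    cluster's wave-2 nodes: sum of squared selected standardized
    coefficients (an orthogonal-predictor approximation)."""
    i = tnet.node_labels.index(node)
    opp = [tnet.node_labels.index(k) for k in clusters.opposite_nodes(node)]
    return float(np.sum(tnet.B[i, opp] ** 2))


def centrality_table(cnet: ContemporaneousNetwork, tnet: TemporalNetwork,
                     data: PanelDataset, clusters: ClusterAssignment) -> pd.DataFrame:
    """Per-node table of bridge EI1/EI2 and in-/out-prediction.

    Covariate (unassigned) rows carry NaN for every statistic.
    """
    rows = []
    for node in cnet.node_labels:
        if clusters.cluster_of(node) is None:
            rows.append({"node": node, "cluster": None, "bridge_ei1": np.nan,
                         "bridge_ei2": np.nan, "in_prediction": np.nan,
                         "out_prediction": np.nan})
        else:
            rows.append({
                "node": node,
                "cluster": clusters.cluster_of(node),
                "bridge_ei1": bridge_ei1(cnet, clusters, node),
                "bridge_ei2": bridge_ei2(cnet, clusters, node),
                "in_prediction": in_prediction(tnet, data, clusters, node),
                "out_prediction": out_prediction(tnet, data, clusters, node),
            })
    return pd.DataFrame(rows)
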