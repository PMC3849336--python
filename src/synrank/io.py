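"""Writers for networks, rankings and evaluation reports."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import SynergyNetwork
from .selection import EvaluationReport
from .spectral import SpectralRanking

SCHEMA_VERSION = 1

__all__ = [
    "write_network",
    "network_to_graphml",
    "write_ranking",
    "write_report",
    "read_report",
]


def write_network(
    network: SynergyNetwork,
    nodes_path: str | Path,
    edges_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Write node-weight and edge-list TSVs (one row per unordered pair)."""
    names = network.feature_names
    pd.DataFrame(
        {"node": names, "weight": network.node_weights}
    ).to_csv(nodes_path, sep="\t", index=False)
    rows = [
        (names[i], names[j], network.edge_weights[i, j])
        for i in range(network.n_features)
        for j in range(i + 1, network.n_features)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(network_to_graphml(network), graphml_path)


def network_to_graphml(network: SynergyNetwork) -> nx.Graph:
    """Graph with node attribute ``f`` and edge attribute ``s``."""
    g = nx.Graph(lam=float(network.lam))
    for i, name in enumerate(network.feature_names):
        g.add_node(name, f=float(network.node_weights[i]))
    for i in range(network.n_features):
        for j in range(i + 1, network.n_features):
            g.add_edge(
                network.feature_names[i],
                network.feature_names[j],
                s=float(network.edge_weights[i, j]),
            )
    return g


def write_ranking(
    ranking: SpectralRanking,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    node_weights=None,
) -> None:
    """Write ``rank  feature  score  node_weight`` TSV and/or a JSON variant."""
    rows = []
    for rank, idx in enumerate(ranking.order, start=1):
        rows.append(
            {
                "rank": rank,
                "feature": ranking.feature_names[idx],
                "score": float(ranking.scores[idx]),
                "node_weight": float(node_weights[idx]) if node_weights is not None else None,
            }
        )
    if tsv_path is not None:
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "eigenvalue": ranking.eigenvalue,
            "diagonal_fallback_used": ranking.diagonal_fallback_used,
            "unstable": ranking.unstable,
            "ranking": rows,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))


def write_report(report: EvaluationReport, path: str | Path, extra: dict | None = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_report(path: str | Path) -> EvaluationReport:
    return EvaluationReport.from_dict(json.loads(Path(path).read_text()))
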