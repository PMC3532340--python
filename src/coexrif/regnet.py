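"""Overlay DCG calls on a TF→target map to build the regulatory network.

A known-regulation pair enters the network when it carries differential-
coexpression evidence. Two retention rules are provided:

* ``"either-endpoint"`` (default) — keep the pair when the TF or the target
  is a DCG. This admits non-DCG TFs whose targets are DCGs, matching networks
  in which both DCG and non-DCG nodes appear.
* ``"dc-link"`` — keep the pair only when it is itself a DC-link (both
  endpoints DCGs and the pair's correlation changed); strictly smaller.

Each retained edge records which endpoint carries the DCG evidence
(``dcg_label``; the TF takes precedence when both endpoints are DCGs) and,
when both genes are measured, the pair's condition-wise correlations. TFs
are classified ``"DCG-TF"`` when the TF itself is a DCG, else
``"TF-of-DCGs"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import RegulatoryPairs

__all__ = [
    "RegulatoryEdge",
    "RegulatoryNetwork",
    "build_network",
    "classify_tfs",
    "export_network",
    "read_network",
]


@dataclass
class RegulatoryEdge:
    tf: str
    target: str
    tf_is_dcg: bool
    target_is_dcg: bool
    dcg_label: str | None
    r1: float | None = None
    r2: float | None = None


@dataclass
class RegulatoryNetwork:
    edges: list[RegulatoryEdge]
    nodes: dict[str, dict] = field(default_factory=dict)  # id -> {"role", "is_dcg"}

    def tfs(self) -> set[str]:
        return {e.tf for e in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {e.target for e in self.edges if e.tf == tf}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node_id, attrs in self.nodes.items():
            g.add_node(node_id, role=attrs["role"], is_dcg=bool(attrs["is_dcg"]))
        for e in self.edges:
            attrs: dict = {"dcg_label": e.dcg_label or ""}
            if e.r1 is not None:
                attrs["r1"] = float(e.r1)
            if e.r2 is not None:
                attrs["r2"] = float(e.r2)
            g.add_edge(e.tf, e.target, **attrs)
        return g


def build_network(
    dcgs: set[str],
    dc_links: set[frozenset[str]] | None,
    reg_pairs: RegulatoryPairs,
    corr1=None,
    corr2=None,
    gene_index: dict[str, int] | None = None,
    retention: str = "either-endpoint",
) -> RegulatoryNetwork:
    """Match DCGs (and optionally DC-links) against known TF→target pairs.

    ``corr1``/``corr2``/``gene_index`` let the pair's condition correlations
    be attached when both endpoints are in the expression matrix. An empty
    network is a legal result.
    """
    if retention not in ("either-endpoint", "dc-link"):
        raise ValueError("retention must be 'either-endpoint' or 'dc-link'")
    if retention == "dc-link" and dc_links is None:
        raise ValueError("dc-link retention needs the DC-link set")
    edges: list[RegulatoryEdge] = []
    for tf, target in reg_pairs.pairs:
        tf_dcg = tf in dcgs
        target_dcg = target in dcgs
        if retention == "either-endpoint":
            keep = tf_dcg or target_dcg
        else:
            keep = frozenset((tf, target)) in dc_links
        if not keep:
            continue
        label = tf if tf_dcg else (target if target_dcg else None)
        r1 = r2 = None
        if corr1 is not None and gene_index is not None:
            if tf in gene_index and target in gene_index:
                i, j = gene_index[tf], gene_index[target]
                r1 = float(corr1[i, j])
                r2 = float(corr2[i, j])
        edges.append(
            RegulatoryEdge(
                tf=tf,
                target=target,
                tf_is_dcg=tf_dcg,
                target_is_dcg=target_dcg,
                dcg_label=label,
                r1=r1,
                r2=r2,
            )
        )
    tf_nodes = {e.tf for e in edges}
    target_nodes = {e.target for e in edges}
    nodes: dict[str, dict] = {}
    for node_id in sorted(tf_nodes | target_nodes):
        if node_id in tf_nodes and node_id in target_nodes:
            role = "both"
        elif node_id in tf_nodes:
            role = "TF"
        else:
            role = "target"
        nodes[node_id] = {"role": role, "is_dcg": node_id in dcgs}
    return RegulatoryNetwork(edges=edges, nodes=nodes)


def classify_tfs(network: RegulatoryNetwork) -> pd.DataFrame:
    """One row per TF: ``"DCG-TF"`` if the TF is itself a DCG, else ``"TF-of-DCGs"``."""
    rows = []
    for tf in sorted(network.tfs()):
        is_dcg = network.nodes[tf]["is_dcg"]
        rows.append((tf, "DCG-TF" if is_dcg else "TF-of-DCGs"))
    return pd.DataFrame(rows, columns=["tf", "tf_class"])


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6f}"


def export_network(network: RegulatoryNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write ``nodes.tsv``, ``edges.tsv`` and ``network.graphml``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
        "graphml": out / "network.graphml",
    }
    with open(paths["nodes"], "w", encoding="utf-8") as fh:
        fh.write("id\trole\tis_dcg\n")
        for node_id in sorted(network.nodes):
            attrs = network.nodes[node_id]
            fh.write(f"{node_id}\t{attrs['role']}\t{int(attrs['is_dcg'])}\n")
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\tdcg_label\tr1\tr2\n")
        for e in network.edges:
            fh.write(
                f"{e.tf}\t{e.target}\t{e.dcg_label or ''}\t{_fmt(e.r1)}\t{_fmt(e.r2)}\n"
            )
    nx.write_graphml(network.to_networkx(), paths["graphml"])
    return paths


def read_network(out_dir: str | Path) -> RegulatoryNetwork:
    """Reload a network from the ``nodes.tsv`` / ``edges.tsv`` pair written by export."""
    out = Path(out_dir)
    nodes_df = pd.read_csv(out / "nodes.tsv", sep="\t", dtype={"id": str})
    edges_df = pd.read_csv(out / "edges.tsv", sep="\t", dtype={"tf": str, "target": str})
    nodes = {
        str(row.id): {"role": row.role, "is_dcg": bool(row.is_dcg)}
        for row in nodes_df.itertuples()
    }
    edges = []
    for row in edges_df.itertuples():
        label = None if pd.isna(row.dcg_label) else str(row.dcg_label)
        edges.append(
            RegulatoryEdge(
                tf=str(row.tf),
                target=str(row.target),
                tf_is_dcg=nodes[str(row.tf)]["is_dcg"],
                target_is_dcg=nodes[str(row.target)]["is_dcg"],
                dcg_label=label,
                r1=None if pd.isna(row.r1) else float(row.r1),
                r2=None if pd.isna(row.r2) else float(row.r2),
            )
        )
    return RegulatoryNetwork(edges=edges, nodes=nodes)
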