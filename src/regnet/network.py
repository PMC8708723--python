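"""Directed TF -> target-gene network inference from binding evidence.

An edge TF -> G exists iff the TF has at least one peak that (i) lies in a
promoter- or enhancer-like signature (cCRE class PLS, pELS or dELS) and
(ii) is associated with G by the regulatory-domain rule. Self-regulatory
loops (a TF binding the gene encoding itself) are permitted and expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .ccre import REGULATORY_CLASSES, CcreClass
from .genome import Peak, ValidationError


@dataclass
class NetworkEdge:
    source: str  # TF name
    target: str  # gene id
    evidence: list[tuple[str, CcreClass]] = field(default_factory=list)

    @property
    def weight(self) -> int:
        return len(self.evidence)


@dataclass
class RegulatoryNetwork:
    edges: list[NetworkEdge]
    tfs: list[str]

    @property
    def nodes(self) -> list[str]:
        seen = dict.fromkeys(self.tfs)
        for e in self.edges:
            seen.setdefault(e.source)
            seen.setdefault(e.target)
        return list(seen)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                weight=e.weight,
                evidence=";".join(f"{p}:{c}" for p, c in e.evidence),
            )
        return g


def infer_edges(
    peak_sets: Mapping[str, Sequence[Peak]],
    peak_classes: Mapping[str, Mapping[str, CcreClass]],
    associations: Mapping[str, Mapping[str, set[str]]],
) -> RegulatoryNetwork:
    """Two-step inference: class filter, then regulatory-domain association.

    ``peak_classes`` and ``associations`` are keyed by factor, then by
    peak name. Evidence lists record every supporting (peak, class) pair;
    the edge weight is the evidence count.
    """
    edges: dict[tuple[str, str], NetworkEdge] = {}
    for factor in sorted(peak_sets):
        if factor not in peak_classes:
            raise ValidationError(f"factor {factor!r} has no class annotations")
        classes = peak_classes[factor]
        assoc = associations.get(factor, {})
        for p in peak_sets[factor]:
            if p.name not in classes:
                raise ValidationError(
                    f"peak {p.name!r} of factor {factor!r} has no class annotation"
                )
            cls = classes[p.name]
            if cls not in REGULATORY_CLASSES:
                continue
            for gene in sorted(assoc.get(p.name, ())):
                key = (factor, gene)
                if key not in edges:
                    edges[key] = NetworkEdge(factor, gene)
                edges[key].evidence.append((p.name, cls))
    ordered = [edges[k] for k in sorted(edges)]
    return RegulatoryNetwork(edges=ordered, tfs=sorted(peak_sets))


def node_statistics(
    network: RegulatoryNetwork, tf_gene_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-node degree table.

    ``tf_gene_map`` maps TF names to the gene ids encoding them (identity
    by default); it defines which targets count as TF-panel nodes for the
    interconnectivity degree (in + out restricted to the panel).
    """
    tf_gene_map = dict(tf_gene_map or {})
    gene_of = {tf: tf_gene_map.get(tf, tf) for tf in network.tfs}
    tf_of_gene = {g: tf for tf, g in gene_of.items()}
    nodes = network.nodes
    out_deg = {n: 0 for n in nodes}
    in_deg = {n: 0 for n in nodes}
    panel_deg = {n: 0 for n in nodes}
    for e in network.edges:
        out_deg[e.source] += 1
        in_deg[e.target] += 1
        if e.target in tf_of_gene:
            panel_deg[e.source] += 1
            target_tf = tf_of_gene[e.target]
            if target_tf in panel_deg:
                panel_deg[target_tf] += 1
    rows = [
        {
            "node": n,
            "out_degree": out_deg[n],
            "in_degree": in_deg[n],
            "total_degree": out_deg[n] + in_deg[n],
            "tf_panel_degree": panel_deg[n],
        }
        for n in sorted(nodes)
    ]
    return pd.DataFrame(rows)


def tf_panel_subgraph(
    network: RegulatoryNetwork, tf_gene_map: Mapping[str, str] | None = None
) -> RegulatoryNetwork:
    """Edges whose target is the gene encoding a panel TF (self-loops kept)."""
    tf_gene_map = dict(tf_gene_map or {})
    panel_genes = {tf_gene_map.get(tf, tf) for tf in network.tfs}
    edges = [e for e in network.edges if e.target in panel_genes]
    return RegulatoryNetwork(edges=edges, tfs=list(network.tfs))


def export_network(network: RegulatoryNetwork, path, format: str = "tsv") -> None:
    if format == "tsv":
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "weight": e.weight,
                "evidence": ";".join(f"{p}:{c}" for p, c in e.evidence),
            }
            for e in network.edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "evidence"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(network.to_digraph(), path)
    else:
        raise ValidationError(f"unknown network export format {format!r}")


def read_network_tsv(path, tfs: Sequence[str] | None = None) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges = []
    for row in df.itertuples(index=False):
        evidence = []
        if isinstance(row.evidence, str) and row.evidence:
            for item in row.evidence.split(";"):
                pname, cls = item.rsplit(":", 1)
                evidence.append((pname, CcreClass(cls)))
        edges.append(NetworkEdge(row.source, row.target, evidence))
    inferred_tfs = sorted({e.source for e in edges}) if tfs is None else list(tfs)
    return RegulatoryNetwork(edges=edges, tfs=inferred_tfs)
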