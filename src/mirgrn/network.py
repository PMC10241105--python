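"""Bipartite miRNA -> term regulatory-network assembly and export.

Only significant enrichment records become edges; an edge's weight is the
number of verified target genes shared between the miRNA and the term, so a
term node's size (the sum of its incident edge weights) is proportional to
the number of target-gene associations it carries — the convention used in
chord/Sankey renderings of such networks.

Exports are byte-deterministic: node orders are fixed (miRNAs by id, terms
by total weight descending then id), JSON is dumped with sorted keys.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRecord
from .io_formats import ValidationError

__all__ = [
    "NetworkEdge",
    "RegulatoryNetwork",
    "build_network",
    "subnetwork_by_term_pattern",
    "export_chord",
    "export_sankey",
]

MITO_PATTERN = "mitochondri"  # default keyword for the mitochondrial GO:CC slice


@dataclass(frozen=True)
class NetworkEdge:
    mirna: str
    set_id: str
    set_name: str
    category: str
    overlap: frozenset[str]

    @property
    def weight(self) -> int:
        return len(self.overlap)


@dataclass(frozen=True)
class RegulatoryNetwork:
    edges: tuple[NetworkEdge, ...]

    @property
    def mirna_nodes(self) -> list[str]:
        return sorted({e.mirna for e in self.edges})

    def term_nodes(self) -> pd.DataFrame:
        """Term table with per-term total weight, ordered by total weight
        descending then set id."""
        totals: dict[str, dict] = {}
        for e in self.edges:
            t = totals.setdefault(
                e.set_id, {"set_id": e.set_id, "set_name": e.set_name,
                           "category": e.category, "total_weight": 0},
            )
            t["total_weight"] += e.weight
        df = pd.DataFrame(
            sorted(totals.values(), key=lambda t: (-t["total_weight"], t["set_id"])),
            columns=["set_id", "set_name", "category", "total_weight"],
        )
        return df

    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for m in self.mirna_nodes:
            g.add_node(m, bipartite="mirna")
        for _, t in self.term_nodes().iterrows():
            g.add_node(
                t["set_id"], bipartite="term", name=t["set_name"],
                category=t["category"], total_weight=int(t["total_weight"]),
            )
        for e in self.edges:
            g.add_edge(e.mirna, e.set_id, weight=e.weight,
                       overlap=sorted(e.overlap))
        return g


def build_network(records: list[EnrichmentRecord]) -> RegulatoryNetwork:
    """One edge per significant (miRNA, set) record with non-empty overlap.

    An input with no significant record yields an empty network (with a
    logged warning), not an error — a run can legitimately find nothing.
    """
    edges = [
        NetworkEdge(r.mirna, r.set_id, r.set_name, r.category, r.overlap)
        for r in records
        if r.significant and r.k >= 1
    ]
    if not edges:
        import logging

        logging.getLogger(__name__).warning(
            "no significant enrichment records; network is empty"
        )
    edges.sort(key=lambda e: (e.mirna, e.set_id))
    return RegulatoryNetwork(tuple(edges))


def subnetwork_by_term_pattern(
    network: RegulatoryNetwork, pattern: str = MITO_PATTERN
) -> RegulatoryNetwork:
    """Retain terms whose *name* matches the case-insensitive regex/substring;
    miRNA nodes left without edges drop out automatically. Edge weights are
    carried over, never recomputed."""
    try:
        rx = re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ValidationError(f"invalid term pattern {pattern!r}: {exc}") from exc
    return RegulatoryNetwork(
        tuple(e for e in network.edges if rx.search(e.set_name))
    )


def _node_order(network: RegulatoryNetwork) -> list[str]:
    return network.mirna_nodes + list(network.term_nodes()["set_id"])


def export_chord(network: RegulatoryNetwork, matrix_path, nodes_path) -> None:
    """Square flow matrix over miRNA + term nodes (TSV) plus JSON node
    metadata. Flows are symmetric (undirected bipartite)."""
    order = _node_order(network)
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for e in network.edges:
        mat.loc[e.mirna, e.set_id] = e.weight
        mat.loc[e.set_id, e.mirna] = e.weight
    with open(matrix_path, "w", encoding="utf-8") as fh:
        mat.to_csv(fh, sep="\t", index_label="node")
    terms = network.term_nodes()
    meta = {
        "mirnas": network.mirna_nodes,
        "terms": [
            {
                "set_id": t.set_id,
                "set_name": t.set_name,
                "category": t.category,
                "total_weight": int(t.total_weight),
            }
            for t in terms.itertuples()
        ],
    }
    with open(nodes_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def export_sankey(network: RegulatoryNetwork, path) -> None:
    """Sankey-ready JSON: nodes plus {source, target, value} links."""
    links = [
        {"source": e.mirna, "target": e.set_id, "value": e.weight}
        for e in network.edges
    ]
    payload = {"nodes": _node_order(network), "links": links}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
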