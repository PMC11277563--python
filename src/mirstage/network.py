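"""Bipartite miRNA–gene interaction tables and per-panel subnetworks."""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .curation import normalize_mirna_id
from .errors import ParseError, ValidationError
from .panels import StagePanel

__all__ = [
    "InteractionTable",
    "PanelNetwork",
    "ExportFormat",
    "load_interactions",
    "write_interactions",
    "panel_subnetwork",
    "export_network",
    "import_network",
]

Edge = tuple[str, str]  # (mirna_id, gene)


@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated bipartite edge set; duplicate rows union their source tags."""

    edges: Mapping[Edge, frozenset[str]]

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "InteractionTable":
        """Build a table from (mirna, gene, source_db) rows, normalizing ids."""
        merged: dict[Edge, set[str]] = {}
        for mirna, gene, source_db in rows:
            key = (normalize_mirna_id(mirna), str(gene).strip().upper())
            if not key[1]:
                raise ValidationError("empty gene symbol in interaction row")
            merged.setdefault(key, set()).add(str(source_db))
        return cls({k: frozenset(v) for k, v in merged.items()})

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}


def load_interactions(path: str | Path) -> InteractionTable:
    """Load an interaction TSV (columns mirna_id, gene, source_db)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError("empty interaction file", path=str(path)) from None
    missing = [c for c in ("mirna_id", "gene", "source_db") if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path=str(path))
    if frame.empty:
        raise ParseError("interaction file has a header but no rows", path=str(path))
    try:
        return InteractionTable.from_rows(
            frame[["mirna_id", "gene", "source_db"]].itertuples(index=False, name=None)
        )
    except ValidationError as exc:
        raise ParseError(str(exc), path=str(path)) from None


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    rows = [
        {"mirna_id": m, "gene": g, "source_db": ";".join(sorted(tags))}
        for (m, g), tags in sorted(table.edges.items())
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene", "source_db"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class PanelNetwork:
    """The restriction of an interaction table to one panel's genes."""

    panel: StagePanel
    edges: Mapping[Edge, frozenset[str]]
    mirnas: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        for (_, gene) in self.edges:
            if gene not in self.panel:
                raise ValidationError(f"edge gene {gene!r} not in panel {self.panel.key}")
        object.__setattr__(self, "mirnas", frozenset(m for m, _ in self.edges))

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}


def panel_subnetwork(table: InteractionTable, panel: StagePanel) -> PanelNetwork:
    """Edges of ``table`` landing on ``panel`` genes; empty intersection is fine."""
    subset = {
        edge: tags for edge, tags in table.edges.items() if edge[1] in panel
    }
    return PanelNetwork(panel=panel, edges=subset)


class ExportFormat(str, enum.Enum):
    GRAPHML = "graphml"
    NODE_LINK_JSON = "node_link_json"


def _to_graph(net: PanelNetwork) -> nx.Graph:
    graph = nx.Graph()
    for gene in net.panel.genes:
        graph.add_node(gene, role="gene")
    for (mirna, gene), tags in net.edges.items():
        graph.add_node(mirna, role="mirna")
        graph.add_edge(mirna, gene, sources=";".join(sorted(tags)))
    return graph


def export_network(net: PanelNetwork, path: str | Path, format: ExportFormat) -> None:
    """Write the bipartite panel network, re-importable losslessly.

    Nodes carry ``role`` in {mirna, gene}; edges carry a semicolon-joined
    ``sources`` attribute (GraphML has no set-valued attributes, so both
    formats use the joined string).
    """
    graph = _to_graph(net)
    path = Path(path)
    if format is ExportFormat.GRAPHML:
        nx.write_graphml(graph, path)
    elif format is ExportFormat.NODE_LINK_JSON:
        payload = nx.node_link_data(graph, edges="edges")
        path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
    else:  # pragma: no cover - enum guard
        raise ValidationError(f"unknown export format {format!r}")


def import_network(path: str | Path, format: ExportFormat, panel: StagePanel) -> PanelNetwork:
    """Inverse of :func:`export_network`."""
    path = Path(path)
    if format is ExportFormat.GRAPHML:
        graph = nx.read_graphml(path)
    elif format is ExportFormat.NODE_LINK_JSON:
        graph = nx.node_link_graph(json.loads(path.read_text(encoding="utf-8")), edges="edges")
    else:  # pragma: no cover - enum guard
        raise ValidationError(f"unknown export format {format!r}")
    edges: dict[Edge, frozenset[str]] = {}
    for u, v, data in graph.edges(data=True):
        if graph.nodes[u].get("role") == "mirna":
            mirna, gene = u, v
        else:
            mirna, gene = v, u
        tags = frozenset(t for t in str(data.get("sources", "")).split(";") if t)
        edges[(mirna, gene)] = tags
    return PanelNetwork(panel=panel, edges=edges)
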