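"""Bipartite compound-target and gene-pathway networks with degree ranking.

Two bipartite views summarize the pipeline. The compound-target network
links each active compound to the common targets it hits (compounds with no
common target are excluded). The gene-pathway network links the member genes
of the top enriched pathways to those pathways; the maximum-degree gene is
the *core gene*. Degree rankings are deterministic: descending degree, ties
broken lexicographically by node id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .enrichment import EnrichmentRow
from .errors import FormatError, IntegrityError
from .targets import CommonTargetSet, TargetMap

__all__ = [
    "BipartiteNetwork",
    "build_compound_target",
    "build_gene_pathway",
    "rank_by_degree",
    "export_bipartite",
    "read_bipartite",
]


@dataclass
class BipartiteNetwork:
    """Left/right node sets with cross edges and per-node attributes."""

    left_nodes: set[str] = field(default_factory=set)
    right_nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    node_attrs: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left_nodes & self.right_nodes:
            raise IntegrityError("left and right node sets must be disjoint")
        for left, right in self.edges:
            if left not in self.left_nodes or right not in self.right_nodes:
                raise IntegrityError(f"edge ({left!r}, {right!r}) not left-to-right")

    @property
    def n_nodes(self) -> int:
        return len(self.left_nodes) + len(self.right_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        if node in self.left_nodes:
            return sum(1 for l, _ in self.edges if l == node)
        if node in self.right_nodes:
            return sum(1 for _, r in self.edges if r == node)
        raise KeyError(node)


def build_compound_target(cts: CommonTargetSet, tm: TargetMap) -> BipartiteNetwork:
    """Compound-target network restricted to the common targets.

    Left nodes are the compounds hitting at least one common target, right
    nodes the common targets themselves; compound nodes carry a semicolon-
    joined ``herb`` attribute (multi-herb compounds keep every label).
    """
    edges = {(mol, gene) for mol, gene in tm.edges if gene in cts.genes}
    compounds = {mol for mol, _ in edges}
    attrs: dict[str, dict[str, str]] = {}
    for mol in compounds:
        herbs = sorted(tm.herb_of.get(mol, set()))
        attrs[mol] = {"role": "compound", "herb": ";".join(herbs)}
    for gene in cts.genes:
        attrs[gene] = {"role": "target"}
    return BipartiteNetwork(left_nodes=compounds, right_nodes=set(cts.genes),
                            edges=edges, node_attrs=attrs)


def build_gene_pathway(rows: Sequence[EnrichmentRow]) -> BipartiteNetwork:
    """Gene-pathway membership network from enrichment results."""
    genes: set[str] = set()
    pathways: set[str] = set()
    edges: set[tuple[str, str]] = set()
    attrs: dict[str, dict[str, str]] = {}
    for row in rows:
        pathways.add(row.term_id)
        attrs[row.term_id] = {"role": "pathway", "category": row.category,
                              "name": row.name}
        for gene in row.members:
            genes.add(gene)
            attrs[gene] = {"role": "gene"}
            edges.add((gene, row.term_id))
    return BipartiteNetwork(left_nodes=genes, right_nodes=pathways,
                            edges=edges, node_attrs=attrs)


def rank_by_degree(b: BipartiteNetwork, side: str = "left") -> list[tuple[str, int]]:
    """Deterministic (node, degree) ranking of one side of the network.

    Descending degree, ties lexicographic. For the gene side of a
    gene-pathway network the first entry is the core gene.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    nodes = b.left_nodes if side == "left" else b.right_nodes
    counts = {v: 0 for v in nodes}
    idx = 0 if side == "left" else 1
    for edge in b.edges:
        counts[edge[idx]] += 1
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def _to_nx(b: BipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in sorted(b.left_nodes):
        g.add_node(node, side="left", **b.node_attrs.get(node, {}))
    for node in sorted(b.right_nodes):
        g.add_node(node, side="right", **b.node_attrs.get(node, {}))
    g.add_edges_from(b.edges)
    return g


def export_bipartite(b: BipartiteNetwork, path: str | Path,
                     fmt: str | None = None) -> None:
    """Write the network as GraphML (attributes preserved) or SIF."""
    path = Path(path)
    fmt = fmt or ("sif" if path.suffix.lower() == ".sif" else "graphml")
    if fmt == "graphml":
        nx.write_graphml(_to_nx(b), path)
    elif fmt == "sif":
        with path.open("w") as fh:
            for left, right in sorted(b.edges):
                fh.write(f"{left}\tbp\t{right}\n")
            linked = {v for e in b.edges for v in e}
            for node in sorted((b.left_nodes | b.right_nodes) - linked):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_bipartite(path: str | Path) -> BipartiteNetwork:
    """Re-read a GraphML export produced by :func:`export_bipartite`."""
    g = nx.read_graphml(Path(path))
    left = {n for n, d in g.nodes(data=True) if d.get("side") == "left"}
    right = {n for n, d in g.nodes(data=True) if d.get("side") == "right"}
    if left | right != set(g.nodes()):
        raise FormatError("GraphML file lacks bipartite side annotations")
    edges = set()
    for u, v in g.edges():
        if u in left and v in right:
            edges.add((u, v))
        elif v in left and u in right:
            edges.add((v, u))
        else:
            raise FormatError(f"edge ({u!r}, {v!r}) does not cross sides")
    attrs = {n: {k: v for k, v in d.items() if k != "side"}
             for n, d in g.nodes(data=True)}
    return BipartiteNetwork(left_nodes=left, right_nodes=right,
                            edges=edges, node_attrs=attrs)
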