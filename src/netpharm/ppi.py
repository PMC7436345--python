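"""PPI network construction, six node centralities, and the two-stage hub screen.

The protein-protein interaction stage grows a network from the common-target
seed genes by one-hop expansion against a background interactome (seeds, their
direct interactors, and every background edge among those nodes), then ranks
nodes by six centrality measures:

``dc``  degree centrality, |N(v)|;
``bc``  betweenness, the sum over unordered node pairs (s, t), s != v != t,
        of the fraction of unweighted shortest s-t paths passing through v
        (unnormalized, CytoNCA-scale raw pair counts);
``cc``  closeness within v's connected component,
        (|C_v| - 1) / sum of distances from v (0 for isolated nodes);
``ec``  eigenvector centrality: the entrywise non-negative dominant
        eigenvector of the adjacency matrix, L2-normalized, computed by
        power iteration from an all-ones start (tol 1e-10, cap 10^4);
``lac`` local average connectivity: mean, over v's neighbors u, of u's
        degree inside the subgraph induced by N(v);
``nc``  neighborhood centrality: the sum over incident edges (v, u) of the
        edge clustering coefficient ECC(v, u) = z / min(d_v - 1, d_u - 1),
        with z the number of triangles through the edge; ECC is defined as 0
        when the denominator is non-positive (a ``z + 1`` numerator variant
        is available via ``ecc_plus_one``).

The hub screen runs in two stages. Stage 1 keeps nodes whose degree is at
least twice the median degree of the full network (inclusive comparison) and
takes the induced subgraph. Stage 2 recomputes all six centralities on that
subgraph and keeps the nodes strictly exceeding all six subgraph medians —
the *core genes*. Medians use the even-count averaging convention. Both the
stage-1 multiplier and the comparison modes are configurable.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "InteractionNetwork",
    "ScreenResult",
    "build_seeded_network",
    "centralities",
    "two_stage_screen",
    "write_network",
    "read_network",
]

CENTRALITY_COLUMNS = ("dc", "bc", "cc", "ec", "lac", "nc")


class InteractionNetwork:
    """Simple undirected interaction graph over gene-symbol nodes."""

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph()
        if graph is not None:
            if any(u == v for u, v in graph.edges()):
                raise IntegrityError("self-loops are not allowed in an interaction network")
            g.add_nodes_from(graph.nodes(data=True))
            g.add_edges_from(graph.edges())
        self.graph = g

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = ()) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise IntegrityError(f"self-loop on node {u!r}")
            g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes: Iterable[str]) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.subgraph(nodes).copy())

    def __eq__(self, other) -> bool:
        return (isinstance(other, InteractionNetwork)
                and self.nodes == other.nodes and self.edges == other.edges)


@dataclass
class ScreenResult:
    """Outcome of the two-stage centrality screen."""

    stage1_threshold: float
    stage1_nodes: set[str]
    core_nodes: set[str]
    stage2_medians: dict[str, float]
    stage1_table: pd.DataFrame | None = field(default=None, repr=False)
    stage2_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "stage1_threshold": self.stage1_threshold,
            "stage2_medians": dict(self.stage2_medians),
            "n_stage1": len(self.stage1_nodes),
            "n_core": len(self.core_nodes),
            "stage1_nodes": sorted(self.stage1_nodes),
            "core_nodes": sorted(self.core_nodes),
        }


def build_seeded_network(seeds: Iterable[str],
                         background: Iterable[tuple[str, str]] | nx.Graph,
                         ) -> InteractionNetwork:
    """One-hop expansion of the seed genes against a background interactome.

    Nodes are the seeds found in the background plus their direct
    interactors; edges are every background edge with both endpoints in that
    node set (induced closure). Self-loops and duplicate edges are dropped.
    Seeds absent from the background are ignored; if none is present the
    result is an empty network.
    """
    if isinstance(background, nx.Graph):
        bg = background
    else:
        bg = nx.Graph()
        bg.add_edges_from((u, v) for u, v in background if u != v)
    bg.remove_edges_from(nx.selfloop_edges(bg))
    present = set(seeds) & set(bg.nodes())
    if not present:
        return InteractionNetwork()
    keep = set(present)
    for s in present:
        keep.update(bg.neighbors(s))
    return InteractionNetwork(bg.subgraph(keep).copy())


def _eigenvector(g: nx.Graph, order: list[str],
                 tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Dominant adjacency eigenvector by power iteration, L2-normalized."""
    n = len(order)
    if n == 0 or g.number_of_edges() == 0:
        return np.zeros(n)
    a = nx.to_numpy_array(g, nodelist=order)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        # shift by +I: same eigenvectors, but keeps the dominant eigenvalue
        # unique on bipartite graphs (where +/- lambda_max pair up)
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(n)
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return np.abs(x)


def _lac_nc(g: nx.Graph, order: list[str],
            ecc_plus_one: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Local average connectivity and edge-clustering (neighborhood) centrality."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    lac = np.zeros(len(order))
    nc = np.zeros(len(order))
    for i, v in enumerate(order):
        nbrs = adj[v]
        dv = len(nbrs)
        if dv == 0:
            continue
        # LAC: total degree inside the induced neighborhood, averaged
        within = sum(len(adj[u] & nbrs) for u in nbrs)
        lac[i] = within / dv
        # NC: sum of per-edge clustering coefficients
        total = 0.0
        for u in nbrs:
            z = len(adj[v] & adj[u])  # triangles through edge (v, u)
            denom = min(dv - 1, len(adj[u]) - 1)
            if denom > 0:
                total += ((z + 1) if ecc_plus_one else z) / denom
        nc[i] = total
    return lac, nc


def centralities(g: InteractionNetwork,
                 ecc_plus_one: bool = False) -> pd.DataFrame:
    """All six centrality measures, as a DataFrame indexed by node.

    Columns: dc, bc, cc, ec, lac, nc (see module docstring for definitions).
    """
    graph = g.graph
    if any(u == v for u, v in graph.edges()):
        raise IntegrityError("graph must be simple")
    order = sorted(graph.nodes())
    dc = np.array([graph.degree(v) for v in order], dtype=float)
    bc_map = nx.betweenness_centrality(graph, normalized=False)
    cc_map = nx.closeness_centrality(graph, wf_improved=False)
    bc = np.array([bc_map[v] for v in order])
    cc = np.array([cc_map[v] for v in order])
    ec = _eigenvector(graph, order)
    lac, nc_vals = _lac_nc(graph, order, ecc_plus_one=ecc_plus_one)
    return pd.DataFrame(
        {"dc": dc, "bc": bc, "cc": cc, "ec": ec, "lac": lac, "nc": nc_vals},
        index=pd.Index(order, name="node"),
    )


def two_stage_screen(g: InteractionNetwork,
                     multiplier: float = 2.0,
                     stage1_strict: bool = False,
                     ecc_plus_one: bool = False) -> ScreenResult:
    """Median-threshold hub screen: degree pre-filter, then six-way median cut.

    Stage 1 keeps nodes with degree >= multiplier x median degree (or > when
    ``stage1_strict``); stage 2 recomputes the six centralities on the
    induced subgraph and keeps nodes strictly exceeding all six medians.
    """
    if g.n_nodes == 0:
        return ScreenResult(0.0, set(), set(), {c: float("nan") for c in CENTRALITY_COLUMNS})
    degrees = {v: g.graph.degree(v) for v in g.graph.nodes()}
    tau1 = multiplier * statistics.median(degrees.values())
    if stage1_strict:
        stage1 = {v for v, d in degrees.items() if d > tau1}
    else:
        stage1 = {v for v, d in degrees.items() if d >= tau1}
    full_table = centralities(g, ecc_plus_one=ecc_plus_one)
    if not stage1:
        return ScreenResult(tau1, set(), set(),
                            {c: float("nan") for c in CENTRALITY_COLUMNS},
                            stage1_table=full_table)
    g1 = g.subgraph(stage1)
    table2 = centralities(g1, ecc_plus_one=ecc_plus_one)
    medians = {c: float(table2[c].median()) for c in CENTRALITY_COLUMNS}
    above = np.ones(len(table2), dtype=bool)
    for c in CENTRALITY_COLUMNS:
        above &= table2[c].to_numpy() > medians[c]
    core = set(table2.index[above])
    return ScreenResult(tau1, stage1, core, medians,
                        stage1_table=full_table, stage2_table=table2)


def write_network(g: InteractionNetwork, path: str | Path,
                  fmt: str | None = None) -> None:
    """Write a network as SIF (``nodeA<TAB>pp<TAB>nodeB``) or GraphML.

    Format is inferred from the extension when ``fmt`` is None. SIF lists
    isolated nodes as bare single-token lines.
    """
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix.lower() == ".graphml" else "sif")
    if fmt == "graphml":
        nx.write_graphml(g.graph, path)
    elif fmt == "sif":
        with path.open("w") as fh:
            written = set()
            for u, v in sorted((sorted((a, b)) for a, b in g.graph.edges())):
                fh.write(f"{u}\tpp\t{v}\n")
                written.update((u, v))
            for node in sorted(set(g.graph.nodes()) - written):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path: str | Path, fmt: str | None = None) -> InteractionNetwork:
    """Read a SIF or GraphML network written by :func:`write_network`."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix.lower() == ".graphml" else "sif")
    if fmt == "graphml":
        return InteractionNetwork(nx.read_graphml(path))
    if fmt != "sif":
        raise ValueError(f"unknown network format: {fmt!r}")
    g = nx.Graph()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                # SIF allows several targets per line
                for target in parts[2:]:
                    g.add_edge(parts[0], target)
            else:
                raise FormatError(f"{path}:{lineno}: malformed SIF line: {line!r}")
    return InteractionNetwork(g)
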