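"""Interaction-network data model and shortest-path services.

The screening stage works on an undirected, unweighted protein–protein
interaction (PPI) graph whose nodes are gene symbols.  Gene identifiers are
case-sensitive strings matched exactly; no alias resolution is attempted.
Disconnected node pairs return the :data:`UNREACHABLE` sentinel rather than a
large number, so callers must decide explicitly how to treat them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "UNREACHABLE",
    "InteractionNetwork",
    "GeneSet",
    "UnknownNodeError",
    "load_network",
    "load_gene_set",
    "shortest_path_length",
]


class _Unreachable:
    """Sentinel for node pairs with no connecting path."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNREACHABLE"


UNREACHABLE = _Unreachable()

#: header names recognised when auto-detecting a header row in edge lists
EDGE_HEADER_NAMES = frozenset(
    {"gene_a", "gene_b", "gene1", "gene2", "source", "target", "protein_a", "protein_b"}
)


class UnknownNodeError(KeyError):
    """Raised when a queried gene symbol is not a node of the network."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:
        return f"gene symbol not in network: {self.symbol!r}"


@dataclass
class InteractionNetwork:
    """Undirected gene–gene interaction graph.

    Thin wrapper over :class:`networkx.Graph` exposing exactly the services
    the proximity screen needs: node membership, degree, and breadth-first
    shortest-path distances (single-pair and multi-source).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, symbol: str) -> bool:
        return self.graph.has_node(symbol)

    def require_node(self, symbol: str) -> None:
        if not self.graph.has_node(symbol):
            raise UnknownNodeError(symbol)

    def degree(self, symbol: str) -> int:
        """Number of distinct neighbours of ``symbol``."""
        self.require_node(symbol)
        return int(self.graph.degree[symbol])

    def neighbors(self, symbol: str) -> set[str]:
        self.require_node(symbol)
        return set(self.graph.neighbors(symbol))

    def distances_from(self, sources: Iterable[str]) -> dict[str, int]:
        """Multi-source BFS: for every node reachable from ``sources``,
        the minimum unweighted distance to any source."""
        src = [s for s in sources]
        for s in src:
            self.require_node(s)
        if not src:
            return {}
        return {
            n: int(d)
            for n, d in nx.multi_source_dijkstra_path_length(self.graph, set(src)).items()
        }


@dataclass
class GeneSet:
    """A named set of gene symbols (e.g. disease-associated genes)."""

    name: str
    members: set[str]

    def __post_init__(self) -> None:
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def intersect_network(self, net: InteractionNetwork) -> set[str]:
        return self.members & net.nodes


def _looks_like_header(fields: list[str]) -> bool:
    return len(fields) >= 2 and all(f.lower() in EDGE_HEADER_NAMES for f in fields[:2])


def load_network(path: Union[str, Path]) -> InteractionNetwork:
    """Load an undirected network from a two-column whitespace/TSV edge list.

    Extra columns are ignored.  Self-loops and duplicate edges are dropped
    (counts logged).  A header row is auto-detected when both leading fields
    match common column names (``gene_a``/``gene_b`` etc.).

    Raises
    ------
    ValueError
        If the file is empty or contains no valid edge.
    """
    path = Path(path)
    g = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                logger.warning("%s:%d: skipping malformed row %r", path, lineno + 1, line)
                continue
            if n_rows == 0 and _looks_like_header(fields):
                continue
            a, b = fields[0], fields[1]
            n_rows += 1
            if a == b:
                n_self_loops += 1
                g.add_node(a)  # node kept, loop dropped
                continue
            if g.has_edge(a, b):
                n_duplicates += 1
                continue
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError(f"no valid edges found in {path}")
    logger.info(
        "loaded network %s: %d nodes, %d edges (%d self-loops, %d duplicates dropped)",
        path.name, g.number_of_nodes(), g.number_of_edges(), n_self_loops, n_duplicates,
    )
    return InteractionNetwork(graph=g)


def load_gene_set(path: Union[str, Path], name: str | None = None) -> GeneSet:
    """Load a gene set from a one-symbol-per-line file; ``#`` comments allowed."""
    path = Path(path)
    members: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            members.add(line.split()[0])
    return GeneSet(name=name or path.stem, members=members)


def shortest_path_length(net: InteractionNetwork, a: str, b: str):
    """Unweighted (BFS) shortest-path length between nodes ``a`` and ``b``.

    Returns
    -------
    int or UNREACHABLE
        Number of edges on a shortest path; 0 when ``a == b``;
        :data:`UNREACHABLE` when no path exists.
    """
    net.require_node(a)
    net.require_node(b)
    try:
        return int(nx.shortest_path_length(net.graph, a, b))
    except nx.NetworkXNoPath:
        return UNREACHABLE
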