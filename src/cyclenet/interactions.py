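"""Coded gene-interaction tables and the augmented directed graph.

A gene-gene interaction table records, for each ordered pair of genes,
whether the row gene regulates the column gene (``X``), binds it (``Y``),
does both (``X/Y``), or neither (``O``).  The table is turned into a
directed graph over the genes, augmented with two artificial nodes: a
restart node ``S`` (edges to and from every gene, modelling influence
from proteins outside the network) and a transition node ``T`` (an edge
from every gene and a single edge back to ``S``, modelling exit from the
network).  The augmentation guarantees the random walk on the graph is
irreducible and aperiodic: ``gene -> T -> S -> gene`` is a cycle of
length 3, and any gene-gene edge closes a cycle of length 4, so the gcd
of cycle lengths is 1.
"""

from __future__ import annotations

import enum
import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Interaction",
    "InteractionTable",
    "GeneNetwork",
    "NetworkDiagnostics",
    "InteractionTableError",
    "TableShapeError",
    "UnknownCodeError",
    "DuplicateLabelError",
    "RESTART_NODE",
    "TRANSITION_NODE",
    "parse_interaction_table",
    "build_network",
    "validate_network",
    "export_graph",
    "import_graph",
]

RESTART_NODE = "S"
TRANSITION_NODE = "T"


class Interaction(enum.Enum):
    """One cell of the interaction table."""

    NONE = "O"
    REGULATES = "X"
    BINDS = "Y"
    BOTH = "X/Y"


_CODE_MAP = {
    "O": Interaction.NONE,
    "X": Interaction.REGULATES,
    "Y": Interaction.BINDS,
    "X/Y": Interaction.BOTH,
    "Y/X": Interaction.BOTH,
}


class InteractionTableError(ValueError):
    """Base class for interaction-table parse errors."""


class TableShapeError(InteractionTableError):
    """The table is not square (row/column counts disagree with the header)."""


class UnknownCodeError(InteractionTableError):
    """A cell holds a string that is not one of O, X, Y, X/Y."""


class DuplicateLabelError(InteractionTableError):
    """Two header columns carry the same gene label."""


@dataclass(frozen=True)
class InteractionTable:
    """A square grid of interaction codes with one gene label per row/column.

    Convention: ``codes[i][j]`` describes the action of gene *i* (row) on
    gene *j* (column); a regulation code means "gene *i* regulates gene *j*".
    """

    labels: tuple[str, ...]
    codes: tuple[tuple[Interaction, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n == 0:
            raise TableShapeError("interaction table must contain at least one gene")
        if len(set(self.labels)) != n:
            seen: set[str] = set()
            for j, lab in enumerate(self.labels):
                if lab in seen:
                    raise DuplicateLabelError(f"duplicate gene label {lab!r} in column {j + 1}")
                seen.add(lab)
        if any(not lab for lab in self.labels):
            raise TableShapeError("gene labels must be non-empty")
        if len(self.codes) != n or any(len(row) != n for row in self.codes):
            raise TableShapeError(
                f"code grid is not {n}x{n} (rows of lengths {[len(r) for r in self.codes]})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.labels)

    def cell(self, i: int, j: int) -> Interaction:
        """Code at 1-based (row, column) position, matching printed-table indexing."""
        return self.codes[i - 1][j - 1]

    def to_csv(self) -> str:
        """Serialize back to the delimited-text interchange format."""
        lines = [",".join(self.labels)]
        for row in self.codes:
            lines.append(",".join(c.value for c in row))
        return "\n".join(lines) + "\n"


def _normalize_cell(raw: str, row: int, col: int) -> Interaction:
    token = raw.strip().upper()
    token = re.sub(r"\s+", "", token)
    try:
        return _CODE_MAP[token]
    except KeyError:
        raise UnknownCodeError(
            f"unknown interaction code {raw.strip()!r} at row {row}, column {col}"
        ) from None


def parse_interaction_table(source: str | io.TextIOBase) -> InteractionTable:
    """Parse a delimited interaction table.

    Parameters
    ----------
    source
        Text (or open text handle) whose first non-blank line is the
        comma- or tab-separated header of gene labels, followed by one
        data row per gene.  Cells are matched case-insensitively and
        whitespace-tolerantly; ``X/Y`` and ``Y/X`` are synonyms.
    """
    text = source.read() if hasattr(source, "read") else source
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableShapeError("empty interaction table")
    delim = "\t" if "\t" in lines[0] else ","
    labels = tuple(tok.strip() for tok in lines[0].split(delim))
    n = len(labels)
    if len(lines) - 1 != n:
        raise TableShapeError(
            f"non-square table: header lists {n} genes but found {len(lines) - 1} data rows"
        )
    rows = []
    for i, ln in enumerate(lines[1:], start=1):
        cells = ln.split(delim)
        if len(cells) != n:
            raise TableShapeError(
                f"non-square table: row {i} has {len(cells)} cells, expected {n}"
            )
        rows.append(tuple(_normalize_cell(c, i, j) for j, c in enumerate(cells, start=1)))
    return InteractionTable(labels=labels, codes=tuple(rows))


@dataclass(frozen=True)
class GeneNetwork:
    """The augmented directed graph: restart node, gene nodes, transition node.

    ``nodes`` is ordered S, genes (table order), T — the order in which
    probability vectors and transition-matrix rows are laid out.
    """

    graph: nx.DiGraph = field(compare=False)
    labels: tuple[str, ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        return (RESTART_NODE, *self.labels, TRANSITION_NODE)

    @property
    def n_genes(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.labels) + 2

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]


@dataclass(frozen=True)
class NetworkDiagnostics:
    """Ergodicity diagnostics of a directed graph.

    ``period`` is the gcd of all directed cycle lengths (0 for an acyclic
    graph); strong connectivity plus period 1 makes the walk ergodic.
    """

    strongly_connected: bool
    period: int
    node_count: int
    edge_count: int

    @property
    def ergodic(self) -> bool:
        return self.strongly_connected and self.period == 1


def build_network(
    table: InteractionTable,
    include_self_loops: bool = True,
    binding_bidirectional: bool = True,
) -> GeneNetwork:
    """Construct the augmented directed graph from an interaction table.

    Regulation (``X``) contributes the directed edge row->column; binding
    (``Y``) is physically symmetric and by default contributes both
    directions (``binding_bidirectional=False`` keeps row->column only);
    ``X/Y`` contributes the union.  Diagonal non-``O`` cells become
    self-loops when ``include_self_loops`` (default).  Duplicate
    contributions collapse to a single edge.  The artificial edges
    S->gene, gene->S, gene->T and T->S are always added.
    """
    g = nx.DiGraph()
    g.add_node(RESTART_NODE, role="restart")
    for lab in table.labels:
        g.add_node(lab, role="gene")
    g.add_node(TRANSITION_NODE, role="transition")

    for i, row in enumerate(table.codes):
        for j, code in enumerate(row):
            if code is Interaction.NONE:
                continue
            if i == j and not include_self_loops:
                continue
            u, v = table.labels[i], table.labels[j]
            if code in (Interaction.REGULATES, Interaction.BOTH):
                g.add_edge(u, v)
            if code in (Interaction.BINDS, Interaction.BOTH):
                g.add_edge(u, v)
                if binding_bidirectional:
                    g.add_edge(v, u)

    for lab in table.labels:
        g.add_edge(RESTART_NODE, lab)
        g.add_edge(lab, RESTART_NODE)
        g.add_edge(lab, TRANSITION_NODE)
    g.add_edge(TRANSITION_NODE, RESTART_NODE)
    return GeneNetwork(graph=g, labels=table.labels)


def _component_period(graph: nx.DiGraph, component: set[str]) -> int:
    """gcd of cycle lengths inside one strongly connected component.

    BFS level differences: for every intra-component edge u->v the value
    level(u) + 1 - level(v) is a cycle-length difference; their gcd is
    the component's period.  Trivial (single node, no self-loop)
    components contain no cycle and return 0.
    """
    root = next(iter(component))
    levels = {root: 0}
    queue = [root]
    g = 0
    while queue:
        u = queue.pop()
        for v in graph.successors(u):
            if v not in component:
                continue
            if v in levels:
                g = math.gcd(g, levels[u] + 1 - levels[v])
            else:
                levels[v] = levels[u] + 1
                queue.append(v)
    return abs(g)


def validate_network(network: GeneNetwork) -> NetworkDiagnostics:
    """Check strong connectivity and compute the graph period."""
    g = network.graph
    strongly = nx.is_strongly_connected(g)
    period = 0
    for comp in nx.strongly_connected_components(g):
        period = math.gcd(period, _component_period(g, comp))
    return NetworkDiagnostics(
        strongly_connected=strongly,
        period=period,
        node_count=g.number_of_nodes(),
        edge_count=g.number_of_edges(),
    )


def export_graph(network: GeneNetwork, format: str = "graphml") -> str:
    """Serialize the network as GraphML or DOT text with node role attributes."""
    if format == "graphml":
        return "\n".join(nx.generate_graphml(network.graph))
    if format == "dot":
        lines = ["digraph cellcycle {"]
        for node in network.nodes:
            lines.append(f'  "{node}" [role="{network.role(node)}"];')
        for u, v in network.graph.edges():
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)
    raise ValueError(f"unknown export format {format!r} (expected 'graphml' or 'dot')")


_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*\[role="([^"]+)"\]\s*;\s*$')
_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"\s*;\s*$')


def import_graph(text: str, format: str = "graphml") -> GeneNetwork:
    """Re-parse an :func:`export_graph` artifact back into a network."""
    if format == "graphml":
        g = nx.parse_graphml(text)
        digraph = nx.DiGraph()
        for node, data in g.nodes(data=True):
            digraph.add_node(node, role=data["role"])
        digraph.add_edges_from(g.edges())
    elif format == "dot":
        digraph = nx.DiGraph()
        for ln in text.splitlines():
            m = _DOT_NODE.match(ln)
            if m:
                digraph.add_node(m.group(1), role=m.group(2))
                continue
            m = _DOT_EDGE.match(ln)
            if m:
                digraph.add_edge(m.group(1), m.group(2))
    else:
        raise ValueError(f"unknown import format {format!r} (expected 'graphml' or 'dot')")
    labels = tuple(n for n, d in digraph.nodes(data=True) if d.get("role") == "gene")
    return GeneNetwork(graph=digraph, labels=labels)
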