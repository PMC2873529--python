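"""Directed acyclic graphs: representation, enumeration, core extensions.

Two enumeration problems matter here. First, exhaustively listing every
labeled DAG on up to 5 nodes (29,281 graphs at n = 5), used to score the full
space of candidate core wirings. Second, listing every way a single new gene
can attach to a fixed core of k genes: each of the 2k possible connecting
edges is either present or absent (2^(2k) = 1024 candidate subsets at k = 5),
filtered to those keeping the combined graph acyclic.

Enumeration order is deterministic (lexicographic on edge bitmasks) so that
downstream score ties resolve reproducibly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigError, DataError

MAX_ENUM_NODES = 5

__all__ = [
    "DAG",
    "CoreNetwork",
    "Extension",
    "is_acyclic",
    "enumerate_dags",
    "enumerate_extensions",
    "read_network",
    "write_network",
]


@dataclass(frozen=True)
class DAG:
    """A labeled directed graph intended to be acyclic.

    Endpoint membership and self-loops are checked at construction;
    acyclicity is checked unless ``check=False`` is passed (so that cyclic
    *candidates* can still be represented and fed to :func:`is_acyclic`).
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Sequence[str], edges=(), *, check: bool = True):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", frozenset((str(a), str(b)) for a, b in edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise DataError("duplicate node labels")
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a not in node_set or b not in node_set:
                raise DataError(f"edge endpoint {a!r}->{b!r} not among nodes")
            if a == b:
                raise DataError(f"self-loop on {a!r}")
        if check and not is_acyclic(self):
            raise DataError("graph contains a directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(b for a, b in self.edges if a == node))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def edge_string(self) -> str:
        """Canonical semicolon-joined 'parent->child' listing (sorted)."""
        return ";".join(f"{a}->{b}" for a, b in sorted(self.edges))


@dataclass
class CoreNetwork:
    """A fixed, known pathway: a DAG over core genes plus the mapping from
    node labels to expression-matrix row ids (identity by default)."""

    dag: DAG
    gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_map:
            self.gene_map = {n: n for n in self.dag.nodes}
        missing = set(self.dag.nodes) - set(self.gene_map)
        if missing:
            raise DataError(f"core nodes without a row mapping: {sorted(missing)}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def row_ids(self) -> tuple[str, ...]:
        return tuple(self.gene_map[n] for n in self.dag.nodes)


@dataclass(frozen=True)
class Extension:
    """One way of attaching a new gene to the core: which core nodes send an
    edge into the new gene (its parents) and which receive one (children)."""

    new_gene: str
    in_edges: frozenset[str]
    out_edges: frozenset[str]

    def __post_init__(self) -> None:
        if self.in_edges & self.out_edges:
            raise DataError("a core node cannot be both parent and child of the new gene")

    @property
    def n_edges(self) -> int:
        return len(self.in_edges) + len(self.out_edges)

    def combined_dag(self, core: CoreNetwork, *, check: bool = True) -> DAG:
        edges = set(core.dag.edges)
        edges |= {(c, self.new_gene) for c in self.in_edges}
        edges |= {(self.new_gene, c) for c in self.out_edges}
        return DAG(core.dag.nodes + (self.new_gene,), edges, check=check)


def is_acyclic(g: DAG) -> bool:
    """True iff a topological order of ``g`` exists."""
    return nx.is_directed_acyclic_graph(g.to_networkx())


# ---------------------------------------------------------------------------
# Exhaustive small-DAG enumeration
# ---------------------------------------------------------------------------

def _edge_list(n: int) -> list[tuple[int, int]]:
    """Bit order for directed edges on n nodes: (i, j), i != j, lexicographic."""
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def _acyclic_edge_masks(n: int) -> np.ndarray:
    """All edge bitmasks on n nodes whose graph is acyclic, ascending.

    Vectorized Kahn elimination over every candidate at once: per node,
    compute the parent-node bitmask implied by each edge mask, then peel
    parentless nodes for n rounds; masks with all nodes peeled are acyclic.
    """
    edges = _edge_list(n)
    masks = np.arange(1 << len(edges), dtype=np.uint32)
    parent_masks = [np.zeros(masks.shape, dtype=np.uint8) for _ in range(n)]
    for b, (i, j) in enumerate(edges):
        parent_masks[j] |= (((masks >> np.uint32(b)) & 1).astype(np.uint8) << i)
    removed = np.zeros(masks.shape, dtype=np.uint8)
    for _ in range(n):
        for j in range(n):
            can = (parent_masks[j] & ~removed) == 0
            removed |= can.astype(np.uint8) << j
    return masks[removed == (1 << n) - 1]


def enumerate_dags(n: int, labels: Sequence[str] | None = None) -> Iterator[DAG]:
    """Yield every labeled DAG on ``n`` nodes exactly once.

    Counts follow the labeled-DAG sequence 1, 3, 25, 543, 29281 for
    n = 1..5. Guarded at n = 5: beyond that the space explodes and the
    single-gene expansion workflow is the intended tool.
    """
    if not 1 <= n <= MAX_ENUM_NODES:
        raise ConfigError(
            f"enumerate_dags supports 1..{MAX_ENUM_NODES} nodes (got {n}); for larger "
            "problems attach genes one at a time with enumerate_extensions"
        )
    if labels is None:
        labels = tuple(f"V{i + 1}" for i in range(n))
    else:
        labels = tuple(labels)
        if len(labels) != n:
            raise ConfigError(f"expected {n} labels, got {len(labels)}")
    edges = _edge_list(n)
    for mask in _acyclic_edge_masks(n):
        mask = int(mask)
        es = [(labels[i], labels[j]) for b, (i, j) in enumerate(edges) if mask >> b & 1]
        yield DAG(labels, es, check=False)


# ---------------------------------------------------------------------------
# Single-gene extensions of a fixed core
# ---------------------------------------------------------------------------

def enumerate_extensions(core: CoreNetwork, new_gene: str) -> Iterator[Extension]:
    """Yield every acyclic attachment of ``new_gene`` to the core.

    The candidate space is all 2^(2k) subsets of the 2k possible connecting
    edges (k core nodes, each may send an edge in and/or receive one out);
    subsets that put a node on both sides (a 2-cycle) or close a longer cycle
    through the core are filtered out. Order: ascending edge bitmask, where
    bit 2i is the in-edge from core node i and bit 2i+1 the out-edge to it.
    """
    nodes = core.dag.nodes
    if new_gene in nodes:
        raise DataError(f"new gene {new_gene!r} is already a core node")
    k = len(nodes)
    g = core.dag.to_networkx()
    # a cycle through the new gene needs a core path from an out-target back
    # to an in-source; precompute strict-descendant bitmasks
    idx = {n: i for i, n in enumerate(nodes)}
    desc_mask = [0] * k
    for n in nodes:
        m = 0
        for d in nx.descendants(g, n):
            m |= 1 << idx[d]
        desc_mask[idx[n]] = m
    for mask in range(1 << (2 * k)):
        in_mask = out_mask = 0
        for i in range(k):
            if mask >> (2 * i) & 1:
                in_mask |= 1 << i
            if mask >> (2 * i + 1) & 1:
                out_mask |= 1 << i
        if in_mask & out_mask:
            continue
        reach = 0
        om = out_mask
        while om:
            i = (om & -om).bit_length() - 1
            reach |= desc_mask[i]
            om &= om - 1
        if reach & in_mask:
            continue
        yield Extension(
            new_gene,
            frozenset(nodes[i] for i in range(k) if in_mask >> i & 1),
            frozenset(nodes[i] for i in range(k) if out_mask >> i & 1),
        )


# ---------------------------------------------------------------------------
# Network file I/O
# ---------------------------------------------------------------------------

def read_network(path) -> DAG:
    """Read an edge-list TSV (``parent<TAB>child`` per line, optional
    ``#nodes:<TAB-or-space separated labels`` header for isolated nodes) or a
    SIF file (``parent interaction child``)."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    seen: set[str] = set()

    def add_node(n: str) -> None:
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#nodes:"):
                for n in line[len("#nodes:"):].replace("\t", " ").split():
                    add_node(n)
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:  # SIF: parent interaction child
                a, _, b = parts
            else:
                raise DataError(f"{path}: line {lineno}: expected 2 or 3 fields")
            add_node(a)
            add_node(b)
            edges.append((a, b))
    return DAG(nodes, edges)


def write_network(dag: DAG, path) -> None:
    isolated = [n for n in dag.nodes if not dag.parents(n) and not dag.children(n)]
    with open(path, "w", encoding="utf-8") as fh:
        if isolated:
            fh.write("#nodes:\t" + "\t".join(isolated) + "\n")
        for a, b in sorted(dag.edges):
            fh.write(f"{a}\t{b}\n")
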