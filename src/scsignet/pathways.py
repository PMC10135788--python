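"""Effector-circuit decomposition of directed signaling-pathway graphs.

A signaling pathway is modeled as a directed graph whose nodes are genes.
Signal enters at *receptors* (nodes with no ascendants) and terminates at
*effectors* (nodes with no descendants), the proteins that trigger the
pathway's cellular function.  Each effector ``e`` defines an *effector
circuit*: the minimal functional sub-pathway consisting of ``e`` together
with every node that can reach ``e`` along directed edges (in particular
every receptor wired to ``e``).

Circuits are turned into a binary gene x circuit *indicator matrix*; the
per-pathway matrices are outer-joined over a common gene axis into the
global indicator that masks the first layer of the classifier network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class PathwayGraph:
    """A directed gene graph for one signaling pathway.

    Self-loops are tolerated but ignored for degree-based receptor/effector
    calls.  Cycles are allowed: membership is defined by reachability, which
    handles them naturally.
    """

    pathway_id: str
    nodes: frozenset
    edges: frozenset

    def __post_init__(self):
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"edge ({u!r}, {v!r}) has endpoint outside node set "
                    f"of pathway {self.pathway_id!r}"
                )

    @classmethod
    def from_edges(cls, pathway_id: str, edges: Iterable[tuple], extra_nodes: Iterable = ()) -> "PathwayGraph":
        edges = frozenset((str(u), str(v)) for u, v in edges)
        nodes = frozenset(str(n) for n in extra_nodes) | {u for u, _ in edges} | {v for _, v in edges}
        return cls(pathway_id=pathway_id, nodes=nodes, edges=edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class EffectorCircuit:
    """One effector's minimal sub-pathway: the effector plus all upstream genes."""

    circuit_id: str
    pathway_id: str
    effector: str
    members: frozenset

    def __post_init__(self):
        if self.effector not in self.members:
            raise ValueError(f"effector {self.effector!r} not in circuit members")


@dataclass
class IndicatorMatrix:
    """Binary gene x circuit membership matrix.

    Row ``i``, column ``j`` is 1 iff gene ``i`` belongs to circuit ``j``.
    Zeros in this matrix force the corresponding first-layer weights of the
    classifier to zero.
    """

    genes: list
    circuits: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.genes), len(self.circuits)):
            raise ValueError(
                f"indicator shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.circuits)} circuits"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def nnz(self) -> int:
        return int(self.values.sum())

    def column(self, circuit_id) -> np.ndarray:
        return self.values[:, self.circuits.index(circuit_id)]


def _degree_edges(graph: PathwayGraph):
    # self-loops are excluded from degree computations
    return [(u, v) for u, v in graph.edges if u != v]


def find_effectors(graph: PathwayGraph) -> set:
    """Nodes with no descendants (out-degree 0, ignoring self-loops)."""
    if not graph.nodes:
        raise ValueError("empty pathway")
    with_out = {u for u, _ in _degree_edges(graph)}
    return set(graph.nodes) - with_out


def find_receptors(graph: PathwayGraph) -> set:
    """Nodes with no ascendants (in-degree 0, ignoring self-loops)."""
    if not graph.nodes:
        raise ValueError("empty pathway")
    with_in = {v for _, v in _degree_edges(graph)}
    return set(graph.nodes) - with_in


def decompose_circuits(graph: PathwayGraph) -> list:
    """Split a pathway into effector circuits.

    One circuit per effector ``e``; members are ``{e}`` plus the reverse
    reachability closure of ``e`` (every node with a directed path to ``e``),
    which in particular contains every receptor connected to ``e``.  Circuits
    are returned sorted by effector id and named ``pathway_id:effector`` so
    ids stay globally unique after joining pathways.
    """
    effectors = find_effectors(graph)
    if not effectors:
        raise ValueError(f"no effector nodes in pathway {graph.pathway_id!r} (every node lies on a cycle)")
    g = graph.to_networkx()
    out = []
    for e in sorted(effectors):
        members = frozenset(nx.ancestors(g, e)) | {e}
        out.append(
            EffectorCircuit(
                circuit_id=f"{graph.pathway_id}:{e}",
                pathway_id=graph.pathway_id,
                effector=e,
                members=members,
            )
        )
    return out


def build_indicator(circuits: Sequence[EffectorCircuit], gene_order: Sequence) -> IndicatorMatrix:
    """Binary membership matrix over ``gene_order`` with one column per circuit."""
    gene_order = list(gene_order)
    idx = {g: i for i, g in enumerate(gene_order)}
    values = np.zeros((len(gene_order), len(circuits)), dtype=np.uint8)
    for j, c in enumerate(circuits):
        for g in c.members:
            if g not in idx:
                raise ValueError(f"gene {g!r} of circuit {c.circuit_id!r} missing from gene_order")
            values[idx[g], j] = 1
    return IndicatorMatrix(genes=gene_order, circuits=[c.circuit_id for c in circuits], values=values)


def join_indicators(per_pathway: Sequence[IndicatorMatrix]) -> IndicatorMatrix:
    """Outer-join per-pathway indicators on the gene axis.

    Genes become the sorted union of all input gene sets; circuits are
    concatenated in input order.  A gene absent from a pathway gets 0 in that
    pathway's columns.
    """
    if not per_pathway:
        raise ValueError("need at least one indicator matrix")
    seen: set = set()
    circuits: list = []
    for m in per_pathway:
        for c in m.circuits:
            if c in seen:
                raise ValueError(f"duplicate circuit id {c!r} across indicator matrices")
            seen.add(c)
            circuits.append(c)
    genes = sorted(set().union(*(m.genes for m in per_pathway)))
    idx = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(circuits)), dtype=np.uint8)
    col = 0
    for m in per_pathway:
        rows = np.array([idx[g] for g in m.genes], dtype=int)
        values[rows, col : col + len(m.circuits)] = m.values
        col += len(m.circuits)
    return IndicatorMatrix(genes=genes, circuits=circuits, values=values)
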