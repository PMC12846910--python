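"""Assembly and serialization of immune-cell knowledge graphs.

The ICKG is a directed multigraph. Nodes are keyed by ``(name, node_type)``
so that the same string tagged as, say, a gene in one abstract and a pathway
in another yields two distinct nodes. Between a given source and target there
is at most one edge per direction; activate and inhibit edges may coexist in
parallel, preserving literature disagreement. Each edge's weight equals the
number of distinct supporting abstracts, and the abstract identifiers are
kept on the edge as provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .entities import AliasTable
from .types import Direction, NodeType, ParseError, RelationTriple, ValidationError

NodeKey = tuple[str, str]  # (name, node_type value)


class ICKG(nx.MultiDiGraph):
    """Typed, signed, weighted, provenance-tracked directed multigraph.

    Node keys are ``(name, node_type)`` tuples; node attributes mirror them
    (``name``, ``node_type``). Edge keys are the direction strings
    ``"activate"`` / ``"inhibit"``; edge attributes are ``direction``,
    ``weight`` (int, number of distinct supporting abstracts) and
    ``provenance`` (frozenset of abstract ids).
    """

    def add_entity(self, name: str, node_type: NodeType | str) -> NodeKey:
        node_type = NodeType(node_type)
        if not name:
            raise ValidationError("node name must be non-empty")
        key = (name, node_type.value)
        if key not in self:
            self.add_node(key, name=name, node_type=node_type.value)
        return key

    def nodes_of_type(self, node_type: NodeType | str) -> list[NodeKey]:
        t = NodeType(node_type).value
        return sorted(n for n, d in self.nodes(data=True) if d["node_type"] == t)

    def gene_nodes(self) -> list[NodeKey]:
        return self.nodes_of_type(NodeType.GENE)

    def pathway_nodes(self) -> list[NodeKey]:
        return self.nodes_of_type(NodeType.PATHWAY)

    def resolve(self, node: NodeKey | str) -> NodeKey:
        """Resolve a node given either its key or its bare name.

        A bare name must match exactly one node (case-insensitive on name);
        ambiguity across node types raises a :class:`ValidationError`.
        """
        if isinstance(node, tuple):
            key = (node[0], NodeType(node[1]).value)
            if key not in self:
                raise ValidationError(f"node {key} not in graph")
            return key
        folded = str(node).casefold()
        hits = [n for n in self.nodes if n[0].casefold() == folded]
        if not hits:
            raise ValidationError(f"no node named {node!r} in graph")
        if len(hits) > 1:
            raise ValidationError(
                f"name {node!r} is ambiguous across node types: {sorted(hits)}"
            )
        return hits[0]


def assemble_graph(
    triples: Iterable[RelationTriple], aliases: AliasTable | None = None
) -> ICKG:
    """Aggregate relation triples into an ICKG.

    Edge weight is the number of *distinct* abstract ids supporting the
    (source, target, direction) relation; duplicate triples from the same
    abstract do not increase the weight. Node names are case-fold merged;
    gene names are normalized through ``aliases`` when given and reported
    as uppercase symbols.
    """
    g = ICKG()
    canon: dict[tuple[str, str], str] = {}  # (folded name, type) -> display name

    def canonical_name(name: str, node_type: NodeType) -> str:
        if not name:
            raise ValidationError("relation endpoint has empty name")
        if node_type is NodeType.GENE:
            if aliases is not None:
                hit = aliases.normalize(name)
                if hit is not None:
                    return hit
            return name.upper()
        key = (name.casefold(), node_type.value)
        return canon.setdefault(key, name)

    support: dict[tuple[NodeKey, NodeKey, str], set[str]] = {}
    for t in triples:
        src = g.add_entity(canonical_name(t.source, t.source_type), t.source_type)
        tgt = g.add_entity(canonical_name(t.target, t.target_type), t.target_type)
        if src == tgt:
            raise ValidationError(f"self-loop after normalization on {src}")
        support.setdefault((src, tgt, t.direction.value), set()).add(t.abstract_id)

    for (src, tgt, direction), ids in sorted(
        support.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        g.add_edge(
            src,
            tgt,
            key=direction,
            direction=direction,
            weight=len(ids),
            provenance=frozenset(ids),
        )
    return g


@dataclass
class GraphStats:
    """Node/edge accounting plus per-node degree centrality."""

    n_nodes: int
    n_edges: int
    n_activate: int
    n_inhibit: int
    nodes_by_type: dict = field(default_factory=dict)
    degree_centrality: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_activate": self.n_activate,
            "n_inhibit": self.n_inhibit,
            "nodes_by_type": dict(sorted(self.nodes_by_type.items())),
            "degree_centrality": {
                f"{t}:{name}": c
                for (name, t), c in sorted(self.degree_centrality.items())
            },
        }


def graph_stats(g: ICKG) -> GraphStats:
    """Exact counts by node type and edge direction.

    Degree centrality is total degree (in + out, parallel edges counted)
    divided by ``n_nodes - 1``.
    """
    by_type: dict[str, int] = {t.value: 0 for t in NodeType}
    for _, d in g.nodes(data=True):
        by_type[d["node_type"]] += 1
    n_act = sum(1 for *_e, d in g.edges(data=True) if d["direction"] == "activate")
    n = g.number_of_nodes()
    centrality = (
        {v: g.degree(v) / (n - 1) for v in g.nodes} if n > 1 else {v: 0.0 for v in g}
    )
    return GraphStats(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_activate=n_act,
        n_inhibit=g.number_of_edges() - n_act,
        nodes_by_type={t: c for t, c in by_type.items() if c},
        degree_centrality=centrality,
    )


def top_edge_subgraph(g: ICKG, fraction: float) -> ICKG:
    """Keep the heaviest ``fraction`` of edges (weight ties kept), drop isolates."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if g.number_of_edges() == 0:
        raise ValidationError("cannot take top-edge subgraph of an edgeless graph")
    weights = np.array([d["weight"] for *_e, d in g.edges(data=True)])
    threshold = float(np.quantile(weights, 1.0 - fraction, method="higher"))
    out = ICKG()
    for u, v, k, d in g.edges(keys=True, data=True):
        if d["weight"] >= threshold:
            out.add_node(u, **g.nodes[u])
            out.add_node(v, **g.nodes[v])
            out.add_edge(u, v, key=k, **d)
    return out


# --- serialization ---------------------------------------------------------

_TSV_HEADER = "source\tsource_type\ttarget\ttarget_type\tdirection\tweight\tprovenance"


def write_graph(g: ICKG, path: str | Path) -> None:
    """Write GraphML (``.graphml``) or edge-list TSV (anything else).

    The TSV dialect lists every node on ``#NODE`` header lines so that
    isolated nodes survive a round-trip; provenance is semicolon-joined.
    """
    path = Path(path)
    if path.suffix == ".graphml":
        h = nx.MultiDiGraph()
        for (name, t), d in sorted(g.nodes(data=True)):
            h.add_node(f"{t}::{name}", name=name, node_type=t)
        for (sn, st), (tn, tt), k, d in sorted(g.edges(keys=True, data=True)):
            h.add_edge(
                f"{st}::{sn}",
                f"{tt}::{tn}",
                key=k,
                direction=d["direction"],
                weight=int(d["weight"]),
                provenance=";".join(sorted(d["provenance"])),
            )
        nx.write_graphml(h, path)
        return
    lines = [_TSV_HEADER]
    for name, t in sorted(g.nodes):
        lines.append(f"#NODE\t{name}\t{t}")
    for (sn, st), (tn, tt), k, d in sorted(g.edges(keys=True, data=True)):
        prov = ";".join(sorted(d["provenance"]))
        lines.append(f"{sn}\t{st}\t{tn}\t{tt}\t{d['direction']}\t{d['weight']}\t{prov}")
    path.write_text("\n".join(lines) + "\n")


def _check_node_type(value: str, where: str) -> str:
    try:
        return NodeType(value).value
    except ValueError:
        raise ParseError(
            f"{where}: unknown node_type {value!r} "
            f"(allowed: {[t.value for t in NodeType]})"
        ) from None


def read_graph(path: str | Path) -> ICKG:
    """Read a graph written by :func:`write_graph`; inverse including provenance."""
    path = Path(path)
    g = ICKG()
    if path.suffix == ".graphml":
        try:
            h = nx.read_graphml(path, force_multigraph=True)
        except Exception as exc:  # lxml/expat errors vary
            raise ParseError(f"{path}: not a readable GraphML file: {exc}") from exc
        for nid, d in h.nodes(data=True):
            if "name" not in d or "node_type" not in d:
                raise ParseError(f"{path}: node {nid!r} missing name/node_type")
            g.add_entity(d["name"], _check_node_type(d["node_type"], f"{path}:{nid}"))
        for u, v, k, d in h.edges(keys=True, data=True):
            src = (h.nodes[u]["name"], h.nodes[u]["node_type"])
            tgt = (h.nodes[v]["name"], h.nodes[v]["node_type"])
            prov = frozenset(p for p in str(d.get("provenance", "")).split(";") if p)
            g.add_edge(
                src,
                tgt,
                key=d["direction"],
                direction=Direction(d["direction"]).value,
                weight=int(d["weight"]),
                provenance=prov,
            )
        return g
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if lineno == 1:
            if line != _TSV_HEADER:
                raise ParseError(f"{path}:1: unexpected header {line!r}")
            continue
        if not line:
            continue
        fields = line.split("\t")
        if fields[0] == "#NODE":
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: malformed #NODE line")
            g.add_entity(fields[1], _check_node_type(fields[2], f"{path}:{lineno}"))
            continue
        if len(fields) != 7:
            raise ParseError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
        sn, st, tn, tt, direction, weight, prov = fields
        src = g.add_entity(sn, _check_node_type(st, f"{path}:{lineno}"))
        tgt = g.add_entity(tn, _check_node_type(tt, f"{path}:{lineno}"))
        try:
            direction = Direction(direction).value
            weight = int(weight)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        g.add_edge(
            src,
            tgt,
            key=direction,
            direction=direction,
            weight=weight,
            provenance=frozenset(p for p in prov.split(";") if p),
        )
    return g


def graphs_equal(a: ICKG, b: ICKG) -> bool:
    """Structural equality including node types, directions, weights, provenance."""

    def edge_set(g: ICKG):
        return {
            (u, v, k, d["weight"], frozenset(d["provenance"]))
            for u, v, k, d in g.edges(keys=True, data=True)
        }

    return set(a.nodes) == set(b.nodes) and edge_set(a) == edge_set(b)
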