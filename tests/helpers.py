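"""Independent oracles and random-graph builders shared by the tests.

The dense PageRank oracle is deliberately written against plain numpy
arrays with no shared code path into the package's sparse solver.
"""

from __future__ import annotations

import numpy as np

from ickg.graph import ICKG
from ickg.types import NodeType


def dense_pagerank(
    g: ICKG,
    seeds: list | None = None,
    alpha: float = 0.85,
    iters: int = 5000,
    tol: float = 1e-15,
) -> dict:
    """Dense power-iteration personalized PageRank (oracle implementation)."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        W[idx[u], idx[v]] += d["weight"]
    s = W.sum(axis=1)
    P = np.divide(W, s[:, None], out=np.zeros_like(W), where=s[:, None] > 0)
    dangling = (s == 0).astype(float)
    p = np.full(n, 1.0 / n)
    if seeds:
        p = np.zeros(n)
        for v in seeds:
            p[idx[v]] = 1.0 / len(seeds)
    x = p.copy()
    for _ in range(iters):
        x_new = alpha * (x @ P + (x @ dangling) * p) + (1 - alpha) * p
        if np.abs(x_new - x).sum() < tol:
            break
        x = x_new
    return dict(zip(nodes, x))


def random_ickg(
    seed: int,
    n_nodes: int = 20,
    n_edges: int = 40,
    max_weight: int = 9,
) -> ICKG:
    """Random weighted digraph with gene/pathway nodes for oracle comparisons."""
    rng = np.random.default_rng(seed)
    g = ICKG()
    names = []
    for i in range(n_nodes):
        t = NodeType.GENE if rng.random() < 0.8 else NodeType.PATHWAY
        names.append(g.add_entity(f"N{i}", t))
    e = 0
    while e < n_edges:
        a, b = rng.integers(n_nodes, size=2)
        if a == b:
            continue
        direction = "activate" if rng.random() < 0.7 else "inhibit"
        u, v = names[a], names[b]
        if g.has_edge(u, v, key=direction):
            continue
        w = int(rng.integers(1, max_weight + 1))
        g.add_edge(
            u, v, key=direction, direction=direction, weight=w,
            provenance=frozenset(f"PM{e}.{j}" for j in range(w)),
        )
        e += 1
    return g


def gene_star_with_candidate(
    n_genes: int, seed: int, n_extra_edges: int = 40, candidate: str = "C"
) -> tuple[ICKG, tuple]:
    """Genes all feeding one concept node with random weights, plus noise edges."""
    rng = np.random.default_rng(seed)
    g = ICKG()
    genes = [g.add_entity(f"g{i}", NodeType.GENE) for i in range(n_genes)]
    cand = g.add_entity(candidate, NodeType.PATHWAY)
    for u in genes:
        g.add_edge(
            u, cand, key="activate", direction="activate",
            weight=int(rng.integers(1, 8)), provenance=frozenset({u[0]}),
        )
    added = 0
    while added < n_extra_edges:
        a, b = rng.choice(n_genes, 2, replace=False)
        u, v = genes[a], genes[b]
        if g.has_edge(u, v, key="activate"):
            continue
        g.add_edge(
            u, v, key="activate", direction="activate",
            weight=int(rng.integers(1, 5)), provenance=frozenset({f"x{added}"}),
        )
        added += 1
    return g, cand
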