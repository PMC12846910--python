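"""Knowledge-graph reasoning: propagation, significance, and explanation.

Relevance of graph nodes to a seed set is measured with personalized
PageRank (damping 0.85): the restart distribution puts uniform mass on the
seed nodes, edge weights (parallel activate/inhibit edges summed) act as
transition weights, and dangling mass is redistributed to the restart
vector. Significance is assessed with a permutation null that replaces the
seed set by uniform same-size draws from the graph's gene nodes; the
p-value is the fraction n/N of permutations whose score meets or exceeds
the observed one, with 95% CIs from the 2.5th/97.5th permutation
percentiles. A temperature-softmax random walk (transition probability
proportional to exp(w/T)) provides an alternative propagation scheme, and
degree-preserving edge rewiring provides the shuffled-graph control.

Edge sign does not enter propagation; inhibition surfaces only in
explanation output, where a predicted gene is called inhibited when its
explanation path crosses an odd number of inhibit edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .evaluation import jaccard_index
from .graph import ICKG, NodeKey
from .types import (
    NodeScoreTable,
    NodeType,
    PageRankConfig,
    RandomWalkConfig,
    ValidationError,
)

logger = logging.getLogger(__name__)


def collapsed_weights(g: ICKG, reverse: bool = False) -> dict[tuple[NodeKey, NodeKey], float]:
    """Transition weight per (u, v): parallel activate/inhibit weights summed."""
    w: dict[tuple[NodeKey, NodeKey], float] = {}
    for u, v, d in g.edges(data=True):
        pair = (v, u) if reverse else (u, v)
        w[pair] = w.get(pair, 0.0) + float(d["weight"])
    return w


class PPRSolver:
    """Power iteration on a cached sparse transition matrix.

    Caching the matrix makes the thousands of solves needed by permutation
    tests cheap: each solve only changes the restart vector.
    """

    def __init__(self, g: ICKG, reverse: bool = False):
        if g.number_of_nodes() == 0:
            raise ValidationError("graph is empty")
        self.nodes: list[NodeKey] = sorted(g.nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        w = collapsed_weights(g, reverse=reverse)
        rows = np.array([self.index[u] for (u, _v) in w], dtype=np.int64)
        cols = np.array([self.index[v] for (_u, v) in w], dtype=np.int64)
        vals = np.array(list(w.values()), dtype=float)
        out_strength = np.zeros(n)
        np.add.at(out_strength, rows, vals)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = vals / out_strength[rows]
        P = sparse.csr_array((vals, (rows, cols)), shape=(n, n))
        self._PT = P.T.tocsr()
        self.dangling = out_strength == 0.0

    def restart_vector(self, personalization: Iterable[NodeKey] | None) -> np.ndarray:
        n = len(self.nodes)
        if personalization is None:
            return np.full(n, 1.0 / n)
        idx = [self.index[v] for v in personalization]
        if not idx:
            raise ValidationError("personalization set is empty")
        p = np.zeros(n)
        p[idx] = 1.0 / len(idx)
        return p

    def solve(
        self, personalization: Iterable[NodeKey] | None, cfg: PageRankConfig
    ) -> np.ndarray:
        p = self.restart_vector(personalization)
        x = p.copy()
        for _ in range(cfg.max_iterations):
            dangling_mass = float(x[self.dangling].sum())
            x_new = cfg.alpha * (self._PT @ x + dangling_mass * p) + (1 - cfg.alpha) * p
            if float(np.abs(x_new - x).sum()) < cfg.tolerance:
                return x_new
            x = x_new
        raise RuntimeError(
            f"PageRank failed to converge in {cfg.max_iterations} iterations"
        )


def _resolve_set(g: ICKG, nodes: Iterable[NodeKey | str]) -> list[NodeKey]:
    resolved, offenders = [], []
    for v in nodes:
        try:
            resolved.append(g.resolve(v))
        except ValidationError:
            offenders.append(v)
    if offenders:
        raise ValidationError(f"nodes not in graph: {offenders}")
    return sorted(set(resolved))


def personalized_pagerank(
    g: ICKG,
    personalization: Iterable[NodeKey | str] | None = None,
    cfg: PageRankConfig | None = None,
) -> dict[NodeKey, float]:
    """Converged personalized PageRank scores, summing to 1.

    ``personalization`` is a set of nodes receiving uniform restart mass
    (empty/None means uniform over all nodes). Edge signs are ignored here.
    """
    cfg = cfg or PageRankConfig()
    seeds = _resolve_set(g, personalization) if personalization else None
    solver = PPRSolver(g)
    x = solver.solve(seeds, cfg)
    return dict(zip(solver.nodes, x.tolist()))


def permutation_test(
    g: ICKG,
    seed_set: Iterable[NodeKey | str],
    candidate_nodes: Iterable[NodeKey | str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    cfg: PageRankConfig | None = None,
    permute_type: NodeType = NodeType.GENE,
    direction: str = "forward",
    estimator: str = "n_over_N",
) -> NodeScoreTable:
    """Permutation significance of personalized PageRank scores.

    Permuted seed sets are uniform, same-size, without-replacement draws
    from the graph's ``permute_type`` nodes (genes by default). For each
    candidate node, ``p = n / n_perm`` where n counts permutations whose
    score met or exceeded the observed score; ``estimator="add_one"``
    switches to the (n+1)/(N+1) variant. CI bounds are the 2.5th and 97.5th
    percentiles of the permutation distribution.
    """
    cfg = cfg or PageRankConfig()
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    seeds = _resolve_set(g, seed_set)
    if not seeds:
        raise ValidationError("seed_set must be non-empty")
    pool = g.nodes_of_type(permute_type)
    if len(pool) < len(seeds):
        raise ValidationError(
            f"graph has {len(pool)} {permute_type.value} nodes, fewer than the "
            f"seed-set size {len(seeds)}"
        )
    solver = PPRSolver(g, reverse=(direction == "reverse"))
    candidates = (
        _resolve_set(g, candidate_nodes) if candidate_nodes is not None else solver.nodes
    )
    cand_idx = np.array([solver.index[v] for v in candidates])

    observed_full = solver.solve(seeds, cfg)
    observed = observed_full[cand_idx]
    rng = np.random.default_rng(seed)
    perm_scores = np.empty((n_perm, len(candidates)))
    k = len(seeds)
    for b in range(n_perm):
        draw = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        perm_scores[b] = solver.solve(draw, cfg)[cand_idx]

    exceed = (perm_scores >= observed).sum(axis=0)
    if estimator == "n_over_N":
        p = exceed / n_perm
    elif estimator == "add_one":
        p = (exceed + 1) / (n_perm + 1)
    else:
        raise ValidationError(f"unknown estimator {estimator!r}")
    ci_low = np.percentile(perm_scores, 2.5, axis=0)
    ci_high = np.percentile(perm_scores, 97.5, axis=0)
    return NodeScoreTable(
        scores=dict(zip(candidates, observed.tolist())),
        p_value=dict(zip(candidates, p.tolist())),
        ci_low=dict(zip(candidates, ci_low.tolist())),
        ci_high=dict(zip(candidates, ci_high.tolist())),
        n_permutations=n_perm,
    )


def adjusted_random_walk(
    g: ICKG,
    start_nodes: Iterable[NodeKey | str],
    cfg: RandomWalkConfig | None = None,
) -> dict[NodeKey, float]:
    """Visit frequencies of temperature-softmax random walks.

    From node u, the walk steps to out-neighbor v with probability
    exp(w_uv/T) / sum_x exp(w_ux/T); it terminates early at nodes without
    out-edges. Every node occupancy (including the start at step 0) counts
    as a visit; frequencies are normalized to sum to 1.
    """
    cfg = cfg or RandomWalkConfig()
    starts = _resolve_set(g, start_nodes)
    if not starts:
        raise ValidationError("start_nodes must be non-empty")
    w = collapsed_weights(g)
    successors: dict[NodeKey, tuple[list[NodeKey], np.ndarray]] = {}
    for (u, v), weight in sorted(w.items()):
        successors.setdefault(u, ([], None))[0].append(v)
    for u, (nbrs, _) in successors.items():
        logits = np.array([w[(u, v)] for v in nbrs]) / cfg.temperature
        probs = np.exp(logits - logits.max())
        cum = np.cumsum(probs / probs.sum())
        successors[u] = (nbrs, cum)

    rng = np.random.default_rng(cfg.seed)
    counts: dict[NodeKey, int] = {v: 0 for v in g.nodes}
    for start in starts:
        for _ in range(cfg.n_walks):
            current = start
            counts[current] += 1
            for _ in range(cfg.walk_length):
                if current not in successors:
                    break
                nbrs, cum = successors[current]
                current = nbrs[int(np.searchsorted(cum, rng.random(), side="right"))]
                counts[current] += 1
    total = sum(counts.values())
    return {v: c / total for v, c in counts.items()}


def transition_probabilities(
    g: ICKG, node: NodeKey | str, temperature: float
) -> dict[NodeKey, float]:
    """Closed-form softmax step distribution exp(w/T) out of one node."""
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    u = g.resolve(node)
    w = collapsed_weights(g)
    nbrs = sorted(v for (a, v) in w if a == u)
    if not nbrs:
        return {}
    logits = np.array([w[(u, v)] for v in nbrs]) / temperature
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    return dict(zip(nbrs, probs.tolist()))


# --- explanation -----------------------------------------------------------


@dataclass
class ExplanationResult:
    """Union of chosen shortest paths plus per-target path listings."""

    subgraph: ICKG
    paths: dict[NodeKey, list[NodeKey]]
    unreachable: set = field(default_factory=set)


def _edge_sign(g: ICKG, u: NodeKey, v: NodeKey) -> str:
    """Dominant sign of the (possibly parallel) edges u -> v.

    The direction with the larger supporting weight wins; a tie counts as
    activate.
    """
    data = g.get_edge_data(u, v)
    act = data.get("activate", {}).get("weight", 0)
    inh = data.get("inhibit", {}).get("weight", 0)
    return "inhibit" if inh > act else "activate"


def explain_paths(
    g: ICKG, source: NodeKey | str, targets: Iterable[NodeKey | str]
) -> ExplanationResult:
    """One shortest path (by hop count) from source to each reachable target.

    Ties are broken by preferring the path whose weakest edge (summed
    parallel weight) is largest, then by lexicographic node order, applied
    greedily per hop, which makes the choice deterministic.
    """
    src = g.resolve(source)
    tgt_keys = _resolve_set(g, targets)
    w = collapsed_weights(g)
    successors: dict[NodeKey, list[NodeKey]] = {}
    for u, v in w:
        successors.setdefault(u, []).append(v)

    dist = {src: 0}
    order = [src]
    for u in order:  # BFS; `order` grows during iteration
        for v in sorted(successors.get(u, [])):
            if v not in dist:
                dist[v] = dist[u] + 1
                order.append(v)

    best_path: dict[NodeKey, list[NodeKey]] = {src: [src]}
    bottleneck: dict[NodeKey, float] = {src: float("inf")}
    for v in order[1:]:
        cands = []
        for u in order:
            if dist.get(u, -1) == dist[v] - 1 and (u, v) in w and u in best_path:
                b = min(bottleneck[u], w[(u, v)])
                cands.append((-b, tuple(best_path[u]), u))
        nb, _, u = min(cands)
        bottleneck[v] = -nb
        best_path[v] = best_path[u] + [v]

    subgraph = ICKG()
    paths: dict[NodeKey, list[NodeKey]] = {}
    unreachable = set()
    for t in tgt_keys:
        if t == src or t not in best_path:
            if t != src:
                unreachable.add(t)
            continue
        path = best_path[t]
        paths[t] = path
        for node in path:
            subgraph.add_node(node, **g.nodes[node])
        for a, b in zip(path, path[1:]):
            for key, d in g.get_edge_data(a, b).items():
                if not subgraph.has_edge(a, b, key=key):
                    subgraph.add_edge(a, b, key=key, **d)
    return ExplanationResult(subgraph=subgraph, paths=paths, unreachable=unreachable)


def path_sign(g: ICKG, path: list[NodeKey]) -> str:
    """'activated' if the path crosses an even number of inhibit edges."""
    inhibits = sum(
        1 for a, b in zip(path, path[1:]) if _edge_sign(g, a, b) == "inhibit"
    )
    return "inhibited" if inhibits % 2 else "activated"


@dataclass
class PerturbationResult:
    """Downstream genes predicted for an in-silico perturbation."""

    perturbed_gene: NodeKey
    ranked_genes: list[tuple[str, float, str]]  # (gene, score, activated/inhibited)
    paths: dict[str, list[NodeKey]]
    explanation: ExplanationResult


def in_silico_perturbation(
    g: ICKG, gene: NodeKey | str, cfg: PageRankConfig | None = None
) -> PerturbationResult:
    """Predict and sign the downstream genes of perturbing one gene.

    Scores are personalized PageRank seeded on the perturbed gene alone;
    gene nodes reached by the propagation are ranked by score and labeled
    activated or inhibited by the inhibit-edge parity of their explanation
    path.
    """
    key = g.resolve(gene)
    scores = personalized_pagerank(g, [key], cfg)
    reached = [
        v
        for v in g.gene_nodes()
        if v != key and scores[v] > 1e-15
    ]
    reached.sort(key=lambda v: (-scores[v], v))
    explanation = explain_paths(g, key, reached)
    ranked, paths = [], {}
    for v in reached:
        if v not in explanation.paths:
            continue
        path = explanation.paths[v]
        ranked.append((v[0], scores[v], path_sign(g, path)))
        paths[v[0]] = path
    return PerturbationResult(
        perturbed_gene=key, ranked_genes=ranked, paths=paths, explanation=explanation
    )


@dataclass
class AnnotationResult:
    """Pathway-node ranking for a query gene set."""

    rows: list[tuple[str, float, float, float, float]]  # name, score, p, ci_low, ci_high
    unmapped: list[str]
    table: NodeScoreTable


def annotate_gene_set(
    g: ICKG,
    genes: Iterable[str],
    cfg: PageRankConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    aliases=None,
) -> AnnotationResult:
    """Rank pathway nodes by relevance to a query gene set.

    Query genes are mapped into the graph (through the alias table when
    given); unmapped genes are reported, and mapping none at all is an
    error. Pathway nodes receiving no propagation mass are omitted.
    """
    genes = list(genes)
    mapped, unmapped, attempted = [], [], []
    gene_index = {name.casefold(): (name, t) for name, t in g.nodes if t == "gene"}
    for q in genes:
        tried = [q]
        if aliases is not None:
            canonical = aliases.normalize(q)
            if canonical is not None and canonical != q:
                tried.append(canonical)
        hit = next((gene_index[t.casefold()] for t in tried if t.casefold() in gene_index), None)
        if hit is None:
            unmapped.append(q)
            attempted.append((q, tried))
        else:
            mapped.append(hit)
    if not mapped:
        raise ValidationError(f"no query gene maps into the graph; attempted: {attempted}")
    pathway_nodes = g.pathway_nodes()
    if not pathway_nodes:
        return AnnotationResult(rows=[], unmapped=unmapped, table=NodeScoreTable({}, {}, {}, {}, n_perm))
    table = permutation_test(
        g,
        sorted(set(mapped)),
        candidate_nodes=pathway_nodes,
        n_perm=n_perm,
        seed=seed,
        cfg=cfg,
    )
    rows = [
        (v[0], table.scores[v], table.p_value[v], table.ci_low[v], table.ci_high[v])
        for v in pathway_nodes
        if table.scores[v] > 1e-15
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    table.unmapped = unmapped
    return AnnotationResult(rows=rows, unmapped=unmapped, table=table)


def concept_associated_genes(
    g: ICKG,
    concept: NodeKey | str,
    cfg: PageRankConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    significance: float = 0.05,
    direction: str = "reverse",
) -> set[str]:
    """Gene nodes significantly associated with a concept node.

    Personalized PageRank is seeded on the concept; by default propagation
    runs on the reversed graph, so genes *upstream* of the concept (its
    literature-reported regulators) score highly. A gene is returned when
    its permutation p-value is strictly below ``significance``.
    """
    key = g.resolve(concept)
    gene_nodes = [v for v in g.gene_nodes() if v != key]
    if not gene_nodes:
        return set()
    table = permutation_test(
        g,
        [key],
        candidate_nodes=gene_nodes,
        n_perm=n_perm,
        seed=seed,
        cfg=cfg,
        direction=direction,
    )
    return {
        v[0]
        for v in gene_nodes
        if table.scores[v] > 1e-15 and table.p_value[v] < significance
    }


def concept_similarity_matrix(
    g: ICKG, concepts: list[NodeKey | str], **kwargs
) -> pd.DataFrame:
    """Pairwise Jaccard index of concept-associated gene sets."""
    if len(concepts) < 2:
        raise ValidationError("need at least 2 concepts")
    keys = [g.resolve(c) for c in concepts]
    gene_sets = {k: concept_associated_genes(g, k, **kwargs) for k in keys}
    names = [k[0] for k in keys]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(keys):
        for j, b in enumerate(keys):
            mat.iloc[i, j] = jaccard_index(gene_sets[a], gene_sets[b])
    return mat


def shuffle_graph(g: ICKG, seed: int = 0, n_attempts: int | None = None) -> ICKG:
    """Degree-preserving rewiring control.

    Repeatedly swaps the targets of two randomly chosen edges (keeping
    their direction labels, weights, and provenance attached to the source
    side), rejecting swaps that would create self-loops or duplicate a
    (source, target, direction) edge. In- and out-degree sequences, node
    types, and the weight and sign multisets are all preserved. Attempts
    default to 10x the edge count.
    """
    edges = sorted(g.edges(keys=True, data=True))
    if len(edges) < 2:
        logger.warning("graph has fewer than 2 edges; returning an unshuffled copy")
        return g.copy()
    rng = np.random.default_rng(seed)
    recs = [(u, v, k, d) for u, v, k, d in edges]
    existing = {(u, v, k) for u, v, k, _ in recs}
    attempts = n_attempts if n_attempts is not None else 10 * len(recs)
    for _ in range(attempts):
        i, j = rng.integers(len(recs)), rng.integers(len(recs))
        if i == j:
            continue
        u1, v1, k1, d1 = recs[i]
        u2, v2, k2, d2 = recs[j]
        if u1 == v2 or u2 == v1:
            continue
        new1, new2 = (u1, v2, k1), (u2, v1, k2)
        if new1 in existing or new2 in existing:
            continue
        existing -= {(u1, v1, k1), (u2, v2, k2)}
        existing |= {new1, new2}
        recs[i] = (u1, v2, k1, d1)
        recs[j] = (u2, v1, k2, d2)
    out = ICKG()
    for node, data in g.nodes(data=True):
        out.add_node(node, **data)
    for u, v, k, d in recs:
        out.add_edge(u, v, key=k, **d)
    return out
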