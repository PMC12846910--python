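"""Benchmarking machinery: overlap, directional agreement, and coherence.

Predicted directional relations are compared with reference databases via a
2x2 confusion matrix over the relation pairs present in both sets, with
gene names expanded through an alias table before matching. KEGG interaction
subtypes are first simplified to activate / inhibit. Gene-set overlap uses
the Jaccard index, performance groups are split with a two-component
Gaussian mixture, PPI structure is summarized by density / clustering /
modularity, and annotation coherence by within-cluster sum of squares and
centroid distances in an embedding space (any text -> vector backend; a
deterministic hashing embedder ships for offline use).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .entities import AliasTable
from .types import (
    ConfusionMatrix,
    Direction,
    PRFMetrics,
    RelationTriple,
    ValidationError,
)


def jaccard_index(a: Iterable, b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    return len(a & b) / len(union) if union else 0.0


#: KEGG interaction subtypes folded into activation.
KEGG_ACTIVATION_SUBTYPES = frozenset(
    {"activation", "activation-indirect effect", "activation-indirect"}
)
#: KEGG interaction subtypes folded into inhibition.
KEGG_INHIBITION_SUBTYPES = frozenset(
    {
        "inhibition",
        "inhibition-indirect effect",
        "inhibition-repression",
        "repression-indirect effect",
    }
)


def simplify_kegg_interaction(subtype: str) -> str:
    """Map a KEGG interaction subtype to 'activate', 'inhibit', or 'excluded'."""
    folded = subtype.strip().casefold()
    if folded in KEGG_ACTIVATION_SUBTYPES:
        return "activate"
    if folded in KEGG_INHIBITION_SUBTYPES:
        return "inhibit"
    return "excluded"


def _normalize_endpoint(name: str, aliases: AliasTable | None) -> str:
    if aliases is not None:
        hit = aliases.normalize(name)
        if hit is not None:
            return hit
    return name.upper()


def relation_confusion(
    pred: Iterable[RelationTriple],
    reference: Iterable[tuple[str, str, str | Direction]],
    aliases: AliasTable | None = None,
) -> ConfusionMatrix:
    """Directional agreement over relation pairs present in both sets.

    Endpoints are alias-normalized before matching. When a pair is
    predicted with both signs across abstracts, the sign with more
    supporting triples wins (a tie counts as activate). Cells follow the
    :class:`~ickg.types.ConfusionMatrix` layout (a/d agree, b/c disagree).
    """
    votes: dict[tuple[str, str], dict[Direction, int]] = {}
    for t in pred:
        key = (
            _normalize_endpoint(t.source, aliases),
            _normalize_endpoint(t.target, aliases),
        )
        votes.setdefault(key, {}).setdefault(t.direction, 0)
        votes[key][t.direction] += 1
    predicted: dict[tuple[str, str], Direction] = {}
    for key, counts in votes.items():
        act = counts.get(Direction.ACTIVATE, 0)
        inh = counts.get(Direction.INHIBIT, 0)
        predicted[key] = Direction.ACTIVATE if act >= inh else Direction.INHIBIT

    ref: dict[tuple[str, str], Direction] = {}
    for s, t, direction in reference:
        key = (_normalize_endpoint(s, aliases), _normalize_endpoint(t, aliases))
        ref.setdefault(key, Direction(direction))

    a = b = c = d = 0
    for key, p_dir in predicted.items():
        if key not in ref:
            continue
        r_dir = ref[key]
        if p_dir is Direction.ACTIVATE:
            a, b = (a + 1, b) if r_dir is Direction.ACTIVATE else (a, b + 1)
        else:
            c, d = (c + 1, d) if r_dir is Direction.ACTIVATE else (c, d + 1)
    return ConfusionMatrix(a=a, b=b, c=c, d=d)


def prf_from_confusion(m: ConfusionMatrix) -> PRFMetrics:
    """P = A/(A+B), R = A/(A+C), F1 harmonic; zero denominators give 0."""
    return PRFMetrics.from_counts(tp=m.a, fp=m.b, fn=m.c)


def degs_to_reference(
    genes: Iterable[str],
    log2fc: Iterable[float],
    cell_type: str,
    lfc_threshold: float = 0.0,
) -> list[tuple[str, str, str]]:
    """Turn a DEG table into gene -> cell-type reference relations.

    Positive log2 fold change maps to activate, negative to inhibit; genes
    with |log2FC| <= threshold are dropped.
    """
    out = []
    for gene, lfc in zip(genes, log2fc):
        if abs(lfc) <= lfc_threshold:
            continue
        direction = "activate" if lfc > 0 else "inhibit"
        out.append((gene, cell_type, direction))
    return out


def read_reference_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Reference relation TSV: columns source, target, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"source", "target", "direction"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: reference TSV missing columns {missing}")
    return [
        (r.source, r.target, Direction(r.direction).value) for r in df.itertuples()
    ]


def gmm_dichotomize(values: Iterable[float], seed: int = 0) -> list[str]:
    """Split values into 'High'/'Low' with a 2-component Gaussian mixture.

    The component with the larger fitted mean is labeled High. Requires at
    least 4 values with at least 2 distinct ones; the labeling does not
    depend on input order.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValidationError("need at least 4 values to fit a 2-component mixture")
    if np.unique(arr).size < 2:
        raise ValidationError("all values identical; mixture fit is degenerate")
    order = np.argsort(arr, kind="stable")
    gmm = GaussianMixture(n_components=2, random_state=seed)
    assignments = gmm.fit_predict(arr[order].reshape(-1, 1))
    high = int(np.argmax(gmm.means_.ravel()))
    labels = np.empty(arr.size, dtype=object)
    labels[order] = np.where(assignments == high, "High", "Low")
    return labels.tolist()


def ppi_network_metrics(
    edges: Iterable[tuple[str, str, float]],
) -> tuple[float, float, float]:
    """(density, average clustering coefficient, greedy modularity).

    Edges are undirected weighted pairs; an empty edge list returns zeros.
    """
    g = nx.Graph()
    for a, b, score in edges:
        g.add_edge(a, b, weight=float(score))
    if g.number_of_edges() == 0:
        return (0.0, 0.0, 0.0)
    density = nx.density(g)
    clustering = nx.average_clustering(g)
    communities = nx.community.greedy_modularity_communities(g)
    modularity = nx.community.modularity(g, communities)
    return (density, clustering, modularity)


def load_ppi_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"])
    return [(str(r.a), str(r.b), float(r.score)) for r in df.itertuples()]


# --- embedding coherence ---------------------------------------------------


@dataclass
class EmbeddingSet:
    """Labeled points in a shared embedding space."""

    labels: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.labels) != self.vectors.shape[0]:
            raise ValidationError("labels and vectors must have equal length")
        if self.vectors.size == 0:
            raise ValidationError("embedding set must be non-empty")

    @property
    def centroid(self) -> np.ndarray:
        return self.vectors.mean(axis=0)


@runtime_checkable
class EmbeddingBackend(Protocol):
    def embed(self, texts: list[str]) -> np.ndarray: ...


class HashingEmbedder:
    """Deterministic bag-of-words hashing embedder for offline tests.

    Each token is hashed (BLAKE2) to a fixed pseudo-random unit vector;
    a text's embedding is the normalized token-vector sum. Not a semantic
    model — it only provides a stable, reproducible vector space.
    """

    def __init__(self, dim: int = 64):
        self.dim = dim

    def _token_vector(self, token: str) -> np.ndarray:
        digest = hashlib.blake2b(token.lower().encode(), digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def embed(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            tokens = text.split()
            if not tokens:
                continue
            v = np.sum([self._token_vector(t) for t in tokens], axis=0)
            norm = np.linalg.norm(v)
            out[i] = v / norm if norm else v
        return out


def embed_texts(labels: list[str], backend: EmbeddingBackend) -> EmbeddingSet:
    return EmbeddingSet(labels=list(labels), vectors=backend.embed(list(labels)))


def wcss(points: EmbeddingSet) -> float:
    """Within-cluster sum of squares around the set centroid."""
    diffs = points.vectors - points.centroid
    return float((diffs**2).sum())


def centroid_distance(a: EmbeddingSet, b: EmbeddingSet) -> float:
    """Euclidean distance between the two set centroids."""
    if a.vectors.shape[1] != b.vectors.shape[1]:
        raise ValidationError(
            f"dimension mismatch: {a.vectors.shape[1]} vs {b.vectors.shape[1]}"
        )
    return float(np.linalg.norm(a.centroid - b.centroid))


def pca_project(points: EmbeddingSet, n_components: int = 2) -> np.ndarray:
    """2-D principal-component projection for plotting only."""
    from sklearn.decomposition import PCA

    n = min(n_components, *points.vectors.shape)
    return PCA(n_components=n).fit_transform(points.vectors)


def compare_dispersion(a: EmbeddingSet, b: EmbeddingSet) -> dict:
    """Standard variance/location comparisons between two embedding sets.

    Levene's test and the Mann-Whitney U test are applied to the
    point-to-centroid distance distributions of the two sets; WCSS and
    centroid distance are reported alongside.
    """
    da = np.linalg.norm(a.vectors - a.centroid, axis=1)
    db = np.linalg.norm(b.vectors - b.centroid, axis=1)
    levene = stats.levene(da, db)
    mwu = stats.mannwhitneyu(da, db, alternative="two-sided")
    return {
        "wcss_a": wcss(a),
        "wcss_b": wcss(b),
        "centroid_distance": centroid_distance(a, b),
        "levene_stat": float(levene.statistic),
        "levene_p": float(levene.pvalue),
        "mannwhitney_u": float(mwu.statistic),
        "mannwhitney_p": float(mwu.pvalue),
    }
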