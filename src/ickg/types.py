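"""Core domain types shared across the ICKG pipeline.

An immune-cell knowledge graph (ICKG) is built from literature abstracts:
entity mentions are tagged, ordered entity pairs are classified into
activate / inhibit / no-association relations, and the surviving directed
relations are aggregated into a typed, signed, weighted graph whose edge
weights count the distinct abstracts supporting each relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class NodeType(str, Enum):
    """Type of a knowledge-graph node."""

    GENE = "gene"
    DISEASE = "disease"
    CELL_TYPE = "cell_type"
    PATHWAY = "pathway"
    OTHER = "other"


class Direction(str, Enum):
    """Sign of a directed relation. No-association is never materialized."""

    ACTIVATE = "activate"
    INHIBIT = "inhibit"


#: Allowed values for :attr:`AbstractRecord.cell_type_tag`.
CELL_TYPE_TAGS = frozenset({"T", "B", "NK", "macrophage", "other"})


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the location."""


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract (PMID or synthetic identifier)."""

    abstract_id: str
    year: int
    title: str
    text: str
    cell_type_tag: str = "other"

    def __post_init__(self) -> None:
        if not self.abstract_id:
            raise ValidationError("abstract_id must be non-empty")
        if not self.text:
            raise ValidationError(
                f"abstract {self.abstract_id!r}: text must be non-empty"
            )
        if self.cell_type_tag not in CELL_TYPE_TAGS:
            raise ValidationError(
                f"abstract {self.abstract_id!r}: unknown cell_type_tag "
                f"{self.cell_type_tag!r} (allowed: {sorted(CELL_TYPE_TAGS)})"
            )


@dataclass(frozen=True)
class EntityMention:
    """A typed entity mention as a half-open character span of the text."""

    surface: str
    start: int
    end: int
    entity_type: NodeType
    normalized_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span [{self.start}, {self.end}) for {self.surface!r}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RelationTriple:
    """A directional activate/inhibit relation supported by one abstract."""

    source: str
    target: str
    direction: Direction
    abstract_id: str
    source_type: NodeType = NodeType.GENE
    target_type: NodeType = NodeType.GENE

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValidationError("relation endpoints must be non-empty")
        if (self.source, self.source_type) == (self.target, self.target_type):
            raise ValidationError(f"self-loop relation on {self.source!r}")
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))
        if not isinstance(self.source_type, NodeType):
            object.__setattr__(self, "source_type", NodeType(self.source_type))
        if not isinstance(self.target_type, NodeType):
            object.__setattr__(self, "target_type", NodeType(self.target_type))


@dataclass(frozen=True)
class PRFMetrics:
    """Precision / recall / F1, with F1 = 2PR/(P+R) and 0 when P+R = 0."""

    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRFMetrics":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return cls(p, r, f1)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 directional agreement table over overlapping relation pairs.

    a: predicted activate, reference activate
    b: predicted activate, reference inhibit
    c: predicted inhibit, reference activate
    d: predicted inhibit, reference inhibit
    """

    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("confusion-matrix cells must be non-negative")

    @property
    def overlap(self) -> int:
        """E: number of relation pairs present in both prediction and reference."""
        return self.a + self.b + self.c + self.d


@dataclass
class PageRankConfig:
    """Personalized PageRank parameters (damping factor defaults to 0.85)."""

    alpha: float = 0.85
    tolerance: float = 1e-10
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValidationError("tolerance must be > 0 and max_iterations >= 1")


@dataclass
class RandomWalkConfig:
    """Temperature-softmax random-walk parameters (1000 walks of 20 steps)."""

    temperature: float = 1.0
    n_walks: int = 1000
    walk_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")
        if self.n_walks < 1 or self.walk_length < 1:
            raise ValidationError("n_walks and walk_length must be >= 1")


@dataclass
class NodeScoreTable:
    """Per-node scores from a reasoning run with permutation significance.

    ``p_value[v]`` is the fraction of permutations whose score for ``v`` met
    or exceeded the observed score (n/N); ``ci_low``/``ci_high`` are the
    2.5th and 97.5th percentiles of the permutation distribution.
    """

    scores: dict
    p_value: dict
    ci_low: dict
    ci_high: dict
    n_permutations: int
    unmapped: list = field(default_factory=list)
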