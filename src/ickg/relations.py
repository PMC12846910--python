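"""Directional relation extraction over ordered entity pairs.

For every abstract, all ordered pairs of its distinct entities are
enumerated; for each pair a zero-shot prompt is rendered asking whether the
first term activates, inhibits, or has no association with the second term
*based only on the abstract*. Backends are pluggable: the packaged
:class:`VerbLookupBackend` is a deterministic trigger-verb matcher used for
synthetic corpora; a real LLM endpoint can be wired through
:class:`HTTPRelationBackend`. Only activate/inhibit answers are materialized
as triples, each carrying the supporting abstract id.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

from .types import (
    AbstractRecord,
    Direction,
    EntityMention,
    NodeType,
    RelationTriple,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Trigger verbs understood by the deterministic mock backend, partitioned by
#: sign. The synthetic corpus draws only from these, so mock extraction is an
#: exact lookup.
ACTIVATE_VERBS = (
    "activates",
    "stimulates",
    "induces",
    "upregulates",
    "promotes",
    "enhances",
)
INHIBIT_VERBS = (
    "inhibits",
    "suppresses",
    "represses",
    "downregulates",
    "blocks",
    "impairs",
)

PROMPT_TEMPLATE_ID = "ickg-relation-v1"

#: Zero-shot relation prompt. Directionality is explicit: the relationship is
#: inferred from the first term to the second only, and anything ambiguous or
#: biologically irrelevant must be answered "no association".
PROMPT_TEMPLATE = """You are given a biomedical abstract and two terms.
Decide, based only on the abstract, whether the FIRST term activates,
inhibits, or has no association with the SECOND term. Relationships must be
inferred only from the first term to the second, never the reverse. If the
relationship is ambiguous or biologically irrelevant, answer "no association".
Answer with exactly one of: Activate, Inhibit, no association.

First term: {source}
Second term: {target}

Abstract:
{abstract}
"""


@dataclass(frozen=True)
class RelationPrompt:
    template_id: str
    rendered_text: str
    pair: tuple[str, str]
    abstract_id: str


def enumerate_pairs(entities: Iterable[str]) -> list[tuple[str, str]]:
    """All n(n-1) ordered pairs of distinct entities, lexicographically sorted."""
    names = sorted(set(entities))
    return [(a, b) for a in names for b in names if a != b]


def build_relation_prompt(
    record: AbstractRecord,
    pair: tuple[str, str],
    known_entities: Iterable[str] | None = None,
) -> RelationPrompt:
    """Render the packaged prompt template for one ordered pair.

    Both entities must occur in the abstract — either in ``known_entities``
    (the extracted mention names) or, failing that, verbatim in the text.
    """
    if known_entities is not None:
        known = {e.casefold() for e in known_entities}
        missing = [e for e in pair if e.casefold() not in known]
    else:
        folded = record.text.casefold()
        missing = [e for e in pair if e.casefold() not in folded]
    if missing:
        raise ValidationError(
            f"abstract {record.abstract_id!r}: entities {missing} not present"
        )
    rendered = PROMPT_TEMPLATE.format(
        source=pair[0], target=pair[1], abstract=record.text
    )
    return RelationPrompt(
        template_id=PROMPT_TEMPLATE_ID,
        rendered_text=rendered,
        pair=(pair[0], pair[1]),
        abstract_id=record.abstract_id,
    )


def parse_relation_response(raw: str) -> Direction | None:
    """Map a backend response to activate / inhibit / None (no association).

    The *first* directional keyword in the response wins; "no association"
    and anything unrecognized map to None, the safe default.
    """
    lowered = raw.casefold()
    hits = []
    for token, value in (
        ("no association", None),
        ("activat", Direction.ACTIVATE),
        ("inhibit", Direction.INHIBIT),
    ):
        idx = lowered.find(token)
        if idx >= 0:
            hits.append((idx, value))
    if not hits:
        return None
    return min(hits, key=lambda h: h[0])[1]


@runtime_checkable
class RelationBackend(Protocol):
    def classify(self, prompt: RelationPrompt) -> str: ...


class VerbLookupBackend:
    """Deterministic mock: answer from 'SOURCE <trigger-verb> TARGET' patterns.

    Scans each sentence of the abstract for the source term, then a trigger
    verb, then the target term, in that order. Matching is case-insensitive
    on whole-word occurrences. Anything else is "no association".
    """

    def __init__(
        self,
        activate_verbs: Iterable[str] = ACTIVATE_VERBS,
        inhibit_verbs: Iterable[str] = INHIBIT_VERBS,
    ):
        self.verb_sign = {v.casefold(): Direction.ACTIVATE for v in activate_verbs}
        self.verb_sign.update({v.casefold(): Direction.INHIBIT for v in inhibit_verbs})

    @staticmethod
    def _find(term: str, sentence: str) -> int:
        m = re.search(rf"(?<!\w){re.escape(term)}(?!\w)", sentence, re.IGNORECASE)
        return m.start() if m else -1

    def classify(self, prompt: RelationPrompt) -> str:
        source, target = prompt.pair
        abstract = prompt.rendered_text.split("Abstract:\n", 1)[-1]
        for sentence in re.split(r"(?<=[.!?])\s+", abstract):
            i = self._find(source, sentence)
            j = self._find(target, sentence)
            if i < 0 or j < 0 or not i < j:
                continue
            for verb, sign in self.verb_sign.items():
                k = self._find(verb, sentence)
                if i < k < j:
                    return "Activate" if sign is Direction.ACTIVATE else "Inhibit"
        return "no association"


class HTTPRelationBackend:
    """Minimal JSON-over-HTTP contract for a live LLM endpoint.

    Posts ``{"model": ..., "prompt": ...}`` and expects a JSON body with a
    ``"text"`` field. Never exercised by tests; provided so a local LLaMA
    server can stand in for the mock without code changes.
    """

    def __init__(self, endpoint: str, model: str, timeout: float = 60.0):
        self.endpoint = endpoint
        self.model = model
        self.timeout = timeout

    def classify(self, prompt: RelationPrompt) -> str:
        import urllib.request

        body = json.dumps({"model": self.model, "prompt": prompt.rendered_text})
        req = urllib.request.Request(
            self.endpoint,
            data=body.encode(),
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read())["text"]


def mention_names(
    mentions: Iterable[EntityMention],
) -> dict[str, NodeType]:
    """Deduplicated entity name -> type map from a mention list.

    Uses the normalized id when present, else the surface form; gene names
    are uppercased. On a name/type conflict the first mention wins.
    """
    out: dict[str, NodeType] = {}
    for m in mentions:
        name = m.normalized_id or m.surface
        if m.entity_type is NodeType.GENE:
            name = name.upper()
        out.setdefault(name, m.entity_type)
    return out


def extract_relations(
    record: AbstractRecord,
    entities: list[EntityMention],
    backend: RelationBackend,
) -> list[RelationTriple]:
    """One backend call per ordered entity pair; keep activate/inhibit only.

    A backend failure on a pair skips that pair (logged) and the run
    continues; self-loops are never emitted.
    """
    names = mention_names(entities)
    triples = []
    for pair in enumerate_pairs(names):
        prompt = build_relation_prompt(record, pair, known_entities=names)
        try:
            raw = backend.classify(prompt)
        except Exception as exc:
            logger.warning(
                "relation backend failed on %s pair %s: %s",
                record.abstract_id,
                pair,
                exc,
            )
            continue
        direction = parse_relation_response(raw)
        if direction is None:
            continue
        triples.append(
            RelationTriple(
                source=pair[0],
                target=pair[1],
                direction=direction,
                abstract_id=record.abstract_id,
                source_type=names[pair[0]],
                target_type=names[pair[1]],
            )
        )
    return triples


def write_triples_tsv(triples: Iterable[RelationTriple], path) -> None:
    lines = ["source\tsource_type\ttarget\ttarget_type\tdirection\tabstract_id"]
    for t in triples:
        lines.append(
            f"{t.source}\t{t.source_type.value}\t{t.target}\t{t.target_type.value}"
            f"\t{t.direction.value}\t{t.abstract_id}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_triples_tsv(path) -> list[RelationTriple]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "direction", "abstract_id"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: triples TSV missing columns {required - set(df.columns)}")
    return [
        RelationTriple(
            source=r.source,
            target=r.target,
            direction=Direction(r.direction),
            abstract_id=r.abstract_id,
            source_type=NodeType(getattr(r, "source_type", "gene")),
            target_type=NodeType(getattr(r, "target_type", "gene")),
        )
        for r in df.itertuples()
    ]
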