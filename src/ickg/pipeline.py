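"""End-to-end graph construction: tag, mine, extract relations, assemble."""

from __future__ import annotations

import re
from typing import Iterable

from .corpus import AbstractRecord
from .entities import AliasTable, EntityMention, Tagger, merge_overlapping_mentions, tag_entities
from .graph import ICKG, assemble_graph
from .pathways import ChunkerBackend, PhraseReviewBackend, mine_pathway_phrases
from .relations import RelationBackend, extract_relations, mention_names
from .types import NodeType, RelationTriple


def build_graph_from_corpus(
    records: Iterable[AbstractRecord],
    tagger: Tagger,
    relation_backend: RelationBackend,
    aliases: AliasTable | None = None,
    vocabulary: Iterable[str] | None = None,
    similarity_threshold: float = 0.85,
    chunker: ChunkerBackend | None = None,
    reviewer: PhraseReviewBackend | None = None,
) -> tuple[ICKG, list[RelationTriple], dict]:
    """Run the full construction pipeline over a corpus.

    Entities come from the tagger; when a controlled vocabulary is supplied,
    mined concept phrases found verbatim in the text are added as pathway
    mentions. Returns the assembled graph, the retained triples, and a
    per-stage accounting log (abstracts, mentions, pairs queried, triples
    kept) for auditability.
    """
    triples: list[RelationTriple] = []
    log = {
        "abstracts": 0,
        "mentions": 0,
        "mined_phrases": 0,
        "pairs_queried": 0,
        "triples_kept": 0,
    }
    vocab = list(vocabulary) if vocabulary is not None else None
    for record in records:
        mentions = tag_entities(record, tagger)
        if vocab:
            phrases = mine_pathway_phrases(
                record.text,
                vocab,
                similarity_threshold=similarity_threshold,
                pos_backend=chunker,
                reviewer=reviewer,
            )
            extra = _phrase_mentions(record.text, [p.phrase for p in phrases])
            log["mined_phrases"] += len(extra)
            mentions = merge_overlapping_mentions(list(mentions) + extra)
        n_entities = len(mention_names(mentions))
        log["abstracts"] += 1
        log["mentions"] += len(mentions)
        log["pairs_queried"] += n_entities * (n_entities - 1)
        kept = extract_relations(record, mentions, relation_backend)
        log["triples_kept"] += len(kept)
        triples.extend(kept)
    graph = assemble_graph(triples, aliases)
    return graph, triples, log


def _phrase_mentions(text: str, phrases: Iterable[str]) -> list[EntityMention]:
    out = []
    for phrase in phrases:
        m = re.search(re.escape(phrase), text, re.IGNORECASE)
        if m:
            out.append(
                EntityMention(
                    surface=text[m.start() : m.end()],
                    start=m.start(),
                    end=m.end(),
                    entity_type=NodeType.PATHWAY,
                    normalized_id=phrase,
                )
            )
    return out
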