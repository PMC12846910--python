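"""Entity tagging, gene-symbol normalization, and NER evaluation.

Taggers are pluggable: anything with a ``tag(text) -> list[EntityMention]``
method satisfies the contract. The packaged :class:`GazetteerTagger` is a
deterministic dictionary matcher (case-insensitive, longest match wins) used
for synthetic corpora and tests; neural taggers can be wrapped behind the
same contract but no trained model ships with the package.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import pandas as pd

from .types import (
    AbstractRecord,
    EntityMention,
    NodeType,
    ParseError,
    PRFMetrics,
    ValidationError,
)


class AliasTable:
    """Case-insensitive alias -> canonical gene symbol lookup.

    Canonical symbols always map to themselves; unknown strings return None.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, canonical in (mapping or {}).items():
            self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        canonical = canonical.upper()
        self._map[alias.casefold()] = canonical
        self._map.setdefault(canonical.casefold(), canonical)

    def normalize(self, surface: str) -> str | None:
        return self._map.get(surface.casefold())

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        """Load a two-column TSV of (alias, canonical); header optional."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ParseError(f"{path}: alias table needs 2 columns (alias, canonical)")
        table = cls()
        for alias, canonical in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if str(alias).casefold() == "alias" and str(canonical).casefold() == "canonical":
                continue  # header row
            table.add(str(alias), str(canonical))
        return table


def normalize_gene(surface: str, aliases: AliasTable) -> str | None:
    """Canonical symbol for ``surface`` if any alias matches, else None."""
    return aliases.normalize(surface)


@runtime_checkable
class Tagger(Protocol):
    def tag(self, text: str) -> list[EntityMention]: ...


class GazetteerTagger:
    """Dictionary tagger: case-insensitive whole-word matches of known terms."""

    def __init__(self, vocabulary: dict[str, NodeType | str]):
        self.vocabulary = {term: NodeType(t) for term, t in vocabulary.items()}
        # Longest terms first so overlapping alternatives prefer the long span.
        terms = sorted(self.vocabulary, key=len, reverse=True)
        self._patterns = [
            (term, re.compile(rf"(?<!\w){re.escape(term)}(?!\w)", re.IGNORECASE))
            for term in terms
        ]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GazetteerTagger":
        """Load a two-column TSV of (surface, entity_type)."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ParseError(f"{path}: gazetteer needs 2 columns (surface, entity_type)")
        vocab = {}
        for surface, etype in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if str(surface).casefold() == "surface":
                continue
            try:
                vocab[str(surface)] = NodeType(str(etype))
            except ValueError:
                raise ParseError(f"{path}: unknown entity_type {etype!r}") from None
        return cls(vocab)

    def tag(self, text: str) -> list[EntityMention]:
        mentions = []
        for term, pattern in self._patterns:
            for m in pattern.finditer(text):
                mentions.append(
                    EntityMention(
                        surface=text[m.start() : m.end()],
                        start=m.start(),
                        end=m.end(),
                        entity_type=self.vocabulary[term],
                        normalized_id=term,
                    )
                )
        return merge_overlapping_mentions(mentions)


def merge_overlapping_mentions(mentions: Iterable[EntityMention]) -> list[EntityMention]:
    """Resolve overlapping mentions of the same type to the longest span.

    Different-type overlaps are retained (a string can be both a gene and
    part of a longer pathway phrase). Output is sorted by start offset.
    """
    kept: list[EntityMention] = []
    by_len = sorted(mentions, key=lambda m: (-(m.end - m.start), m.start, m.entity_type))
    for m in by_len:
        clash = any(
            k.entity_type == m.entity_type and k.start < m.end and m.start < k.end
            for k in kept
        )
        if not clash:
            kept.append(m)
    return sorted(kept, key=lambda m: (m.start, m.end, m.entity_type.value))


def tag_entities(record: AbstractRecord, backend: Tagger) -> list[EntityMention]:
    """Tag a record's text, sorting mentions and merging same-type overlaps."""
    try:
        mentions = backend.tag(record.text)
    except Exception as exc:
        raise RuntimeError(f"tagger failed on abstract {record.abstract_id!r}: {exc}") from exc
    for m in mentions:
        if m.end > len(record.text) or record.text[m.start : m.end] != m.surface:
            raise ValidationError(
                f"abstract {record.abstract_id!r}: mention {m.surface!r} does not "
                f"match text span [{m.start}, {m.end})"
            )
    return merge_overlapping_mentions(mentions)


_TOKEN_RE = re.compile(r"\w+")


def evaluate_ner(
    predicted: Iterable[EntityMention],
    gold: Iterable[EntityMention],
    mode: str = "entity",
    text: str | None = None,
) -> PRFMetrics:
    """Precision/recall/F1 of predicted mentions against gold mentions.

    ``mode="entity"`` (default) scores exact-span, exact-type matches.
    ``mode="token"`` scores per word token (requires ``text``): each token
    is labeled by the mention covering it, and (token span, type) pairs are
    compared as sets — partial span overlaps then earn partial credit.
    """
    if mode == "entity":
        pset = {(m.start, m.end, m.entity_type) for m in predicted}
        gset = {(m.start, m.end, m.entity_type) for m in gold}
    elif mode == "token":
        if text is None:
            raise ValidationError("token-level evaluation requires the text")
        tokens = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]

        def token_labels(mentions):
            out = set()
            for m in mentions:
                for ts, te in tokens:
                    if ts < m.end and m.start < te:
                        out.add((ts, te, m.entity_type))
            return out

        pset, gset = token_labels(predicted), token_labels(gold)
    else:
        raise ValidationError(f"unknown evaluation mode {mode!r}")
    tp = len(pset & gset)
    return PRFMetrics.from_counts(tp, len(pset) - tp, len(gset) - tp)
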