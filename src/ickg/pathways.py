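"""Mining candidate pathway / biomedical-concept phrases from sentences.

Candidate phrases are multi-token noun phrases with stop words stripped
from their edges. They are then screened for biological relevance by three
OR-combined lexical filters: approximate (Levenshtein) match to a
controlled vocabulary, a biomedical suffix on the final token, or a
biomedical substring anywhere in the phrase. An optional reviewer backend
(an LLM in production, a deterministic mock here) can prune the survivors
but can never add phrases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import edlib

from .types import ValidationError

logger = logging.getLogger(__name__)

#: Frozen English stop-word list (kept in-repo for reproducibility).
STOP_WORDS = frozenset(
    """a about above after again against all also am an and any are as at be
    because been before being below between both but by can could did do does
    doing down during each few for from further had has have having he her
    here hers herself him himself his how i if in into is it its itself just
    me more most my myself no nor not now of off on once only or other our
    ours ourselves out over own same she should so some such than that the
    their theirs them themselves then there these they this those through to
    too under until up very was we were what when where which while who whom
    why will with you your yours yourself yourselves""".split()
)

#: Biomedical suffixes; "in" is guarded (see :func:`filter_biomedical_phrases`).
BIOMEDICAL_SUFFIXES = ("ase", "in", "ion", "itis", "osis", "oma", "icity", "pathy")

#: Biomedical substrings checked anywhere in the phrase.
BIOMEDICAL_SUBSTRINGS = (
    "cell",
    "gene",
    "protein",
    "receptor",
    "antibody",
    "immune",
    "tumor",
    "cancer",
    "virus",
    "bacteria",
)


@dataclass(frozen=True)
class CandidatePhrase:
    """A whitespace-normalized, lowercased candidate concept phrase."""

    phrase: str
    source_sentence: str
    passed_filters: frozenset[str] = frozenset()

    @property
    def tokens(self) -> list[str]:
        return self.phrase.split()


@runtime_checkable
class ChunkerBackend(Protocol):
    """Noun-phrase chunking contract: sentence -> list of phrase strings."""

    def chunk(self, sentence: str) -> list[str]: ...


# Closed-class words and common verbs that terminate a noun-phrase run in the
# rule-based chunker. Verb lemmas are inflected (-s, -ed, -ing) automatically.
_VERB_LEMMAS = """activate inhibit suppress enhance induce promote stimulate
    repress block upregulate downregulate regulate mediate increase decrease
    reduce impair trigger modulate attenuate augment abolish drive show
    demonstrate reveal suggest indicate require improve express target remain
    play involve observe report identify find associate correlate lead result
    contribute depend affect alter cause prevent""".split()


def _inflect(lemma: str) -> set[str]:
    forms = {lemma, lemma + "s"}
    if lemma.endswith("e"):
        forms |= {lemma + "d", lemma[:-1] + "ing"}
    else:
        forms |= {lemma + "ed", lemma + "ing", lemma + "es"}
    return forms


_BREAK_WORDS = frozenset(
    w for lemma in _VERB_LEMMAS for w in _inflect(lemma)
) | STOP_WORDS


class RuleChunker:
    """Deterministic noun-phrase chunker based on closed-class word breaks.

    Tokenizes on word characters (hyphens kept inside tokens) and emits
    maximal runs of tokens uninterrupted by stop words, common verbs, or
    punctuation. It has no part-of-speech model, so it over-generates on
    adjectives and verbs outside its lexicon; the downstream lexical filters
    are responsible for discarding non-biomedical runs.
    """

    token_re = re.compile(r"[A-Za-z0-9][A-Za-z0-9-]*")

    def chunk(self, sentence: str) -> list[str]:
        chunks: list[list[str]] = []
        current: list[str] = []
        pos = 0
        for m in self.token_re.finditer(sentence):
            gap = sentence[pos : m.start()]
            if current and any(ch in gap for ch in ".,;:!?()[]"):
                chunks.append(current)
                current = []
            token = m.group()
            if token.lower() in _BREAK_WORDS:
                if current:
                    chunks.append(current)
                    current = []
            else:
                current.append(token)
            pos = m.end()
        if current:
            chunks.append(current)
        return [" ".join(c) for c in chunks]


def _strip_edges(tokens: list[str]) -> list[str]:
    while tokens and tokens[0].lower() in STOP_WORDS:
        tokens = tokens[1:]
    while tokens and tokens[-1].lower() in STOP_WORDS:
        tokens = tokens[:-1]
    return tokens


def extract_candidate_phrases(
    sentence: str, pos_backend: ChunkerBackend | None = None
) -> list[CandidatePhrase]:
    """Multi-token noun phrases of a sentence, in order of appearance.

    Stop words are stripped from phrase edges; phrases reduced to a single
    token are dropped.
    """
    backend = pos_backend if pos_backend is not None else RuleChunker()
    out = []
    for chunk in backend.chunk(sentence):
        tokens = _strip_edges(chunk.split())
        if len(tokens) >= 2:
            out.append(
                CandidatePhrase(
                    phrase=" ".join(t.lower() for t in tokens),
                    source_sentence=sentence,
                )
            )
    return out


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - edit_distance / max(len); 1.0 for two empty strings."""
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _suffix_hit(phrase: str) -> str | None:
    head = phrase.split()[-1]
    for suffix in BIOMEDICAL_SUFFIXES:
        if suffix == "in":
            # Unguarded, "in" floods on prepositions and short words; require
            # the head token itself to be a plausible protein-like noun.
            if len(head) >= 4 and head.endswith("in"):
                return "suffix:in"
        elif head.endswith(suffix):
            return f"suffix:{suffix}"
    return None


def filter_biomedical_phrases(
    phrases: Iterable[CandidatePhrase],
    vocabulary: Iterable[str],
    similarity_threshold: float = 0.85,
) -> list[CandidatePhrase]:
    """Keep phrases passing any of the vocabulary / suffix / substring filters.

    Each kept phrase records which filters fired in ``passed_filters``
    (``vocabulary``, ``suffix:<sfx>``, ``substring:<sub>``). Raising the
    threshold never adds phrases, and the filter is idempotent.
    """
    vocab = [v.lower() for v in vocabulary]
    if not vocab:
        raise ValidationError("vocabulary must be non-empty")
    if not 0.0 <= similarity_threshold <= 1.0:
        raise ValidationError("similarity_threshold must be in [0, 1]")
    kept = []
    for cp in phrases:
        fired = set()
        if any(
            levenshtein_similarity(cp.phrase, term) >= similarity_threshold
            for term in vocab
        ):
            fired.add("vocabulary")
        hit = _suffix_hit(cp.phrase)
        if hit:
            fired.add(hit)
        for sub in BIOMEDICAL_SUBSTRINGS:
            if sub in cp.phrase:
                fired.add(f"substring:{sub}")
        if fired:
            kept.append(
                CandidatePhrase(
                    phrase=cp.phrase,
                    source_sentence=cp.source_sentence,
                    passed_filters=frozenset(cp.passed_filters | fired),
                )
            )
    return kept


@runtime_checkable
class PhraseReviewBackend(Protocol):
    """Term-review contract: list of terms -> retained sublist."""

    def review(self, terms: list[str]) -> list[str]: ...


class IdentityReviewer:
    def review(self, terms: list[str]) -> list[str]:
        return list(terms)


class DropListReviewer:
    """Mock reviewer that drops a configured set of uninformative terms."""

    def __init__(self, drop: Iterable[str]):
        self.drop = {t.lower() for t in drop}

    def review(self, terms: list[str]) -> list[str]:
        return [t for t in terms if t.lower() not in self.drop]


def refine_phrases(
    phrases: list[CandidatePhrase], llm_backend: PhraseReviewBackend
) -> list[CandidatePhrase]:
    """Apply a reviewer backend; output is always a subset of the input.

    Terms the backend returns that were not in the input are discarded with
    a warning (anti-hallucination contract); input order is preserved.
    """
    terms = [cp.phrase for cp in phrases]
    retained = llm_backend.review(terms)
    known = set(terms)
    hallucinated = [t for t in retained if t not in known]
    if hallucinated:
        logger.warning(
            "reviewer returned %d term(s) not in the input; discarding: %s",
            len(hallucinated),
            hallucinated,
        )
    keep = set(retained) & known
    return [cp for cp in phrases if cp.phrase in keep]


def load_vocabulary(path: str | Path) -> list[str]:
    """One controlled-vocabulary term per line, UTF-8, blanks skipped."""
    return [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    """Lightweight sentence splitter on terminal punctuation."""
    return [s for s in _SENTENCE_RE.split(text) if s]


def mine_pathway_phrases(
    text: str,
    vocabulary: Iterable[str],
    similarity_threshold: float = 0.85,
    pos_backend: ChunkerBackend | None = None,
    reviewer: PhraseReviewBackend | None = None,
) -> list[CandidatePhrase]:
    """Full mining pipeline for one abstract: chunk, filter, optionally review."""
    candidates: list[CandidatePhrase] = []
    for sentence in split_sentences(text):
        candidates.extend(extract_candidate_phrases(sentence, pos_backend))
    kept = filter_biomedical_phrases(candidates, vocabulary, similarity_threshold)
    if reviewer is not None:
        kept = refine_phrases(kept, reviewer)
    return kept
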