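"""Noun-phrase extraction, normalization, and per-phrase corpus statistics.

Assessment scales and therapies appear in abstracts as noun phrases, so the
unit of term extraction is the maximal NP produced by shallow chunking over a
coarse POS stream: an optional determiner followed by attributive modifiers
(adjectives, participles, nouns) ending in a noun. Each phrase is then
normalized to a canonical form (lowercase, determiners and edge punctuation
stripped) and counted per document:

* document frequency ``df`` — the number of distinct records containing the
  phrase at least once (title or abstract), the "number of articles" count;
* TF-IDF — a corpus-level importance score,
  ``score(p) = Σ_d tf(p, d) · ln(N / df(p))``
  where ``tf`` is the raw occurrence count of the phrase in document ``d`` and
  ``N`` the corpus size. A phrase present in every document scores 0.

Matching is exact on the canonical string; no stemming or lemmatization is
applied (surface forms like "treatment" and "treatments" stay distinct).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .corpus_io import Corpus
from .tagging import ADJ, DET, DETERMINERS, NOUN, RuleTagger, Tagger, split_sentences, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "ChunkGrammar",
    "PhraseStats",
    "DegeneratePhraseError",
    "extract_noun_phrases",
    "normalize_phrase",
    "phrase_document_frequency",
    "compute_tfidf",
]

_EDGE_PUNCT = ".,;:!?()[]{}\"'`“”‘’-–—"


class DegeneratePhraseError(ValueError):
    """Raised when normalization leaves nothing (e.g. a bare determiner)."""


@dataclass(frozen=True)
class ChunkGrammar:
    """Declarative NP pattern: ``DET? (ADJ|NOUN)* NOUN``, maximal match.

    ``determiner_stoplist`` holds the tokens stripped from the front of a raw
    phrase during normalization.
    """

    determiner_stoplist: frozenset[str] = DETERMINERS
    head_tags: frozenset[str] = frozenset({NOUN})
    modifier_tags: frozenset[str] = frozenset({ADJ, NOUN})

    def __post_init__(self) -> None:
        if not self.determiner_stoplist:
            raise ValueError("determiner_stoplist must be non-empty")
        if not (self.head_tags <= self.modifier_tags):
            raise ValueError("head tags must be acceptable modifiers")


DEFAULT_GRAMMAR = ChunkGrammar()
_DEFAULT_TAGGER = RuleTagger()


@dataclass
class PhraseStats:
    """Canonical phrase with its supporting documents and scores.

    ``term_counts`` maps doc_id → raw occurrence count; ``doc_freq`` and
    ``doc_ids`` derive from it, so the ``doc_freq == |doc_ids|`` invariant
    holds by construction.
    """

    phrase: str
    term_counts: dict[str, int] = field(default_factory=dict)
    tfidf: float | None = None

    @property
    def doc_ids(self) -> set[str]:
        return set(self.term_counts)

    @property
    def doc_freq(self) -> int:
        return len(self.term_counts)

    def add_occurrence(self, doc_id: str, count: int = 1) -> None:
        self.term_counts[doc_id] = self.term_counts.get(doc_id, 0) + count


def normalize_phrase(raw: str, grammar: ChunkGrammar = DEFAULT_GRAMMAR) -> str:
    """Canonical form: lowercase, leading determiners and edge punctuation
    stripped, internal whitespace collapsed; internal hyphens preserved.

    Raises :class:`DegeneratePhraseError` if nothing survives.
    """
    tokens = raw.lower().split()
    while tokens and tokens[0] in grammar.determiner_stoplist:
        tokens = tokens[1:]
    tokens = [t.strip(_EDGE_PUNCT) for t in tokens]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise DegeneratePhraseError(f"phrase degenerate after normalization: {raw!r}")
    return " ".join(tokens)


def extract_noun_phrases(
    text: str,
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
) -> list[str]:
    """Return raw NP spans in text order, maximal and non-nested.

    A span is a maximal run ``DET? (ADJ|NOUN)*`` trimmed back to its last
    NOUN; runs with no noun after the optional determiner are discarded. A
    determiner always starts a fresh span.
    """
    tagger = tagger or _DEFAULT_TAGGER
    phrases: list[str] = []
    for sentence in split_sentences(text):
        tokens = tokenize(sentence)
        if not tokens:
            continue
        try:
            tags = tagger.tag(tokens)
        except Exception:  # pragma: no cover — contract: skip, don't fail
            logger.warning("tagger failed on sentence %r; skipped", sentence[:60])
            continue
        i = 0
        n = len(tokens)
        while i < n:
            start = i
            if tags[i] == DET:
                i += 1
            j = i
            while j < n and tags[j] in grammar.modifier_tags and tags[j] != DET:
                j += 1
            # trim back to the last head (noun)
            end = j
            while end > i and tags[end - 1] not in grammar.head_tags:
                end -= 1
            if end > i:
                phrases.append(" ".join(tokens[start:end]))
                i = j if j > i else i + 1
            else:
                i = max(j, start + 1)
    return phrases


def _normalized_phrase_counts(
    doc_text: str, grammar: ChunkGrammar, tagger: Tagger | None
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for raw in extract_noun_phrases(doc_text, grammar, tagger):
        try:
            canon = normalize_phrase(raw, grammar)
        except DegeneratePhraseError:
            continue
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def document_phrase_set(
    doc_text: str,
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
) -> set[str]:
    """The set of canonical NPs a document contains (title+abstract scope)."""
    return set(_normalized_phrase_counts(doc_text, grammar, tagger))


def phrase_document_frequency(
    corpus: Corpus,
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
) -> dict[str, PhraseStats]:
    """Per-phrase stats over a corpus: df and raw per-document counts.

    A phrase occurring k ≥ 1 times within one record contributes exactly 1 to
    its document frequency; title and abstract count as one unit.
    """
    stats: dict[str, PhraseStats] = {}
    for doc in corpus:
        for canon, count in _normalized_phrase_counts(doc.text, grammar, tagger).items():
            stats.setdefault(canon, PhraseStats(canon)).add_occurrence(doc.doc_id, count)
    return stats


def compute_tfidf(corpus: Corpus, stats: dict[str, PhraseStats]) -> dict[str, PhraseStats]:
    """Fill ``tfidf = Σ_d tf(d) · ln(N/df)`` for every phrase, in place."""
    n_docs = len(corpus)
    if n_docs < 1:
        raise ValueError("corpus must contain at least one document")
    for ps in stats.values():
        if ps.doc_freq > n_docs:
            raise ValueError(
                f"doc_freq {ps.doc_freq} exceeds corpus size {n_docs} for {ps.phrase!r}"
            )
        total_tf = sum(ps.term_counts.values())
        ps.tfidf = total_tf * math.log(n_docs / ps.doc_freq)
    return stats
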