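"""Lightweight part-of-speech tagging for shallow noun-phrase chunking.

Noun-phrase extraction only needs a coarse tag set — determiner, adjective
(including participles used attributively), noun, verb, other — so the shipped
tagger is a deterministic rule tagger: closed-class word lists plus suffix
heuristics, with unknown alphabetic tokens defaulting to NOUN (the safe choice
for biomedical term mining, where most out-of-vocabulary tokens are nominal:
scale names, interventions, anatomy).

The tagger is an injection point: anything implementing :class:`Tagger` can be
passed to the extraction functions, so a statistical tagger can be swapped in
without touching the pipeline, and tests can pin exact tag sequences.
"""

from __future__ import annotations

import re
from typing import Protocol, Sequence

__all__ = ["Tagger", "RuleTagger", "FixedTagger", "tokenize", "split_sentences"]

# Coarse tags
DET = "DET"
ADJ = "ADJ"
NOUN = "NOUN"
VERB = "VERB"
OTHER = "OTHER"

_SENT_SPLIT = re.compile(r"(?<=[.!?;])\s+")
# Words keep internal hyphens as single tokens ("fugl-meyer", "constraint-induced").
_TOKEN = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*")

DETERMINERS = frozenset(
    "a an the this that these those each every all both some any no "
    "their its his her our your my".split()
)

# Prepositions, conjunctions, pronouns, adverbials and other closed-class
# tokens that terminate a noun-phrase span.
_CLOSED_CLASS = frozenset(
    """of in on at by for with without after before during from to and or but
    as than which who whom whose while when where if because although though
    however also not only between among within under over into onto via per
    versus vs against about above below across through following using towards
    toward despite we they it he she you i them us him me then there here very
    more most less least such same other another several many much few little
    each both yet so nor once twice still already again further moreover thus
    therefore hence meanwhile whereas until unless since respectively
    significantly respectively p n either neither whether"""
    .split()
)

# Common verb forms seen in abstracts; -ed forms NOT listed here are treated
# as attributive participles (ADJ) so phrases like "induced movement therapy"
# and "constraint-induced movement therapy" chunk correctly.
_VERBS = frozenset(
    """is are was were be been being am has have had having do does did done
    can could may might will would shall should must receive received receives
    improve improved improves show showed shows shown demonstrate demonstrated
    demonstrates assess assessed assesses measured evaluate evaluated
    examine examined investigate investigated use used uses underwent undergo
    perform performed performs compare compared include included includes
    report reported reports find found reveal revealed suggest suggested
    suggests indicate indicated indicates increase increased increases
    decrease decreased decreases reduce reduced reduces remain remained
    remains appear appeared appears conduct conducted enroll enrolled recruit
    recruited complete completed randomize randomized assign assigned observe
    observed obtain obtained analyze analyzed treat treated require required
    occur occurred occurs apply applied provide provided differ differed
    improve consist consisted achieve achieved"""
    .split()
)

# Deliberately narrow: only endings that are almost never nominal in
# biomedical text. "-ent"/"-ant" are excluded (assessment, treatment, patient
# are nouns), and interior ADJ vs NOUN makes no difference to chunk spans —
# the tag only matters at span edges.
_ADJ_SUFFIXES = ("ive", "ous", "ical", "ary", "ful", "less", "able", "ible")


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation; good enough for abstracts."""
    return [s for s in _SENT_SPLIT.split(text) if s.strip()]


def tokenize(sentence: str) -> list[str]:
    """Word tokens with internal hyphens/apostrophes preserved."""
    return _TOKEN.findall(sentence)


class Tagger(Protocol):
    """Maps a token sequence to a same-length coarse tag sequence."""

    def tag(self, tokens: Sequence[str]) -> list[str]:  # pragma: no cover
        ...


class RuleTagger:
    """Deterministic lexicon + suffix tagger over the coarse tag set."""

    def tag(self, tokens: Sequence[str]) -> list[str]:
        return [self._tag_one(t) for t in tokens]

    @staticmethod
    def _tag_one(token: str) -> str:
        low = token.lower()
        if not any(c.isalpha() for c in low):
            return OTHER
        if low in DETERMINERS:
            return DET
        if low in _CLOSED_CLASS:
            return OTHER
        if low in _VERBS:
            return VERB
        if low.endswith("ly") and len(low) > 3:
            return OTHER  # adverb
        if low.endswith("ed") and len(low) > 3:
            return ADJ  # attributive participle ("induced", "massed", "paired")
        if low.endswith("ing"):
            return NOUN  # gerund: "training", "tracking" — NP-final in therapy names
        for suf in _ADJ_SUFFIXES:
            if low.endswith(suf) and len(low) > len(suf) + 2:
                return ADJ
        return NOUN


class FixedTagger:
    """Test helper: returns pre-assigned tags keyed by lowercase token."""

    def __init__(self, tags_by_token: dict[str, str], default: str = NOUN):
        self.tags_by_token = {k.lower(): v for k, v in tags_by_token.items()}
        self.default = default

    def tag(self, tokens: Sequence[str]) -> list[str]:
        return [self.tags_by_token.get(t.lower(), self.default) for t in tokens]
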