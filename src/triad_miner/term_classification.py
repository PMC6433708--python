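"""Suffix-rule classification of phrases into scale/therapy term tables.

A candidate phrase is assigned a category purely by its final token: phrases
ending in "test", "scale", "assessment", "measure", "score" or "index" are
assessment-scale candidates; phrases ending in "training", "therapy",
"treatment", "treatments", "practice", "program", "practise" or "simulation"
are therapy candidates. Single-token phrases (a bare "therapy" or "index") are
never classified — they are noise, not named instruments.

Classified phrases are then thresholded on document frequency (default ≥ 6,
i.e. appearing in more than five articles) and filtered against per-category
blacklists. The shipped blacklists encode the kind of generic or off-topic
phrases a domain expert would strike out during manual review ("pre-test",
"body mass index", drug therapies such as "antiplatelet therapy"); they are
configuration, editable without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .phrase_mining import PhraseStats

__all__ = [
    "SuffixRuleSet",
    "Blacklist",
    "TermRow",
    "TermTable",
    "DEFAULT_SUFFIX_RULES",
    "DEFAULT_BLACKLIST",
    "classify_suffix",
    "build_term_table",
    "rank_table",
    "load_rules_yaml",
    "load_blacklist_yaml",
]

SCALE = "scale"
THERAPY = "therapy"


@dataclass(frozen=True)
class SuffixRuleSet:
    """category → ordered suffix tokens; categories must not share a suffix."""

    rules: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cat, suffixes in self.rules.items():
            for s in suffixes:
                if s != s.lower() or " " in s or not s:
                    raise ValueError(f"suffix must be a lowercase single token: {s!r}")
                if s in seen:
                    raise ValueError(
                        f"suffix {s!r} in both {seen[s]!r} and {cat!r}: categories must be disjoint"
                    )
                seen[s] = cat

    def category_of_token(self, token: str) -> str | None:
        for cat, suffixes in self.rules.items():
            if token in suffixes:
                return cat
        return None

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.rules)


DEFAULT_SUFFIX_RULES = SuffixRuleSet(
    {
        SCALE: ("test", "scale", "assessment", "measure", "score", "index"),
        THERAPY: (
            "training", "therapy", "treatment", "treatments",
            "practice", "program", "practise", "simulation",
        ),
    }
)


@dataclass(frozen=True)
class Blacklist:
    """category → canonical phrases to drop (the emulated manual review)."""

    phrases: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def excluded(self, category: str, phrase: str) -> bool:
        return phrase in self.phrases.get(category, frozenset())


DEFAULT_BLACKLIST = Blacklist(
    {
        SCALE: frozenset(
            {
                "pre-test", "post-test", "outcome assessment",
                "body mass index", "depression score", "mmse score",
            }
        ),
        THERAPY: frozenset(
            {
                "clinical practice", "conventional therapy", "medical therapy",
                "physical therapy", "specific training", "combined therapy",
                "antiplatelet therapy", "anticoagulant therapy",
                "antihypertensive therapy", "antithrombotic therapy",
            }
        ),
    }
)


def classify_suffix(phrase: str, rules: SuffixRuleSet = DEFAULT_SUFFIX_RULES) -> str | None:
    """Category of a canonical phrase, decided solely by its last token.

    Single-token phrases return None.
    """
    tokens = phrase.split()
    if len(tokens) < 2:
        return None
    return rules.category_of_token(tokens[-1])


@dataclass(frozen=True)
class TermRow:
    phrase: str
    category: str
    doc_freq: int
    tfidf: float | None = None


@dataclass
class TermTable:
    """Classified, thresholded, blacklist-filtered phrases of one category."""

    rows: list[TermRow]
    category: str
    threshold_used: int = 1
    sort_key: str = "doc_freq"

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def phrases(self) -> set[str]:
        return {r.phrase for r in self.rows}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.phrase, r.category, r.doc_freq, r.tfidf) for r in self.rows],
            columns=["phrase", "category", "doc_freq", "tfidf"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, category: str, threshold_used: int = 1) -> "TermTable":
        rows = [
            TermRow(
                str(r.phrase), category, int(r.doc_freq),
                None if pd.isna(r.tfidf) else float(r.tfidf),
            )
            for r in df.itertuples()
        ]
        return cls(rows, category, threshold_used)


def build_term_table(
    stats: Mapping[str, PhraseStats],
    rules: SuffixRuleSet = DEFAULT_SUFFIX_RULES,
    min_doc_freq: int = 6,
    blacklist: Blacklist = DEFAULT_BLACKLIST,
) -> dict[str, TermTable]:
    """One table per category: classified, df-thresholded, blacklist-filtered.

    Output is independent of the iteration order of ``stats`` (rows are sorted
    by the default ranking).
    """
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be ≥ 1")
    tables: dict[str, list[TermRow]] = {c: [] for c in rules.categories}
    for phrase, ps in stats.items():
        cat = classify_suffix(phrase, rules)
        if cat is None:
            continue
        if ps.doc_freq < min_doc_freq:
            continue
        if blacklist.excluded(cat, phrase):
            continue
        tables[cat].append(TermRow(phrase, cat, ps.doc_freq, ps.tfidf))
    return {
        cat: rank_table(TermTable(rows, cat, threshold_used=min_doc_freq), "doc_freq")
        for cat, rows in tables.items()
    }


def _sort_value(v: float | None) -> float:
    return 0.0 if v is None else v


def rank_table(table: TermTable, key: str = "doc_freq") -> TermTable:
    """Sort descending by ``key`` ('doc_freq' or 'tfidf'); ties broken by the
    other key descending, then phrase ascending. Deterministic."""
    if key not in ("doc_freq", "tfidf"):
        raise ValueError(f"invalid sort key: {key!r}")
    other = "tfidf" if key == "doc_freq" else "doc_freq"

    def sort_key(row: TermRow):
        primary = _sort_value(getattr(row, key))
        secondary = _sort_value(getattr(row, other))
        return (-primary, -secondary, row.phrase)

    return TermTable(sorted(table.rows, key=sort_key), table.category,
                     table.threshold_used, sort_key=key)


# ---------------------------------------------------------------------------
# Configuration files (YAML)
# ---------------------------------------------------------------------------

def load_rules_yaml(stream) -> SuffixRuleSet:
    """Load ``{category: [suffix, ...]}`` from YAML."""
    data = yaml.safe_load(stream)
    if not isinstance(data, dict) or not data:
        raise ValueError("rules file must map categories to suffix lists")
    return SuffixRuleSet({str(c): tuple(str(s) for s in sfx) for c, sfx in data.items()})


def load_blacklist_yaml(stream) -> Blacklist:
    """Load ``{category: [phrase, ...]}`` from YAML."""
    data = yaml.safe_load(stream) or {}
    if not isinstance(data, dict):
        raise ValueError("blacklist file must map categories to phrase lists")
    return Blacklist({str(c): frozenset(str(p) for p in ps or []) for c, ps in data.items()})
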