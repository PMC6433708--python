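"""Synthetic corpora with controlled A–B–C structure, plus packaged fixtures.

The generator emulates the statistical skeleton of a disease/scale/therapy
literature: a disease corpus in which every record mentions a disease keyword
and samples assessment scales and known therapies, and a scale-anchored corpus
in which each record is anchored on one scale and co-mentions therapies at
configured per-pair rates. One *planted candidate* therapy is constructed to
co-occur with a fixed set of scales but never with the disease — the
recoverable ground truth for the whole pipeline. *Decoy* candidates have fewer
scale links; *leaky* candidates do co-occur with the disease (in a few
below-threshold disease records) and must be caught by the exclusion step.

Documents are template sentences with phrases inserted into fixed grammatical
frames, so the shallow chunker recovers them reliably and tests isolate
pipeline logic from tagger quality. All bookkeeping (true document
frequencies, true edge weights, abstract-less ids) is recorded *during*
generation, never recomputed, making the ground truth a valid independent
oracle.

Also packaged here: the published reference tables (26 stroke scales, 47
stroke therapies, 5 repositioning candidates) as checksummed TSV fixtures.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .corpus_io import Corpus, Document
from .term_classification import (
    DEFAULT_SUFFIX_RULES,
    SCALE,
    THERAPY,
    TermRow,
    TermTable,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate_corpus",
    "load_paper_tables",
    "FixtureError",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic run.

    ``cooccur_rates`` maps therapy → (scale → per-document probability) in the
    scale-anchored corpus; a therapy absent from the mapping is never sampled
    there. ``planted_candidate`` gets one dedicated record per scale in
    ``planted_links`` (co-occurrence rate 1.0 over exactly those records) and
    never enters the disease corpus. ``leaky_candidates`` each get
    ``leaky_disease_docs`` dedicated disease records (below the df threshold,
    so they stay out of the known-therapy set but trip the exclusion scan).
    """

    n_disease_docs: int = 200
    n_scale_docs: int = 320
    disease_terms: tuple[str, ...] = ("stroke", "cerebral infarction", "brain ischemia")
    scale_vocab: tuple[str, ...] = ()
    therapy_vocab: tuple[str, ...] = ()  # known therapies, present in both corpora
    noise_vocab: tuple[str, ...] = ()
    planted_candidate: str = "hand arm bimanual intensive training"
    planted_links: tuple[str, ...] = ()
    decoy_candidates: tuple[str, ...] = ()
    leaky_candidates: tuple[str, ...] = ()
    cooccur_rates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    known_disease_rate: float = 0.08  # per-doc rate of each known therapy in disease docs
    noise_rate: float = 0.5
    abstractless_rate: float = 0.05
    leaky_disease_docs: int = 2
    seed: int = 0

    def validate(self) -> None:
        rules = DEFAULT_SUFFIX_RULES
        all_therapy_phrases = (
            set(self.therapy_vocab) | set(self.decoy_candidates)
            | set(self.leaky_candidates) | {self.planted_candidate}
        )
        for p in all_therapy_phrases:
            last = p.split()[-1] if p.split() else ""
            if rules.category_of_token(last) != THERAPY:
                raise ValueError(f"therapy phrase lacks a therapy suffix: {p!r}")
        for p in self.scale_vocab:
            if rules.category_of_token(p.split()[-1]) != SCALE:
                raise ValueError(f"scale phrase lacks a scale suffix: {p!r}")
        disease_side = set(self.therapy_vocab) | set(self.noise_vocab) | set(self.scale_vocab)
        if self.planted_candidate in disease_side:
            raise ValueError("planted candidate must be absent from disease-doc vocabulary")
        if set(self.decoy_candidates) & disease_side:
            raise ValueError("decoy candidates must be absent from disease-doc vocabulary")
        if not set(self.planted_links) <= set(self.scale_vocab):
            raise ValueError("planted_links must be a subset of scale_vocab")
        for therapy, per_scale in self.cooccur_rates.items():
            for scale, rate in per_scale.items():
                if scale not in self.scale_vocab:
                    raise ValueError(f"cooccur rate for unknown scale {scale!r}")
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"rate out of [0,1] for ({therapy!r}, {scale!r})")
        for name, rate in (("known_disease_rate", self.known_disease_rate),
                           ("noise_rate", self.noise_rate),
                           ("abstractless_rate", self.abstractless_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} out of [0,1]")
        n_vocab = (len(self.scale_vocab) + len(self.therapy_vocab) + len(self.noise_vocab)
                   + len(self.decoy_candidates) + len(self.leaky_candidates) + 1)
        if n_vocab != len(all_therapy_phrases | set(self.scale_vocab) | set(self.noise_vocab)):
            raise ValueError("vocabulary phrases must be pairwise distinct across roles")


_SCALES = (
    "fugl-meyer assessment",
    "barthel index",
    "action research arm test",
    "wolf motor function test",
    "berg balance scale",
    "motricity index",
    "nihss score",
    "goal attainment scale",
    "assisting hand assessment",
    "canadian occupational performance measure",
)

_KNOWN_THERAPIES = (
    "mirror therapy",
    "treadmill training",
    "botulinum toxin treatment",
    "electroacupuncture treatments",
    "massed practice",
    "exercise program",
    "bimanual practise",
    "gait simulation",
)

_DECOYS = (
    "massage therapy",
    "homeopathic treatment",
    "music training",
    "relaxation practice",
    "aromatherapy program",
)

_LEAKY = ("cognitive behavior therapy", "yoga treatment")

_NOISE = (
    "upper limb function",
    "motor recovery",
    "hospital stay",
    "activity performance",
    "grip strength",
)

_PLANTED_LINKS = (
    "canadian occupational performance measure",
    "assisting hand assessment",
    "goal attainment scale",
    "action research arm test",
    "barthel index",
    "nihss score",
    "berg balance scale",
)

# Scale links for the decoy and leaky candidates (fewer than the planted 7).
_DECOY_LINKS: dict[str, tuple[str, ...]] = {
    "massage therapy": ("fugl-meyer assessment", "barthel index"),
    "homeopathic treatment": ("berg balance scale",),
    "music training": ("motricity index", "nihss score", "goal attainment scale"),
    "relaxation practice": ("wolf motor function test", "assisting hand assessment"),
    "aromatherapy program": ("action research arm test",),
}
_LEAKY_LINKS: dict[str, tuple[str, ...]] = {
    "cognitive behavior therapy": ("fugl-meyer assessment", "barthel index"),
    "yoga treatment": ("berg balance scale", "motricity index"),
}

_LINKED_RATE = 0.35  # per-doc co-mention rate on a candidate's linked scales
_KNOWN_SCALE_RATE = 0.08  # per-doc rate of each known therapy in scale-anchored docs


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default study conditions: 10 scales, 8 known therapies, 5 decoys,
    2 leaky candidates, and one planted candidate linked to 7 scales."""
    rates: dict[str, dict[str, float]] = {
        t: {s: _KNOWN_SCALE_RATE for s in _SCALES} for t in _KNOWN_THERAPIES
    }
    for decoy, links in _DECOY_LINKS.items():
        rates[decoy] = {s: _LINKED_RATE for s in links}
    for leaky, links in _LEAKY_LINKS.items():
        rates[leaky] = {s: _LINKED_RATE for s in links}
    return SyntheticConfig(
        scale_vocab=_SCALES,
        therapy_vocab=_KNOWN_THERAPIES,
        noise_vocab=_NOISE,
        decoy_candidates=_DECOYS,
        leaky_candidates=_LEAKY,
        planted_links=_PLANTED_LINKS,
        cooccur_rates=rates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generation-time bookkeeping; the independent oracle for the pipeline."""

    df: dict[str, dict[str, int]]  # corpus name → phrase → true document frequency
    edges: dict[tuple[str, str], int]  # (scale, therapy) → true weight in scale corpus
    planted_candidate: str
    planted_links: frozenset[str]
    decoy_links: dict[str, frozenset[str]]
    leaky_candidates: tuple[str, ...]
    abstractless: dict[str, set[str]]  # corpus name → doc ids with empty abstract

    @property
    def planted_n_links(self) -> int:
        return len(self.planted_links)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _make_doc(doc_id: str, title: str, sentences: list[str], abstractless: bool) -> Document:
    return Document(doc_id, title, "" if abstractless else " ".join(sentences))


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, Corpus, GroundTruth]:
    """Generate (disease corpus, scale-anchored corpus, ground truth).

    Deterministic: the same config (seed included) yields byte-identical
    corpora. Phrase bookkeeping is recorded as documents are emitted.
    """
    config.validate()
    rng = random.Random(config.seed)
    df: dict[str, dict[str, int]] = {"disease": {}, "scale": {}}
    edges: dict[tuple[str, str], int] = {}
    abstractless: dict[str, set[str]] = {"disease": set(), "scale": set()}

    tracked = (set(config.scale_vocab) | set(config.therapy_vocab)
               | set(config.noise_vocab) | set(config.decoy_candidates)
               | set(config.leaky_candidates) | {config.planted_candidate})

    def record(corpus_name: str, phrases: set[str]) -> None:
        table = df[corpus_name]
        for p in phrases & tracked:
            table[p] = table.get(p, 0) + 1

    # ---- disease corpus -------------------------------------------------
    disease_docs: list[Document] = []
    for i in range(config.n_disease_docs):
        doc_id = f"D{i + 1:05d}"
        disease = config.disease_terms[i % len(config.disease_terms)]
        title = f"Rehabilitation outcomes in patients with {disease}."
        empty = rng.random() < config.abstractless_rate
        phrases: set[str] = set()
        sentences = [f"We recruited patients with {disease}."]
        if not empty:
            scale = config.scale_vocab[i % len(config.scale_vocab)]
            phrases.add(scale)
            sentences.append(f"Patients improved on the {scale}.")
            for therapy in config.therapy_vocab:
                if rng.random() < config.known_disease_rate:
                    phrases.add(therapy)
                    sentences.append(f"Participants received {therapy} during rehabilitation.")
            if rng.random() < config.noise_rate:
                noise = config.noise_vocab[i % len(config.noise_vocab)] if config.noise_vocab else None
                if noise:
                    phrases.add(noise)
                    sentences.append(f"The study examined {noise}.")
        else:
            abstractless["disease"].add(doc_id)
        disease_docs.append(_make_doc(doc_id, title, sentences, empty))
        record("disease", phrases)

    # dedicated leaky records: candidate + disease keyword, below threshold
    idx = config.n_disease_docs
    for leaky in config.leaky_candidates:
        for k in range(config.leaky_disease_docs):
            idx += 1
            doc_id = f"D{idx:05d}"
            disease = config.disease_terms[0]
            title = "A pilot intervention study."
            sentences = [
                f"We recruited patients with {disease}.",
                f"Participants received {leaky} during rehabilitation.",
            ]
            disease_docs.append(_make_doc(doc_id, title, sentences, False))
            record("disease", {leaky})

    # ---- scale-anchored corpus ------------------------------------------
    scale_docs: list[Document] = []
    therapies_in_order = (tuple(config.therapy_vocab) + tuple(config.decoy_candidates)
                          + tuple(config.leaky_candidates))
    for i in range(config.n_scale_docs):
        doc_id = f"S{i + 1:05d}"
        anchor = config.scale_vocab[i % len(config.scale_vocab)]
        title = f"Assessment with the {anchor} in clinical rehabilitation."
        empty = rng.random() < config.abstractless_rate
        phrases = {anchor}
        sentences = [f"Function was measured with the {anchor}."]
        doc_therapies: set[str] = set()
        if not empty:
            for therapy in therapies_in_order:
                rate = config.cooccur_rates.get(therapy, {}).get(anchor, 0.0)
                if rate and rng.random() < rate:
                    doc_therapies.add(therapy)
                    sentences.append(f"Participants received {therapy} during the intervention.")
            if rng.random() < config.noise_rate and config.noise_vocab:
                noise = config.noise_vocab[i % len(config.noise_vocab)]
                phrases.add(noise)
                sentences.append(f"The study examined {noise}.")
        else:
            abstractless["scale"].add(doc_id)
            doc_therapies = set()
        scale_docs.append(_make_doc(doc_id, title, sentences, empty))
        record("scale", phrases | doc_therapies)
        for t in doc_therapies:
            edges[(anchor, t)] = edges.get((anchor, t), 0) + 1

    # dedicated planted records: one per linked scale, co-occurrence rate 1.0
    idx = config.n_scale_docs
    for scale in config.planted_links:
        idx += 1
        doc_id = f"S{idx:05d}"
        title = "Bimanual intervention outcomes in children."
        sentences = [
            f"Children received {config.planted_candidate} twice daily.",
            f"Function was measured with the {scale}.",
        ]
        scale_docs.append(_make_doc(doc_id, title, sentences, False))
        record("scale", {scale, config.planted_candidate})
        key = (scale, config.planted_candidate)
        edges[key] = edges.get(key, 0) + 1

    truth = GroundTruth(
        df=df,
        edges=edges,
        planted_candidate=config.planted_candidate,
        planted_links=frozenset(config.planted_links),
        decoy_links={d: frozenset(links) for d, links in _decoy_links_of(config).items()},
        leaky_candidates=tuple(config.leaky_candidates),
        abstractless=abstractless,
    )
    return (
        Corpus(disease_docs, source_label=f"synthetic-disease:seed={config.seed}"),
        Corpus(scale_docs, source_label=f"synthetic-scale:seed={config.seed}"),
        truth,
    )


def _decoy_links_of(config: SyntheticConfig) -> dict[str, tuple[str, ...]]:
    return {
        d: tuple(s for s, r in config.cooccur_rates.get(d, {}).items() if r > 0)
        for d in config.decoy_candidates
    }


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

class FixtureError(RuntimeError):
    """A packaged fixture failed its checksum or structure check."""


_FIXTURE_SHA256 = {
    "stroke_scales.tsv": "696b059f3921c8add86ef8452173fc660e0e213ff2f04d48e7096d8cbb941c35",
    "stroke_therapies.tsv": "c2ea35b7102005d0d51f1c7175d0310e1895404b724d71364ed4f0ffe5e4f689",
    "repositioning_candidates.tsv": "e9f304482880aecee6f48f2e82547a5d5530cbf5fbad64036f61e7975286be87",
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("triad_miner.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(f"fixture {name} corrupt: sha256 {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def load_paper_tables() -> tuple[TermTable, TermTable, TermTable]:
    """The published reference tables as term tables.

    Returns (stroke scales, stroke therapies, repositioning candidates) with
    canonical lowercase phrases and document frequencies; the scale table also
    carries TF-IDF scores. Published surface-form duplicates (the Rankin scale
    appears twice) are preserved as distinct rows.
    """
    scales_df = _read_fixture("stroke_scales.tsv")
    scales = TermTable(
        [TermRow(str(r.phrase), SCALE, int(r.doc_freq), float(r.tfidf))
         for r in scales_df.itertuples()],
        SCALE, threshold_used=6,
    )
    therapies_df = _read_fixture("stroke_therapies.tsv")
    therapies = TermTable(
        [TermRow(str(r.phrase), THERAPY, int(r.doc_freq)) for r in therapies_df.itertuples()],
        THERAPY, threshold_used=6,
    )
    candidates_df = _read_fixture("repositioning_candidates.tsv")
    candidates = TermTable(
        [TermRow(str(r.phrase), THERAPY, int(r.doc_freq)) for r in candidates_df.itertuples()],
        THERAPY, threshold_used=6,
    )
    return scales, therapies, candidates
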