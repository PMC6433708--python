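"""Co-occurrence linking, subtraction, disease exclusion, and ranking."""

import dataclasses
import itertools

import pytest
from hypothesis import given, strategies as st

from triad_miner.abc_discovery import (
    CooccurrenceEdge,
    cooccurrence_edges,
    derive_all_therapies,
    exclude_disease_cooccurrence,
    export_interaction_matrix,
    rank_candidates,
    run_discovery,
    subtract_known,
)
from triad_miner.corpus_io import Corpus, Document
from triad_miner.phrase_mining import document_phrase_set
from triad_miner.term_classification import THERAPY, TermRow, TermTable

PHRASE = st.text(alphabet="abcde", min_size=1, max_size=5)


def brute_force_edges(corpus, scales, therapies):
    """Independent all-pairs nested-loop document scan."""
    weights = {}
    doc_sets = [document_phrase_set(d.text) for d in corpus]
    for b in scales:
        for c in therapies:
            w = sum(1 for s in doc_sets if b in s and c in s)
            if w:
                weights[(b, c)] = w
    return weights


class TestCooccurrenceEdges:
    def test_single_shared_document(self):
        corpus = Corpus([
            Document("1", "", "Scores on the barthel index improved after massage therapy."),
        ])
        edges = cooccurrence_edges(corpus, {"barthel index"}, {"massage therapy"})
        assert edges == [CooccurrenceEdge("barthel index", "massage therapy", 1)]

    def test_planted_candidate_gets_exactly_its_configured_links(self, default_run):
        cfg, _, scale_corpus, truth = default_run
        edges = cooccurrence_edges(
            scale_corpus, set(cfg.scale_vocab), {truth.planted_candidate}
        )
        assert {e.scale_phrase for e in edges} == set(truth.planted_links)
        assert len(edges) == 7

    def test_matches_brute_force_oracle_on_small_corpora(self):
        from triad_miner.synthetic_corpus import default_config, generate_corpus

        cfg = dataclasses.replace(default_config(seed=11),
                                  n_disease_docs=5, n_scale_docs=40)
        _, scale_corpus, _ = generate_corpus(cfg)
        assert len(scale_corpus) <= 50
        scales = set(cfg.scale_vocab)
        therapies = (set(cfg.therapy_vocab) | set(cfg.decoy_candidates)
                     | {cfg.planted_candidate})
        got = {(e.scale_phrase, e.therapy_phrase): e.weight
               for e in cooccurrence_edges(scale_corpus, scales, therapies)}
        assert got == brute_force_edges(scale_corpus, scales, therapies)

    def test_invariant_to_document_order_and_phrase_repetition(self):
        base = [
            Document("1", "Massage therapy report.",
                     "The barthel index improved after massage therapy. "
                     "We repeated massage therapy daily."),
            Document("2", "", "Scores on the barthel index improved."),
        ]
        scales, therapies = {"barthel index"}, {"massage therapy"}
        fwd = cooccurrence_edges(Corpus(base), scales, therapies)
        rev = cooccurrence_edges(Corpus(base[::-1]), scales, therapies)
        assert fwd == rev
        assert fwd[0].weight == 1  # repeats within one record count once

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            cooccurrence_edges(Corpus([]), {"x therapy"}, {"x therapy"})


class TestDeriveAllTherapies:
    def test_planted_above_threshold_retained_below_absent(self, default_run):
        cfg, _, scale_corpus, truth = default_run
        table = derive_all_therapies(scale_corpus, min_doc_freq=6)
        assert truth.planted_candidate in table.phrases()  # df 7 ≥ 6
        table_high = derive_all_therapies(scale_corpus, min_doc_freq=8)
        assert truth.planted_candidate not in table_high.phrases()  # df 7 < 8

    def test_equals_independent_straight_line_recomputation(self, default_run):
        """Oracle: a from-scratch scan of the corpus with no shared pipeline code
        beyond phrase extraction, applying suffix/threshold/blacklist by hand."""
        from triad_miner.term_classification import (
            DEFAULT_BLACKLIST, DEFAULT_SUFFIX_RULES,
        )

        _, _, scale_corpus, _ = default_run
        suffixes = DEFAULT_SUFFIX_RULES.rules[THERAPY]
        counts = {}
        for doc in scale_corpus:
            for p in document_phrase_set(doc.text):
                toks = p.split()
                if len(toks) >= 2 and toks[-1] in suffixes:
                    counts[p] = counts.get(p, 0) + 1
        expected = {
            p for p, c in counts.items()
            if c >= 6 and p not in DEFAULT_BLACKLIST.phrases[THERAPY]
        }
        table = derive_all_therapies(scale_corpus, min_doc_freq=6)
        assert table.phrases() == expected
        for row in table:
            assert row.doc_freq == counts[row.phrase]


def _table(phrases_df):
    return TermTable(
        [TermRow(p, THERAPY, df) for p, df in phrases_df.items()], THERAPY, 6
    )


class TestSubtractKnown:
    def test_exact_set_difference_preserves_stats(self):
        table = _table({"a therapy": 9, "b therapy": 7})
        out = subtract_known(table, {"b therapy"})
        assert out.phrases() == {"a therapy"}
        assert out.rows[0].doc_freq == 9

    def test_subtracting_everything_gives_empty_table(self):
        table = _table({"a therapy": 9})
        assert subtract_known(table, table.phrases()).rows == []

    @given(
        st.dictionaries(PHRASE, st.integers(min_value=6, max_value=50), max_size=20),
        st.sets(PHRASE, max_size=20),
    )
    def test_output_disjoint_from_known_set(self, phrases, known):
        out = subtract_known(_table(phrases), known)
        assert not (out.phrases() & known)
        assert out.phrases() == set(phrases) - known


class TestExcludeDiseaseCooccurrence:
    CORPUS = Corpus([
        Document("1", "", "Patients with stroke received massage therapy."),
        Document("2", "", "Participants received music training after surgery."),
        Document("3", "", "We recruited patients with cerebral infarction."),
    ])

    def test_candidate_co_mentioned_with_disease_removed(self):
        table = _table({"massage therapy": 8, "music training": 8})
        out = exclude_disease_cooccurrence(table, self.CORPUS, {"stroke"})
        assert out.phrases() == {"music training"}

    def test_zero_co_mention_candidate_retained_even_if_present(self):
        # music training appears only in a document with no disease keyword
        table = _table({"music training": 8})
        out = exclude_disease_cooccurrence(
            table, self.CORPUS, {"stroke", "cerebral infarction"}
        )
        assert out.phrases() == {"music training"}

    def test_empty_candidate_table(self):
        out = exclude_disease_cooccurrence(_table({}), self.CORPUS, {"stroke"})
        assert out.rows == []

    def test_exclusion_soundness_by_independent_scan(self, default_run):
        cfg, disease_corpus, scale_corpus, truth = default_run
        table = derive_all_therapies(scale_corpus)
        survivors = exclude_disease_cooccurrence(
            table, disease_corpus, cfg.disease_terms
        ).phrases()
        terms = [t.lower() for t in cfg.disease_terms]
        for doc in disease_corpus:
            if any(t in doc.text.lower() for t in terms):
                assert not (survivors & document_phrase_set(doc.text))


class TestRankCandidates:
    def test_more_linked_scales_wins(self):
        table = _table({"a therapy": 7, "b therapy": 40})
        edges = [CooccurrenceEdge(f"s{i} scale", "a therapy", 1) for i in range(7)]
        edges += [CooccurrenceEdge(f"s{i} scale", "b therapy", 5) for i in range(2)]
        result = rank_candidates(table, edges)
        assert [c.phrase for c in result.candidates] == ["a therapy", "b therapy"]
        assert result.candidates[0].rank == 1
        assert result.candidates[0].n_links == 7

    def test_equal_links_broken_by_document_frequency(self):
        table = _table({"massage therapy": 30, "homeopathic treatment": 16})
        edges = [
            CooccurrenceEdge("barthel index", "massage therapy", 1),
            CooccurrenceEdge("barthel index", "homeopathic treatment", 1),
        ]
        result = rank_candidates(table, edges)
        assert [c.phrase for c in result.candidates] == [
            "massage therapy", "homeopathic treatment",
        ]

    def test_empty_input_gives_empty_result(self):
        result = rank_candidates(_table({}), [])
        assert result.candidates == []

    @given(st.dictionaries(PHRASE, st.tuples(
        st.integers(min_value=1, max_value=40),      # doc_freq
        st.integers(min_value=0, max_value=5),       # n_links
    ), max_size=12))
    def test_ranking_is_a_total_order(self, spec):
        table = _table({p: df for p, (df, _) in spec.items()})
        edges = [
            CooccurrenceEdge(f"scale{i} scale", p, 1)
            for p, (_, k) in spec.items()
            for i in range(k)
        ]
        result = rank_candidates(table, edges)
        assert [c.rank for c in result.candidates] == list(range(1, len(spec) + 1))
        keys = [(-c.n_links, -c.doc_freq, c.phrase) for c in result.candidates]
        assert keys == sorted(keys)
        # antisymmetry: no two candidates share a full sort key
        assert len(set(keys)) == len(keys)


class TestInteractionMatrix:
    def test_single_edge_with_marginals(self):
        mat = export_interaction_matrix(
            [CooccurrenceEdge("b scale", "c therapy", 3)], ["b scale"], ["c therapy"]
        )
        assert mat.loc["b scale", "c therapy"] == 3
        assert mat.loc["b scale", "_total"] == 3
        assert mat.loc["_total", "c therapy"] == 3
        assert mat.loc["_total", "_total"] == 3

    def test_empty_edge_set_is_all_zero(self):
        mat = export_interaction_matrix([], ["b scale"], ["c therapy"])
        assert (mat.to_numpy() == 0).all()

    def test_marginals_equal_oracle_pair_counts(self, default_run):
        cfg, _, scale_corpus, truth = default_run
        therapies = set(cfg.decoy_candidates) | {truth.planted_candidate}
        scales = set(cfg.scale_vocab)
        edges = cooccurrence_edges(scale_corpus, scales, therapies)
        oracle = brute_force_edges(scale_corpus, scales, therapies)
        mat = export_interaction_matrix(edges, scales, therapies)
        assert mat.loc["_total", "_total"] == sum(oracle.values())
        for t in therapies:
            assert mat.loc["_total", t] == sum(
                w for (b, c), w in oracle.items() if c == t
            )


class TestRunDiscovery:
    def test_full_pipeline_recovers_planted_candidate(self, default_run):
        cfg, disease, scale, truth = default_run
        result, tables = run_discovery(disease, scale, cfg.disease_terms)
        top = result.candidates[0]
        assert top.phrase == truth.planted_candidate
        assert top.rank == 1
        assert top.linked_scales == truth.planted_links
        # known therapies are gone, leaky candidates are excluded
        survivors = {c.phrase for c in result.candidates}
        assert not (survivors & set(cfg.therapy_vocab))
        assert not (survivors & set(truth.leaky_candidates))

    def test_scale_universe_override_is_respected(self, default_run):
        cfg, disease, scale, truth = default_run
        universe = set(truth.planted_links) - {sorted(truth.planted_links)[0]}
        result, _ = run_discovery(disease, scale, cfg.disease_terms,
                                  scale_universe=universe)
        top = next(c for c in result.candidates if c.phrase == truth.planted_candidate)
        assert top.linked_scales == frozenset(universe)
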