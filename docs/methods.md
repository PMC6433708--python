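# Methods

## Model

The pipeline implements open literature-based discovery in Swanson's ABC form.
Let *A* be a disease, *B* a set of intermediate terms, and *C* a set of
interventions. Two corpora are used: a disease corpus `D_A` (records retrieved
by disease keywords) and a scale-anchored corpus `D_B` (records retrieved by
the *B* terms). The *B* set here is the set of clinical assessment scales: the
working assumption is that therapies targeting the same functional outcome are
evaluated on the same named instruments, so scale co-occurrence is a proxy for
therapeutic comparability even across patient populations.

Stages, with the contracts that matter:

1. **Noun-phrase mining.** Titles and abstracts are sentence-split, tokenized
   (internal hyphens preserved), POS-tagged with a coarse tag set, and chunked
   with the maximal pattern `DET? (ADJ|NOUN)* NOUN`; spans are trimmed back to
   their final noun and never nested. Phrases are normalized to a canonical
   form: lowercase, leading determiners and edge punctuation stripped,
   whitespace collapsed. Matching everywhere downstream is exact on the
   canonical string — no stemming or lemmatization, so surface forms such as
   "treatment" and "treatments" stay distinct by design.
2. **Statistics.** `df(p)` counts distinct records containing `p` (a record's
   title and abstract are one unit; k occurrences in one record contribute 1).
   The importance score is the corpus-level aggregate
   `tfidf(p) = Σ_d tf(p,d) · ln(N / df(p))` with raw occurrence counts `tf`;
   it is zero exactly when `p` occurs in every record, and adding a record
   that lacks `p` strictly increases it. This is the simplest corpus-level
   weighting consistent with ranking terms by how concentrated their usage is.
3. **Classification.** Category is a function of the final whitespace token
   only. Single-token phrases are never classified: every informative scale or
   therapy name is multiword, and bare suffix tokens ("therapy", "index") are
   pure noise. The frequency threshold is `df ≥ 6` ("more than five
   articles", read strictly); it is configurable. Blacklists are shipped
   configuration emulating expert review — generic phrases ("pre-test",
   "outcome assessment"), off-topic instruments ("body mass index"), and drug
   therapies ("antiplatelet therapy") — and are applied per category after
   thresholding. The `review` CLI command dumps terms near the threshold for
   human triage.
4. **Linking and ranking.** An edge (b, c, w) exists iff `w ≥ 1` records of
   the scale corpus contain both canonical phrases; counting is binary per
   record, so edge weights are invariant to phrase repetition within a record
   and to record order. Known therapies (the therapy table of the disease
   corpus) are removed from the scale-corpus therapy table by exact set
   difference. The disease-exclusion step then removes any candidate present
   (as a canonical NP) in a record that also contains a disease keyword (raw
   lowercase substring — disease terms are keywords, not tracked NPs);
   survivors provably have zero co-mention records in the scanned corpus.
   Ranking uses the comparator (number of linked scales desc, df desc, phrase
   asc); the tie rule is fully specified so ranks are reproducible.

The B set used for linking defaults to the disease-derived scale table but can
be overridden with a superset (`scale_universe`), since in practice relevant
scales may come from outside the disease literature (e.g. pediatric
instruments linked to a candidate developed for congenital hemiplegia).

## Part-of-speech tagging

Chunking needs only five tags (DET/ADJ/NOUN/VERB/OTHER), so the shipped tagger
is a deterministic rule tagger: closed-class word lists (determiners,
prepositions, conjunctions, pronouns, auxiliaries, ~100 common abstract
verbs), adverb (`-ly`) and participle (`-ed` → attributive ADJ) heuristics,
gerunds (`-ing`) treated as nouns (therapy names end in "training"), a
deliberately narrow adjectival-suffix list (`-ive, -ous, -ical, -ary, -ful,
-less, -able, -ible` — notably *not* `-ent`/`-ant`, which are nominal in
"assessment", "treatment", "patient"), and NOUN as the default for unknown
alphabetic tokens. The interior of a chunk treats ADJ and NOUN identically, so
only span edges are sensitive to tagging errors. The tagger is an injection
point (`Tagger` protocol): tests that must be tagger-independent pin exact tag
sequences with `FixedTagger`, and a statistical tagger can be swapped in
without touching pipeline code. Unknown `-ed` verbs outside the lexicon will
be absorbed into a following noun phrase as participles; this is the main
known failure mode on free text and is harmless for suffix-classified terms.

## Synthetic corpus generator

The generator emulates the *statistical structure* of the two literatures, not
their language. Documents are fixed grammatical frames with phrases inserted
("Patients improved on the {scale} after {therapy}."), chosen so the chunker
recovers every planted phrase exactly; this isolates pipeline logic from
tagger quality. Default conditions (one decision, made once):

| parameter | default | why |
|---|---|---|
| disease records | 200 | desk-scale analogue of a keyword retrieval; every vocab term clears df ≥ 6 with margin |
| scale-anchored records | 320 | 32 records per anchor scale |
| scales | 10, covering all six scale suffixes | exercises every rule |
| known therapies | 8, covering all eight therapy suffixes | present in both corpora (df ≈ 16 and ≈ 25), so they are mined *and* subtracted |
| planted candidate | linked to 7 scales, 1 dedicated record each (rate 1.0), never in the disease corpus | the recoverable ground truth; df = links = 7 deterministically |
| decoy candidates | 5, linked to 1–3 scales at per-record rate 0.35 | survive exclusion but rank below the planted candidate |
| leaky candidates | 2, plus 2 dedicated disease records each | below the df threshold in the disease corpus (so not "known"), yet co-mentioned with the disease — they must be caught by the exclusion step, not the subtraction |
| known-therapy mention rate | 0.08 per record | ~1.3 therapy mentions per record |
| abstract-less rate | 0.05 | records lacking abstracts, for the filtering contract |

Scale-corpus records carry exactly one anchor scale, so a candidate's true
link count equals its configured link set — decoy link counts cannot drift
upward by chance. Ground truth (per-phrase df, edge weights, abstract-less
ids) is recorded *during* emission and never recomputed, which makes it a
valid independent oracle. What the generator does **not** emulate: real
syntactic variety, abbreviation usage (FMA vs Fugl-Meyer assessment), synonym
scatter, section structure, or MeSH indexing — so passing tests demonstrate
the pipeline's logic is correct, not that its recall on real PubMed text
matches any published figure. Corpus-scale counts from any particular
historical retrieval (tens of thousands of records, hundreds of thousands of
distinct NPs) are snapshot-dependent and are not reproduction targets; the
published term tables themselves ship as fixtures instead.

## Numerical and design notes

- **Determinism.** All randomness flows from one `random.Random(seed)`; the
  same configuration yields byte-identical JSONL. Ranking tie-breaks and edge
  ordering are total, so every output table is reproducible byte-for-byte.
- **Thresholds.** "More than five articles" is read strictly as `df ≥ 6`.
  Degenerate inputs: an empty corpus yields empty maps; `min_doc_freq < 1`,
  empty query groups, df > N, and non-disjoint scale/therapy sets are
  rejected with errors rather than silently repaired.
- **Structured abstracts** are concatenated in document order, single-space
  joined. Duplicate PMIDs within one file are an error; across fetch batches
  the first occurrence wins (logged).
- **E-utilities etiquette.** The fetcher throttles to 3 requests/s without an
  API key (10 with), retries transient failures, and is transport-injectable
  so the test suite never touches the network.
- **Fixtures.** The packaged reference tables preserve the published rows
  verbatim — including a duplicated "Rankin scale" row with two frequencies,
  a surface-form duplication in the source table — and are guarded by SHA-256
  checksums.

## Problem sizes used in the checks

The oracle-equivalence checks run 20 corpora of ≤ 50 records against
brute-force nested-loop scans; the recovery experiment runs the full pipeline
on 20 seeds of the default configuration (~530 records each, ~1.5 s total).
These sizes are the package's chosen verification scale: large enough that
every vocabulary phrase clears its threshold with high probability, small
enough that the oracles stay trivially auditable.

## Known limitations

- Suffix rules are a high-recall, low-precision classifier; the blacklist
  (and human review of borderline terms) carries the precision burden, as in
  any manual-curation workflow.
- Exclusion soundness is relative to the scanned corpus: a candidate with
  disease co-mentions only in records outside the given corpora will survive.
  Online per-candidate exclusion against full PubMed is possible via the
  fetcher but is not part of the offline contract.
- Exact canonical matching means abbreviations and inflectional variants are
  distinct terms; merging them would change df and the rankings.
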