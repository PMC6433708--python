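# triad-miner

Literature-based discovery of **therapy repositioning candidates** through
shared clinical assessment scales, for biomedical text-mining and clinical
informatics researchers.

## The idea

Swanson's ABC model finds hidden connections across disjoint bodies of
literature: a disease *A* and an intervention *C* may never be mentioned
together, yet both co-occur with the same intermediate terms *B*. Here the
*B* terms are clinical assessment scales (Fugl-Meyer assessment, action
research arm test, …): therapies aimed at the same functional outcome are
evaluated on the same scales regardless of the condition they were developed
for, so a therapy that shares a disease's outcome instruments — but has never
been studied in that disease — is a repositioning hypothesis.

The pipeline, given a disease-anchored corpus and a scale-anchored corpus of
bibliographic records (PMID, title, abstract):

1. **Phrase mining** — shallow noun-phrase chunking over a coarse POS stream
   (`DET? (ADJ|NOUN)* NOUN`, maximal spans), canonical normalization, and
   per-phrase statistics: document frequency *df* (number of distinct records
   containing the phrase) and a corpus-level TF-IDF score
   `tfidf(p) = Σ_d tf(p,d) · ln(N / df(p))`.
2. **Suffix classification** — phrases ending in *test / scale / assessment /
   measure / score / index* are scale candidates; phrases ending in
   *training / therapy / treatment / treatments / practice / program /
   practise / simulation* are therapy candidates. Terms are kept at
   `df ≥ 6` (appearing in more than five articles) and filtered by editable
   blacklists that emulate expert manual review.
3. **ABC discovery** — scales mined from the disease corpus (B set) are linked
   to therapies mined from the scale-anchored corpus by document co-occurrence
   (binary per record, title+abstract scope). Therapies already known for the
   disease are subtracted; candidates that co-occur with a disease keyword in
   any record are excluded; survivors are ranked by number of linked scales,
   then document frequency, then lexicographically.

A synthetic-corpus generator produces corpora with controlled ABC structure —
including one *planted* candidate that co-occurs with 7 scales but never with
the disease — and emits generation-time ground truth, so the whole pipeline is
testable offline. The published reference tables (26 stroke scales, 47 known
stroke therapies, 5 repositioning candidates) ship as checksummed fixtures.

## Worked example

```bash
triad-miner simulate --seed 1 --out-dir sim/
triad-miner discover \
    --disease-corpus sim/disease.jsonl --scale-corpus sim/scale.jsonl \
    --disease-term stroke --disease-term "cerebral infarction" \
    --disease-term "brain ischemia" \
    --out-dir run/
```

prints

```
204 disease / 327 scale records → sim
top candidate: hand arm bimanual intensive training (7 linked scales)
```

and `run/candidates_ranked.tsv` begins

```
rank  phrase                                n_links  doc_freq
1     hand arm bimanual intensive training  7        7
2     music training                        3        38
3     relaxation practice                   2        22
```

The planted candidate is ranked first: it shares documents with 7 distinct
assessment scales (its `linked_scales` column lists them) while the decoy
candidates link at most 3, and the "leaky" candidates — therapies that do
co-occur with the disease — have been excluded. `run/` also contains the
scale/therapy term tables, the edge list, the scales × therapies interaction
matrix with marginals, and a `manifest.json` for reproducibility.

The same operations are available as a library:

```python
from triad_miner import generate_corpus, default_config, run_discovery

cfg = default_config(seed=1)
disease, scale, truth = generate_corpus(cfg)
result, tables = run_discovery(disease, scale, cfg.disease_terms)
print(result.candidates[0].phrase)   # hand arm bimanual intensive training
```

Real corpora can be read from MEDLINE tagged text, PubMed XML or JSONL
(`triad-miner convert`), or fetched live from PubMed E-utilities
(`triad-miner fetch`, online only; everything downstream is offline).

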