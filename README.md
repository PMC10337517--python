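# famhist

Rule-based extraction of **family history (FH)** information from clinical
notes, driven by a corpus-derived semantic lexicon.

Family history — which blood relatives had which conditions, whether they
are alive, at what age events occurred — is one of the strongest readily
documented risk signals in a patient record, yet it is usually buried in
free text. `famhist` is a small, fully deterministic toolkit for clinical
NLP researchers and health-informatics engineers that:

* models an **FH lexicon**: surface *variants* (including raw EHR typos such
  as `typediabetes`) mapped to UMLS concept unique identifiers (CUIs),
  optional SNOMED-CT codes and UMLS semantic types, restricted to the eleven
  disorder/finding types admissible as family-history concepts (T019, T020,
  T033, T037, T046, T047, T048, T049, T184, T190, T191 — never T050);
* **builds** such a lexicon from a raw corpus through pluggable
  mention-source and normalizer adapters, semantic-type screening, a
  replayable manual-curation queue for frequent unnormalizable mentions
  (≥ 20 distinct patients by default), and variant enrichment;
* **extracts** the four FH entity types — family members (with side of
  family and degree of consanguinity), lexicon observations, living status,
  ages — plus binary certainty (negated / nonnegated), and links them into
  relations by clause co-occurrence or by coreference across at most three
  adjacent sentences, excluding spouses and in-laws;
* **scores** predictions challenge-style (entity task 1, relation task 2
  with/without certainty; precision, recall, F1 with maximum one-to-one
  matching) and evaluates **lexicon coverage** at variant and concept level,
  where variant-level recall is TP/(TP+FN) over partially matched entity
  surfaces;
* **simulates** FH-style notes with a self-annotating gold standard and a
  synthetic mini-lexicon, so the whole pipeline is testable without
  access-restricted clinical corpora.

Real lexicon content (UMLS/SNOMED-CT) is license-restricted and is *not*
shipped; any lexicon in the documented 5-column TSV dialect
(`variant  cui  snomed_code  preferred_term  semantic_type_code`) can be
dropped in, with SNOMED codes supplied through a separate 2-column mapping
file.

## Worked example

```python
from famhist import Document, extract_document
from famhist.lexicon import loads_lexicon

lex = loads_lexicon(
    "diabetes\tC0011854\t73211009\tDiabetes mellitus\tT047\n"
    "colon cancer\tC0007102\t\tColon cancer\tT191\n"
    "asthma\tC0004096\t\tAsthma\tT047\n")

note = Document("note-001", """FAMILY HISTORY:
Mother has diabetes. Father is deceased. He had colon cancer.
No family history of asthma. Her husband has asthma.
""")

for r in extract_document(note, lex).relations:
    print((r.fm_category, r.fm_side, r.target_kind, r.target_text,
           r.certainty, r.provenance))
```

prints

```
('Mother', 'NA', 'observation', 'diabetes', 'nonnegated', 'same_clause')
('Father', 'NA', 'living_status', 'Dead', 'nonnegated', 'same_clause')
('Father', 'NA', 'observation', 'colon cancer', 'nonnegated', 'coreference')
```

Reading: the mother–diabetes link comes from co-occurrence inside one
clause; the father's colon cancer is attached across a sentence boundary
because "He" is a coreference cue within the three-sentence window; the
negated asthma statement produces an observation entity but no relation
(there is no family member in its clause); and the husband's asthma is
recorded as an entity but never becomes a family-history relation — spouses
are not blood relatives. Chains (`result.chains`) aggregate everything per
family member and serialize to FHIR-style `FamilyMemberHistory` JSON
(`famhist.io_out.write_fhir`), e.g. the father's chain carries
`"deceased": true` and both conditions.

## Command line

```bash
famhist simulate --out sim --n-docs 200 --seed 1
famhist extract  --lexicon sim/mini_lexicon.tsv --notes sim/notes --out run
famhist evaluate --gold-entities sim/gold_entities.tsv \
                 --gold-relations sim/gold_relations.tsv \
                 --pred-entities run/pred_entities.tsv \
                 --pred-relations run/pred_relations.tsv --with-certainty
famhist build-lexicon --corpus segments.tsv \
                 --reference-lexicon sim/mini_lexicon.tsv --out built.tsv
```

`extract` writes entity CSV (`file_name, sentence_id, chunk_id, entity_type,
concept, certainty`), relation CSV (`file_name, family_member,
side_of_family, observation_text, certainty`), gold-format prediction TSVs,
and optionally FHIR-style JSON validated against the schema in
`src/famhist/data/`.

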