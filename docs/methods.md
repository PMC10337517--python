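# Methods

## The extraction model

`famhist` treats family-history extraction as a dictionary-and-rules
problem over a segmented note.

**Segmentation.** The family-history section is located by a
case-insensitive header match (defaults: `FAMILY HISTORY`, `FAMILY HX`,
`FH`, each followed by a colon at the start of a line) and runs to the next
all-caps `NAME:` header; if no header matches, the whole document is used
and flagged as a fallback. Sentences split deterministically on `. ! ?` and
newline, with a guard list for abbreviations (`Dr.`, `vs.`, `y.o.`, …) that
also covers their internal dots, and a guard for decimal numbers. All
coordinates are 0-based half-open character intervals into the document;
sentence and clause identifiers are 0-based, which fixes the output format
byte-for-byte across runs.

**Clauses.** Clinical FH statements frequently pack several observations
onto one relative ("Mother has diabetes and hypertension") while also
packing several relatives into one sentence ("Mother has diabetes; father
has asthma"). The clause rule splits at semicolons always, and at a comma
or `" and "` only when a family-member mention *starts after* the
delimiter. This keeps observation lists attached to a single relative in
one clause while separating genuinely independent assertions. Clause spans
partition the sentence exactly (property-tested).

**Entities.**

* *Observations* are found by a leftmost-longest dictionary matcher over
  the lexicon. Both the sentence and every variant are reduced to a match
  key — lowercase alphanumeric tokens joined by single spaces — so case and
  hyphenation never block a hit while token boundaries are strictly
  respected (`cancer` never fires inside `cancerous`). When a longer
  variant covers a shorter one, only the longer match is emitted. An
  ambiguous variant emits all its CUIs, the lexicographically first marked
  primary — an arbitrary but deterministic tie-break. The matcher is
  verified against an exhaustive enumerate-all-substrings oracle.
* *Family members* are matched from an editable rule table (term, category,
  side, degree). Degrees follow the standard genetic-counseling
  aggregation: degree 1 parents/siblings/children, degree 2
  grandparents/aunts/uncles (and half-siblings, mapped to Sibling), degree
  3 cousins and great-grandparents. Side of family comes from
  maternal/paternal modifiers or from possessive constructions
  ("mother's brother" → Uncle, Maternal, elevated one generation).
  Spouse and in-law terms are recognized but flagged: they carry no
  category or degree and never participate in relations. Niece/nephew fall
  outside the 15-category challenge convention and are dropped by default;
  `map_extended=True` maps them to Child (degree 2) for users who prefer
  lossy capture over omission.
* *Living status* uses cue tables ({alive, living, well, healthy} → Alive;
  {deceased, dead, died, passed away, death, expired} → Dead; {unknown} →
  Unknown), one mention per status per sentence, with a `healthy` qualifier
  on Alive mentions when a health cue co-occurs.
* *Ages* match "at (the) age (of) N", "N years old", "N y.o.", "aged N"
  and decade forms "in his/her N0s" (kind `decade`, value N0); values
  outside [0, 130] are rejected.

**Certainty.** A minimal NegEx-style scheme: an observation or living
status is `negated` iff a trigger from an editable list (`no`, `not`,
`denies`, `without`, `no family history of`, …) precedes it *within the
same clause* with no intervening conjunction reset (`but`, `however`).
Anything else is `nonnegated`. This is intentionally the smallest scheme
that covers leftward clause-scoped negation; double negation and
post-position negation are out of scope.

**Relations.** Within a clause, every non-spouse family member links to
every observation and living-status mention, certainty copied from the
target. Across sentences, a target with no same-clause family member may
link backward to the nearest preceding non-spouse family member within the
cue sentence plus two preceding sentences — and only when the target's
sentence carries a coreference cue (`he`, `she`, `his`, `her`, `they`,
`them`, `none of them`; configurable). "Three adjacent sentences" is read
as a window of span three (distance ≤ 2); only anaphora is supported, since
the cue list is pronominal. The plural-negative cue `none of them` links
the target to *all* family members in the window with certainty forced to
`negated`. A clause owned by any family member — spouse included — claims
its targets: a spouse's conditions are recorded as entities but are never
re-linked to an earlier relative by a stray pronoun. Relations group into
one chain per (category, side) per document, with duplicate targets merged
and ages attached from the sentences where the relative was mentioned.

## Lexicon and builder

The lexicon is a 5-column TSV (`variant, cui, snomed_code, preferred_term,
semantic_type_code`), UTF-8, LF, header optional. Variants are normalized
by case-folding and whitespace collapsing only — no stemming, because typo
variants harvested from real notes are first-class content. Exact
`(variant, cui)` duplicates collapse; a variant mapped to several CUIs is
kept under all of them. Eleven semantic types are admissible; T050
(experimental model of disease) is structurally excluded. SNOMED codes
live in a separate CUI→code mapping file because SNOMED-CT content cannot
be redistributed.

The builder pipeline is adapter-based. The mention source (in production a
fine-tuned NER model; here a dictionary-backed reference implementation and
a noisy variant that deterministically injects concatenation typos) feeds
patient-tagged segments; mentions deduplicate under the variant
normalization with frequency and distinct-patient counts. The normalizer
contract (mention → CUI candidates) is satisfied by a lexicon-backed
reference adapter and an explicit-table adapter. Screening drops candidates
with inadmissible semantic types; mentions left without candidates and
seen in ≥ 20 distinct patients (patient count, not raw frequency, is the
thresholded quantity) enter a curation queue whose decisions replay from a
TSV, making the manual step reproducible. Enrichment adds variants of
*existing* concepts from an external variant resource and never introduces
concepts. Every final entry carries provenance (`auto`, `manual`,
`enrichment`), and the builder report states the auto-normalized share to
two decimals.

## Evaluation

Entity scoring pools per document and entity type, then computes a maximum
one-to-one matching (augmenting paths, deterministic position ordering) —
greedy-by-position pairing is a special case, and the implementation is
tested against an exhaustive bipartite oracle. Family members require
category *and* side equality; observations under the default partial mode
match on any character overlap, falling back to concept equality when spans
are unavailable; exact mode requires identical spans. Relation scoring is
set-based after deduplication on (document, category, side, target kind,
normalized target[, certainty]). Micro-averages pool counts across types.

Coverage takes gold (text, concept) pairs: an entity is covered when its
text shares at least one token with some lexicon variant; misses split into
concept-present (a variant gap) and concept-absent entities. Variant-level
recall is TP/(TP+FN) over entities; concept-level recall credits
concept-present misses in both numerator and denominator, counting the
present group at the concept level and the absent group at the entity
level — the reading consistent with both published benchmark worked
examples.

## Synthetic corpus

The generator emulates the constructs the rules target, and nothing else:
plain FM–observation statements, observation lists, living status with
optional age, negated statements (with and without a family member),
cross-sentence coreference pairs with gender-consistent pronouns, and
spouse distractors. Default composition per statement: spouse 0.10,
negation 0.15, coreference 0.20, observation list 0.20, remainder plain
(living-status share 0.30 and age share 0.15 within plain statements);
2–5 statements per note, 200 notes, 20 concepts with up to 4 variants each
(including 0.2-probability concatenation typos). These defaults are a
plausible FH-section mix chosen once; the seed fixes the corpus
byte-for-byte. Mini-lexicon variants are globally unique across concepts,
so matches are unambiguous by construction.

Because templates are rule-covered, the extractor reproduces the gold
standard exactly (P = R = F1 = 1 for both tasks); this is the headline
self-consistency property and is what the acceptance script's synthetic F1
values certify. It shows internal coherence of rules, generator and
scorer — it does **not** estimate performance on real notes, which contain
section-header variation, list formatting, hedging, family-history content
outside the FH section, and coreference beyond pronouns. The
`adversarial` switch adds cataphora and distance-3 coreference, whose gold
relations the extractor misses by design (recall < 1, and cataphora can
also attach a wrong antecedent, lowering precision) — a deliberate check
that the evaluation machinery registers failure modes rather than
saturating.

## Numerical and design choices

* Ratios (variants/CUI, percentages, recalls) are reported rounded to two
  decimals (one for percentage points); an empty lexicon reports 0 with an
  explicit empty flag rather than raising.
* Ambiguity tie-break: lexicographic CUI order, chosen for determinism.
* Degenerate inputs: empty documents yield empty extractions; a header
  with an empty body yields an empty section; sentences made only of
  delimiters yield one clause covering themselves.
* The FHIR-style output is validated against a repo-local schema (subset:
  type/required/properties/items/enum) rather than a full FHIR profile;
  the shape follows `FamilyMemberHistory` with condition sub-entries.
* Problem sizes in tests and the acceptance script (200-document corpora,
  1,000-sentence matcher sweeps, 500 scorer sets, 100-corpus orderings)
  were chosen to exercise the properties at comfortable margins while the
  whole suite stays fast enough to run on every commit.

## Known limitations

* No statistical NER or learned coreference; recall on real notes is
  bounded by the lexicon and the pronoun cue list.
* Negation is clause-scoped and leftward only; "is not known to be
  deceased"-style constructions are mis-scoped.
* One living-status mention per status per sentence; conflicting statuses
  in one sentence produce two mentions rather than a resolution.
* The possessive rule covers single-step possessives only ("mother's
  brother"), not chains ("mother's brother's wife").
* Coverage's token-overlap criterion is permissive (a single shared token
  counts); it is configurable but the default mirrors the partial-match
  convention.
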