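"""Lexicon construction pipeline: mention collection, normalization,
semantic-type screening, curation queue, enrichment and reporting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famhist.builder import (
    DictionaryMentionSource,
    LexiconNormalizer,
    NoisyMentionSource,
    NormalizationResult,
    RawMention,
    TableNormalizer,
    apply_curation_decisions,
    auto_normalized_percent,
    build_curation_queue,
    build_lexicon,
    collect_mentions,
    enrich_variants,
    load_curation_decisions,
    normalize_mentions,
    screen_semantic_types,
)
from famhist.lexicon import FH_ELIGIBLE_TYPES, Lexicon, LexiconEntry, SemanticType


def entry(variant, cui, stype="T047"):
    return LexiconEntry(variant, cui, "", variant, SemanticType(stype))


class TestCollect:
    def test_frequency_and_patient_counts(self, tiny_lexicon):
        source = DictionaryMentionSource(tiny_lexicon)
        corpus = [
            ("p1", "Mother has diabetes."),
            ("p1", "History of diabetes."),
            ("p2", "Sister has diabetes."),
            ("p3", "Diabetes and asthma."),
            ("p3", "Diabetes noted."),
        ]
        mentions = {m.text: m for m in collect_mentions(source, corpus)}
        assert mentions["diabetes"].frequency == 5
        assert mentions["diabetes"].n_patients == 3
        assert mentions["asthma"].n_patients == 1

    def test_empty_corpus(self, tiny_lexicon):
        assert collect_mentions(DictionaryMentionSource(tiny_lexicon), []) == []

    def test_case_variants_merge(self, tiny_lexicon):
        source = DictionaryMentionSource(tiny_lexicon)
        corpus = [("p1", "DIABETES."), ("p2", "diabetes.")]
        mentions = collect_mentions(source, corpus)
        assert len(mentions) == 1 and mentions[0].n_patients == 2

    def test_failing_adapter_skips_segment(self, tiny_lexicon):
        calls = []

        def flaky(text):
            calls.append(text)
            if "BAD" in text:
                raise RuntimeError("boom")
            return [("diabetes", 0, 8)]

        mentions = collect_mentions(flaky, [("p1", "BAD"), ("p2", "ok")])
        assert len(mentions) == 1 and mentions[0].n_patients == 1

    def test_n_patients_never_exceeds_frequency(self):
        with pytest.raises(ValueError):
            RawMention("x", frequency=1, n_patients=2)


class TestNormalize:
    def test_reference_adapter_resolves_known_variant(self, tiny_lexicon):
        results = normalize_mentions(
            LexiconNormalizer(tiny_lexicon), [RawMention("diabetes", 3, 2)])
        assert results[0].candidates[0][0] == "C0011854"

    def test_multi_candidate_mention(self):
        # a mention normalizing to two concepts, one later screened out
        table = TableNormalizer({
            "allergy-induced asthma": [
                ("C0440102", "Various patch test substance", "T130"),
                ("C0155877", "Allergic asthma", "T047"),
            ]})
        results = normalize_mentions(
            table, [RawMention("allergy-induced asthma", 5, 3)])
        cuis = [c[0] for c in results[0].candidates]
        assert cuis == ["C0440102", "C0155877"]

    def test_unknown_mention_empty_candidates(self, tiny_lexicon):
        results = normalize_mentions(
            LexiconNormalizer(tiny_lexicon), [RawMention("zzz", 1, 1)])
        assert results[0].candidates == [] and not results[0].failed

    def test_idempotent(self, tiny_lexicon):
        mentions = [RawMention("diabetes", 3, 2), RawMention("zzz", 1, 1)]
        adapter = LexiconNormalizer(tiny_lexicon)
        assert normalize_mentions(adapter, mentions) == normalize_mentions(
            adapter, mentions)


class TestScreening:
    def test_ineligible_candidate_removed(self):
        results = [NormalizationResult("allergy-induced asthma", [
            ("C0440102", "Various patch test substance", "T130", "auto"),
            ("C0155877", "Allergic asthma", "T047", "auto"),
        ])]
        screened = screen_semantic_types(results)
        assert [c[0] for c in screened[0].candidates] == ["C0155877"]

    def test_all_eligible_unchanged(self):
        results = [NormalizationResult("asthma", [
            ("C0004096", "Asthma", "T047", "auto")])]
        assert screen_semantic_types(results) == results

    def test_all_ineligible_empties_mention(self):
        results = [NormalizationResult("model", [
            ("C0012634", "Disease model", "T050", "auto")])]
        assert screen_semantic_types(results)[0].candidates == []

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(
        st.sampled_from(["T047", "T050", "T130", "T191", "T033", "T999"]),
        st.integers(0, 99)), max_size=6))
    def test_never_emits_ineligible_type(self, raw):
        results = [NormalizationResult("m", [
            (f"C{i:07d}", "x", stype, "auto") for stype, i in raw])]
        for r in screen_semantic_types(results):
            assert all(c[2] in FH_ELIGIBLE_TYPES for c in r.candidates)


class TestCurationQueue:
    def _mentions(self):
        return [
            RawMention("typediabetes", 3693, 25),
            RawMention("rare typo", 19, 19),
            RawMention("diabetes", 100, 50),
        ]

    def _results(self):
        return [
            NormalizationResult("typediabetes", []),
            NormalizationResult("rare typo", []),
            NormalizationResult("diabetes", [("C0011854", "Diabetes", "T047", "auto")]),
        ]

    def test_threshold_on_patient_count(self):
        queue = build_curation_queue(self._mentions(), self._results())
        assert [q.mention for q in queue] == ["typediabetes"]
        assert queue[0].n_patients == 25 and queue[0].frequency == 3693

    def test_threshold_boundary_nineteen_excluded(self):
        queue = build_curation_queue(self._mentions(), self._results(),
                                     min_patients=20)
        assert "rare typo" not in [q.mention for q in queue]

    def test_threshold_one_queues_every_unnormalized(self):
        queue = build_curation_queue(self._mentions(), self._results(),
                                     min_patients=1)
        assert {q.mention for q in queue} == {"typediabetes", "rare typo"}

    def test_decision_replay_maps_cui(self, tmp_path):
        decisions_file = tmp_path / "decisions.tsv"
        decisions_file.write_text(
            "mention\tcui\tstatus\ntypediabetes\tC0011854\tmapped\n")
        decisions = load_curation_decisions(decisions_file)
        queue = build_curation_queue(self._mentions(), self._results())
        resolved = apply_curation_decisions(queue, decisions)
        assert [(q.status, q.cui) for q in resolved] == [("mapped", "C0011854")]


class TestEnrichment:
    def test_variants_of_existing_concept_added(self):
        lex = Lexicon([entry("diabetes", "C0011854")])
        source = Lexicon([entry("diabetes mellitus", "C0011854")])
        out = enrich_variants(lex, source)
        assert {e.variant for e in out} == {"diabetes", "diabetes mellitus"}

    def test_new_concepts_never_introduced(self):
        lex = Lexicon([entry("diabetes", "C0011854")])
        source = Lexicon([entry("asthma", "C0004096"),
                          entry("diabetes type 2", "C0011854")])
        out = enrich_variants(lex, source)
        # set-algebra oracle: concepts(out) == concepts(lex)
        assert set(out.concept_index) == set(lex.concept_index)
        assert "diabetes type 2" in out.variant_index

    def test_empty_source_identity(self, tiny_lexicon):
        assert enrich_variants(tiny_lexicon, Lexicon()) == tiny_lexicon


class TestReport:
    def test_published_share_of_auto_normalized(self):
        # 47,250 of 72,518 unique mentions resolved automatically
        assert auto_normalized_percent(47250, 72518) == 65.16

    def test_zero_and_full(self):
        assert auto_normalized_percent(0, 10) == 0.0
        assert auto_normalized_percent(10, 10) == 100.0
        assert auto_normalized_percent(0, 0) == 0.0


class TestEndToEnd:
    def test_noisy_pipeline_curation_and_provenance(self, tiny_lexicon):
        # 25 patients each mention "colon cancer"; the noisy source mangles
        # it to "coloncancer", which the reference normalizer cannot resolve
        corpus = [(f"p{i}", "Mother has colon cancer.") for i in range(25)]
        source = NoisyMentionSource(tiny_lexicon, typo_rate=1.0, seed=1)
        outcome = build_lexicon(
            corpus, source, LexiconNormalizer(tiny_lexicon),
            decisions={"coloncancer": ("C0007102", "mapped")},
        )
        assert [q.mention for q in outcome.queue] == ["coloncancer"]
        assert ("coloncancer", "C0007102") in outcome.lexicon
        assert outcome.provenance[("coloncancer", "C0007102")] == "manual"

    def test_reference_pipeline_reproduces_planted_concepts(self, tiny_lexicon):
        from famhist.simulate import GenerationConfig, generate_corpus
        corpus = generate_corpus(GenerationConfig(n_documents=30, seed=11))
        segments = [(d.doc_id, d.text) for d in corpus.documents]
        outcome = build_lexicon(
            segments,
            DictionaryMentionSource(corpus.lexicon),
            LexiconNormalizer(corpus.lexicon),
        )
        planted = {e.label for e in corpus.gold_entities
                   if e.etype == "observation"}
        assert set(outcome.lexicon.concept_index) == planted
        # conservation: every entry traces to a recorded provenance
        for e in outcome.lexicon:
            assert (e.variant, e.cui) in outcome.provenance
        assert outcome.report.pct_auto_normalized == 100.0
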