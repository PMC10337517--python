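"""Entity recognition: dictionary matcher (with brute-force oracle),
family-member rules, certainty, living status, ages."""

import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famhist.entities import (
    NEGATED,
    NONNEGATED,
    ObservationMatcher,
    detect_certainty,
    extract_age,
    extract_living_status,
    match_key,
    match_observations,
    recognize_family_members,
)
from famhist.textprep import Sentence, split_clauses


def _sentence(text: str, sent_id: int = 0, offset: int = 0) -> Sentence:
    return Sentence(sent_id, (offset, offset + len(text)), text)


# ---------------------------------------------------------------------------
# observation matching
# ---------------------------------------------------------------------------

def brute_force_match(text: str, lexicon) -> list[tuple[int, int, str]]:
    """Independent oracle: enumerate every token-aligned substring, keep
    lexicon hits, then apply the leftmost-longest filter."""
    keys = {}
    for e in lexicon:
        keys.setdefault(match_key(e.variant), []).append(e.cui)
    tokens = list(re.finditer(r"[a-z0-9]+", text.casefold()))
    candidates = []
    for i in range(len(tokens)):
        for j in range(i + 1, len(tokens) + 1):
            key = " ".join(t.group(0) for t in tokens[i:j])
            if key in keys:
                candidates.append(
                    (tokens[i].start(), tokens[j - 1].end(), min(keys[key]))
                )
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    chosen, end = [], -1
    for s, e, cui in candidates:
        if s >= end:
            chosen.append((s, e, cui))
            end = e
    return chosen


class TestObservationMatching:
    def test_direct_hit(self, tiny_lexicon):
        hits = match_observations(_sentence("Her mother has diabetes."),
                                  tiny_lexicon)
        assert len(hits) == 1 and hits[0].cui == "C0011854"
        assert hits[0].certainty == NONNEGATED

    def test_leftmost_longest_beats_substring(self, tiny_lexicon):
        hits = match_observations(_sentence("She has colon cancer."),
                                  tiny_lexicon)
        assert [h.text for h in hits] == ["colon cancer"]
        assert hits[0].cui == "C0007102"

    def test_token_boundary_blocks_partial_word(self, tiny_lexicon):
        hits = match_observations(
            _sentence("A cancerous growth discussion."), tiny_lexicon)
        # "cancer" must not fire inside "cancerous"; "growth" still matches
        assert [h.text for h in hits] == ["growth"]

    def test_ambiguous_variant_emits_all_cuis_primary_first(self, tiny_lexicon):
        hits = match_observations(_sentence("A growth was noted."), tiny_lexicon)
        assert hits[0].cui == "C0018270"  # lexicographically first
        assert hits[0].alternatives == ("C0220844",)

    def test_case_and_hyphen_insensitive(self, tiny_lexicon):
        hits = match_observations(_sentence("ALLERGIC-ASTHMA suspected."),
                                  tiny_lexicon)
        assert hits[0].cui == "C0155877"

    def test_spans_index_into_document(self, tiny_lexicon):
        s = _sentence("Mother has asthma.", offset=50)
        hits = match_observations(s, tiny_lexicon)
        assert hits[0].span == (61, 67)

    def test_matches_brute_force_oracle_on_random_sentences(self, tiny_lexicon):
        vocab = ["the", "patient", "has", "no", "diabetes", "mellitus",
                 "colon", "cancer", "asthma", "allergic", "growth", "mi",
                 "hypertension", "typediabetes", "and", "also", "severe"]
        rng = random.Random(20)
        matcher = ObservationMatcher(tiny_lexicon)
        for _ in range(300):
            words = [rng.choice(vocab) for _ in range(rng.randint(1, 12))]
            text = " ".join(words) + "."
            got = [(h.span[0], h.span[1], h.cui)
                   for h in matcher.match(_sentence(text))]
            assert got == brute_force_match(text, tiny_lexicon), text


# ---------------------------------------------------------------------------
# family members
# ---------------------------------------------------------------------------

class TestFamilyMembers:
    @pytest.mark.parametrize("text,category,side,degree", [
        ("mother", "Mother", "NA", 1),
        ("Father", "Father", "NA", 1),
        ("maternal grandmother", "Grandmother", "Maternal", 2),
        ("paternal uncle", "Uncle", "Paternal", 2),
        ("cousins", "Cousin", "NA", 3),
        ("half brother", "Sibling", "NA", 2),
        ("great grandfather", "Grandfather", "NA", 3),
        ("mother's brother", "Uncle", "Maternal", 2),
        ("father's sister", "Aunt", "Paternal", 2),
        ("mother's mother", "Grandmother", "Maternal", 2),
    ])
    def test_category_side_degree(self, text, category, side, degree):
        fms = recognize_family_members(_sentence(f"Her {text} has asthma."))
        fms = [f for f in fms if not f.is_spouse_or_inlaw]
        assert len(fms) == 1
        fm = fms[0]
        assert (fm.category, fm.side, fm.degree) == (category, side, degree)

    @pytest.mark.parametrize("text", ["husband", "wife", "spouse",
                                      "mother-in-law", "brother in law"])
    def test_spouse_and_inlaw_flagged_without_category(self, text):
        fms = recognize_family_members(_sentence(f"Her {text} has asthma."))
        assert len(fms) == 1
        assert fms[0].is_spouse_or_inlaw
        assert fms[0].category is None and fms[0].degree is None

    def test_inlaw_not_read_as_blood_relative(self):
        fms = recognize_family_members(_sentence("Mother-in-law has cancer."))
        assert [f.is_spouse_or_inlaw for f in fms] == [True]

    def test_case_and_punctuation_invariant(self):
        for text in ("MOTHER has asthma.", "mother, has asthma.",
                     "(mother) has asthma."):
            fms = recognize_family_members(_sentence(text))
            assert [f.category for f in fms] == ["Mother"]

    def test_niece_dropped_by_default_mapped_when_extended(self):
        s = _sentence("Her niece has asthma.")
        assert recognize_family_members(s) == []
        extended = recognize_family_members(s, map_extended=True)
        assert [(f.category, f.degree) for f in extended] == [("Child", 2)]

    def test_plural_and_multiple_mentions(self):
        fms = recognize_family_members(
            _sentence("Her brothers and sister are well."))
        assert [f.category for f in fms] == ["Brother", "Sister"]


# ---------------------------------------------------------------------------
# certainty
# ---------------------------------------------------------------------------

def _one_clause(text: str):
    s = _sentence(text)
    return s, split_clauses(s, [])[0]


class TestCertainty:
    def test_trigger_in_clause_negates(self, tiny_lexicon):
        s, clause = _one_clause("No family history of cancer.")
        m = match_observations(s, tiny_lexicon)[0]
        assert detect_certainty(s.text, m.span, clause) == NEGATED

    def test_no_trigger_nonnegated(self, tiny_lexicon):
        s, clause = _one_clause("Mother has diabetes.")
        m = match_observations(s, tiny_lexicon)[0]
        assert detect_certainty(s.text, m.span, clause) == NONNEGATED

    def test_conjunction_resets_negation(self, tiny_lexicon):
        s, clause = _one_clause("Denies cancer but has diabetes.")
        cancer, diabetes = match_observations(s, tiny_lexicon)
        assert detect_certainty(s.text, cancer.span, clause) == NEGATED
        assert detect_certainty(s.text, diabetes.span, clause) == NONNEGATED

    def test_trigger_must_precede_in_same_clause(self, tiny_lexicon):
        s = _sentence("Mother has diabetes; no asthma.")
        clauses = split_clauses(s, [])
        diabetes, asthma = match_observations(s, tiny_lexicon)
        assert detect_certainty(s.text, diabetes.span, clauses[0]) == NONNEGATED
        assert detect_certainty(s.text, asthma.span, clauses[1]) == NEGATED

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from(
        ["mother", "has", "had", "history", "of", "also", "the"]),
        min_size=1, max_size=8))
    def test_never_negated_without_trigger(self, words):
        text = " ".join(words) + " diabetes."
        s, clause = _one_clause(text)
        span = (len(text) - len("diabetes."), len(text) - 1)
        assert detect_certainty(s.text, span, clause) == NONNEGATED


# ---------------------------------------------------------------------------
# living status and age
# ---------------------------------------------------------------------------

class TestLivingStatus:
    def test_deceased(self):
        out = extract_living_status(_sentence("Father is deceased."))
        assert [(m.status, m.healthy) for m in out] == [("Dead", None)]

    def test_alive_and_well_sets_healthy(self):
        out = extract_living_status(_sentence("Mother is alive and well."))
        assert [(m.status, m.healthy) for m in out] == [("Alive", True)]

    def test_no_cues_empty(self):
        assert extract_living_status(_sentence("Mother has asthma.")) == []

    def test_unknown_hedge(self):
        out = extract_living_status(_sentence("Status of father unknown."))
        assert [m.status for m in out] == ["Unknown"]

    def test_passed_away_multiword_cue(self):
        out = extract_living_status(_sentence("Grandmother passed away."))
        assert [m.status for m in out] == ["Dead"]


class TestAge:
    @pytest.mark.parametrize("text,value,kind", [
        ("died of MI at age 62.", 62, "exact"),
        ("at the age of 45", 45, "exact"),
        ("she is 62 years old", 62, "exact"),
        ("a 62-year-old woman", 62, "exact"),
        ("patient 30 y.o. today", 30, "exact"),
        ("aged 77 at diagnosis", 77, "exact"),
        ("in his 50s", 50, "decade"),
        ("in her 40's", 40, "decade"),
    ])
    def test_patterns(self, text, value, kind):
        out = extract_age(_sentence(text))
        assert [(a.value, a.kind) for a in out] == [(value, kind)]

    @pytest.mark.parametrize("text", [
        "Route 66 closed.",          # bare numeral, no age pattern
        "at age 205",                # outside [0, 130]
        "lived on 50s street",       # no pronoun before decade
    ])
    def test_non_ages_rejected(self, text):
        assert extract_age(_sentence(text)) == []

    def test_span_offsets(self):
        out = extract_age(_sentence("died at age 62.", offset=10))
        assert out[0].span[0] >= 10 and out[0].value == 62
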