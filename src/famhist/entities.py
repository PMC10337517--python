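"""Recognition and normalization of the four family-history entity types.

* family members — rule-table matching with side-of-family and degree of
  consanguinity; spouse/in-law mentions are recorded but flagged for
  exclusion from relations,
* observations — leftmost-longest, token-boundary dictionary matching against
  the semantic lexicon,
* living status — cue tables for alive/dead/unknown with a health qualifier,
* ages — pattern matching for exact ages and decades,

plus binary certainty (negated / nonnegated) assignment with a minimal
NegEx-style trigger scheme scoped to the clause.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .lexicon import Lexicon, LexiconEntry
from .textprep import Clause, Sentence, Span

NEGATED = "negated"
NONNEGATED = "nonnegated"

#: Challenge-convention family-member categories.
FM_CATEGORIES = (
    "Father", "Mother", "Parent", "Sister", "Brother", "Sibling",
    "Grandfather", "Grandmother", "Grandparent", "Son", "Daughter", "Child",
    "Aunt", "Uncle", "Cousin",
)

_SPOUSE_TERMS = ("husband", "wife", "spouse", "widow", "widower", "partner")

#: Conjunctions that reset negation scope within a clause.
NEGATION_RESETS = ("but", "however", "although", "though")


# ---------------------------------------------------------------------------
# mention types
# ---------------------------------------------------------------------------

@dataclass
class FamilyMemberMention:
    doc_id: str
    sent_id: int
    span: Span
    text: str
    category: Optional[str]  # None for spouse/in-law mentions
    side: str  # Maternal | Paternal | NA
    degree: Optional[int]  # 1, 2 or 3; None for spouse/in-law
    is_spouse_or_inlaw: bool = False

    def __post_init__(self) -> None:
        if self.is_spouse_or_inlaw:
            if self.category is not None or self.degree is not None:
                raise ValueError("spouse/in-law mentions carry no category/degree")
        elif self.category not in FM_CATEGORIES:
            raise ValueError(f"unknown FM category {self.category!r}")


@dataclass
class ObservationMention:
    doc_id: str
    sent_id: int
    span: Span
    text: str
    cui: str
    snomed_code: str = ""
    certainty: str = NONNEGATED
    chunk_id: int = 0
    alternatives: tuple[str, ...] = ()  # other CUIs of an ambiguous variant


@dataclass
class LivingStatusMention:
    doc_id: str
    sent_id: int
    span: Span
    status: str  # Alive | Dead | Unknown
    healthy: Optional[bool] = None
    certainty: str = NONNEGATED
    chunk_id: int = 0


@dataclass
class AgeMention:
    doc_id: str
    sent_id: int
    span: Span
    value: int
    kind: str  # exact | decade

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 130:
            raise ValueError(f"age {self.value} outside [0, 130]")


# ---------------------------------------------------------------------------
# family-member rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FMRule:
    term: str
    category: str
    side: str
    degree: int


def load_fm_rules(path: Optional[Union[str, Path]] = None) -> dict[str, FMRule]:
    """Read the consanguinity rule table (term, category, side, degree TSV).

    Defaults to the table shipped with the package: degree 1 for the nuclear
    family, degree 2 for grandparents/aunts/uncles, degree 3 for cousins.
    """
    if path is None:
        text = (
            resources.files("famhist").joinpath("data/fm_rules.tsv").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    rules: dict[str, FMRule] = {}
    for lineno, line in enumerate(text.splitlines()):
        if not line.strip() or (lineno == 0 and line.startswith("term\t")):
            continue
        term, category, side, degree = line.split("\t")
        rules[term.casefold()] = FMRule(term.casefold(), category, side, int(degree))
    return rules


_DEFAULT_FM_RULES = load_fm_rules()

# possessive elevation: "mother's brother" names a maternal uncle
_POSSESSIVE_HEAD_SIDE = {"mother": "Maternal", "father": "Paternal"}
_POSSESSIVE_ELEVATION = {
    "mother": "Grandmother",
    "father": "Grandfather",
    "brother": "Uncle",
    "sister": "Aunt",
    "son": "Child",       # nephew/niece by blood-line possessive is rare; keep nearest
    "daughter": "Child",
}


def recognize_family_members(
    sentence: Sentence,
    doc_id: str = "",
    fm_rules: Optional[dict[str, FMRule]] = None,
    map_extended: bool = False,
) -> list[FamilyMemberMention]:
    """Match family-member trigger terms in a sentence.

    Handles plurals, side modifiers ("maternal grandmother"), possessives
    ("mother's brother" → maternal Uncle), half-siblings (degree 2),
    great-grandparents (degree 3) and spouse/in-law terms (flagged, no
    category).  Niece/nephew are outside the challenge category set and are
    dropped unless ``map_extended`` maps them to Child (degree 2).
    Matching is case-insensitive and leftmost-longest.
    """
    rules = fm_rules if fm_rules is not None else _DEFAULT_FM_RULES
    text = sentence.text
    low = text.casefold()
    base = sentence.span[0]
    candidates: list[tuple[Span, FamilyMemberMention]] = []

    def add(m_start: int, m_end: int, mention: FamilyMemberMention) -> None:
        candidates.append(((m_start, m_end), mention))

    def doc_span(m: re.Match) -> Span:
        return (base + m.start(), base + m.end())

    # in-law compounds and spouse terms: flagged, excluded from relations
    inlaw_re = re.compile(
        r"\b(mother|father|brother|sister|son|daughter)s?[ -]in[ -]laws?\b"
    )
    for m in inlaw_re.finditer(low):
        s = doc_span(m)
        add(s[0], s[1], FamilyMemberMention(
            doc_id, sentence.sent_id, s, text[m.start():m.end()],
            None, "NA", None, is_spouse_or_inlaw=True))
    spouse_re = re.compile(r"\b(" + "|".join(_SPOUSE_TERMS) + r")s?\b")
    for m in spouse_re.finditer(low):
        s = doc_span(m)
        add(s[0], s[1], FamilyMemberMention(
            doc_id, sentence.sent_id, s, text[m.start():m.end()],
            None, "NA", None, is_spouse_or_inlaw=True))

    # possessive: (mother|father)'s <relative>
    poss_re = re.compile(
        r"\b(mother|father)’?'?s\s+(mother|father|brother|sister|son|daughter)s?\b"
    )
    for m in poss_re.finditer(low):
        head, rel = m.group(1), m.group(2)
        category = _POSSESSIVE_ELEVATION[rel]
        degree = 2 if category in ("Grandmother", "Grandfather", "Uncle", "Aunt") else 2
        s = doc_span(m)
        add(s[0], s[1], FamilyMemberMention(
            doc_id, sentence.sent_id, s, text[m.start():m.end()],
            category, _POSSESSIVE_HEAD_SIDE[head], degree))

    # great-grandparents: degree 3, side modifier optional
    gg_re = re.compile(
        r"\b(?:(maternal|paternal)[ -])?great[ -]?grand(mother|father|parent)s?\b"
    )
    for m in gg_re.finditer(low):
        side = (m.group(1) or "na").capitalize().replace("Na", "NA")
        category = {"mother": "Grandmother", "father": "Grandfather",
                    "parent": "Grandparent"}[m.group(2)]
        s = doc_span(m)
        add(s[0], s[1], FamilyMemberMention(
            doc_id, sentence.sent_id, s, text[m.start():m.end()],
            category, side, 3))

    # half-siblings: degree 2, Sibling category
    half_re = re.compile(r"\bhalf[ -]?(brother|sister|sibling)s?\b")
    for m in half_re.finditer(low):
        s = doc_span(m)
        add(s[0], s[1], FamilyMemberMention(
            doc_id, sentence.sent_id, s, text[m.start():m.end()],
            "Sibling", "NA", 2))

    # niece/nephew: outside the challenge set
    if map_extended:
        nn_re = re.compile(r"\b(niece|nephew)s?\b")
        for m in nn_re.finditer(low):
            s = doc_span(m)
            add(s[0], s[1], FamilyMemberMention(
                doc_id, sentence.sent_id, s, text[m.start():m.end()],
                "Child", "NA", 2))

    # plain rule-table terms with optional side modifier
    term_alt = "|".join(
        sorted((re.escape(t) for t in rules), key=len, reverse=True)
    )
    plain_re = re.compile(
        r"\b(?:(maternal|paternal)[ -])?(" + term_alt + r")s?\b"
    )
    for m in plain_re.finditer(low):
        rule = rules.get(m.group(2))
        if rule is None:
            continue
        side = m.group(1).capitalize() if m.group(1) else rule.side
        s = doc_span(m)
        add(s[0], s[1], FamilyMemberMention(
            doc_id, sentence.sent_id, s, text[m.start():m.end()],
            rule.category, side, rule.degree))

    # leftmost-longest resolution across all candidate patterns
    candidates.sort(key=lambda c: (c[0][0], -(c[0][1] - c[0][0])))
    chosen: list[FamilyMemberMention] = []
    occupied_end = -1
    for (s, e), mention in candidates:
        if s >= occupied_end:
            chosen.append(mention)
            occupied_end = e
    return chosen


# ---------------------------------------------------------------------------
# observation matching
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def match_key(text: str) -> str:
    """Canonical key for dictionary matching: lowercase, alphanumeric tokens
    joined by single spaces (so hyphens and case never block a hit)."""
    return " ".join(_TOKEN_RE.findall(text.casefold()))


class ObservationMatcher:
    """Leftmost-longest dictionary matcher over a lexicon.

    Matches respect token boundaries (``cancer`` never fires inside
    ``cancerous``); when a longer variant covers a shorter one, only the
    longer match is emitted; an ambiguous variant emits all its CUIs as
    alternatives with the lexicographically first CUI as primary.
    """

    def __init__(self, lexicon: Lexicon) -> None:
        self._index: dict[str, list[LexiconEntry]] = {}
        self.max_tokens = 1
        for entry in lexicon:
            key = match_key(entry.variant)
            if not key:
                continue
            self._index.setdefault(key, []).append(entry)
            self.max_tokens = max(self.max_tokens, key.count(" ") + 1)
        for entries in self._index.values():
            entries.sort(key=lambda e: e.cui)

    def match(self, sentence: Sentence, doc_id: str = "") -> list[ObservationMention]:
        low = sentence.text.casefold()
        tokens = list(_TOKEN_RE.finditer(low))
        base = sentence.span[0]
        out: list[ObservationMention] = []
        i = 0
        while i < len(tokens):
            hit: Optional[tuple[int, list[LexiconEntry]]] = None
            limit = min(len(tokens), i + self.max_tokens)
            for j in range(limit, i, -1):  # longest first
                key = " ".join(t.group(0) for t in tokens[i:j])
                entries = self._index.get(key)
                if entries:
                    hit = (j, entries)
                    break
            if hit is None:
                i += 1
                continue
            j, entries = hit
            start = base + tokens[i].start()
            end = base + tokens[j - 1].end()
            primary = entries[0]
            out.append(
                ObservationMention(
                    doc_id, sentence.sent_id, (start, end),
                    sentence.text[tokens[i].start():tokens[j - 1].end()],
                    primary.cui, primary.snomed_code,
                    alternatives=tuple(e.cui for e in entries[1:]),
                )
            )
            i = j  # suppress shorter matches inside the chosen span
        return out


def match_observations(
    sentence: Sentence, lexicon: Lexicon, doc_id: str = ""
) -> list[ObservationMention]:
    """Convenience wrapper building a fresh :class:`ObservationMatcher`."""
    return ObservationMatcher(lexicon).match(sentence, doc_id)


# ---------------------------------------------------------------------------
# certainty
# ---------------------------------------------------------------------------

def load_negation_triggers(path: Optional[Union[str, Path]] = None) -> tuple[str, ...]:
    """Negation trigger list, one phrase per line; defaults to the shipped
    minimal NegEx-style set ("no", "denies", "no family history of", ...)."""
    if path is None:
        text = (
            resources.files("famhist")
            .joinpath("data/negation_triggers.tsv")
            .read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    return tuple(line.strip().casefold() for line in text.splitlines() if line.strip())


_DEFAULT_TRIGGERS = load_negation_triggers()


def detect_certainty(
    doc_text: str,
    mention_span: Span,
    clause: Clause,
    triggers: Sequence[str] = _DEFAULT_TRIGGERS,
) -> str:
    """``negated`` iff a negation trigger precedes the mention within the
    same clause with no conjunction reset ("but", "however") in between."""
    c_start, c_end = clause.span
    m_start = mention_span[0]
    if not (c_start <= m_start < c_end):
        raise ValueError("mention does not lie in clause")
    window = doc_text[c_start:m_start].casefold()

    trigger_ends: list[int] = []
    for trig in sorted(triggers, key=len, reverse=True):
        for m in re.finditer(r"\b" + re.escape(trig) + r"\b", window):
            trigger_ends.append(m.end())
    if not trigger_ends:
        return NONNEGATED

    reset_re = re.compile(r"\b(" + "|".join(NEGATION_RESETS) + r")\b")
    for t_end in trigger_ends:
        if not reset_re.search(window, pos=t_end):
            return NEGATED
    return NONNEGATED


# ---------------------------------------------------------------------------
# living status and age
# ---------------------------------------------------------------------------

_ALIVE_CUES = ("alive", "living", "well", "healthy")
_DEAD_CUES = ("deceased", "dead", "died", "dies", "passed away", "death", "expired")
_UNKNOWN_CUES = ("unknown",)
_HEALTHY_CUES = ("healthy", "well", "good health")


def _find_cues(low: str, cues: Sequence[str]) -> list[re.Match]:
    hits: list[re.Match] = []
    for cue in sorted(cues, key=len, reverse=True):
        hits.extend(re.finditer(r"\b" + re.escape(cue) + r"\b", low))
    return sorted(hits, key=lambda m: m.start())


def extract_living_status(
    sentence: Sentence, doc_id: str = ""
) -> list[LivingStatusMention]:
    """Cue-table living-status detection.

    One mention per status present in the sentence (Dead, Alive, Unknown),
    anchored at the first cue of that status; the ``healthy`` flag is set on
    Alive mentions when a health cue co-occurs.
    """
    low = sentence.text.casefold()
    base = sentence.span[0]
    out: list[LivingStatusMention] = []
    healthy_present = bool(_find_cues(low, _HEALTHY_CUES))
    for status, cues in (("Dead", _DEAD_CUES), ("Alive", _ALIVE_CUES),
                         ("Unknown", _UNKNOWN_CUES)):
        hits = _find_cues(low, cues)
        if not hits:
            continue
        m = hits[0]
        out.append(
            LivingStatusMention(
                doc_id, sentence.sent_id, (base + m.start(), base + m.end()),
                status,
                healthy=healthy_present if status == "Alive" else None,
            )
        )
    return out


_AGE_PATTERNS: tuple[tuple[re.Pattern, str], ...] = (
    (re.compile(r"\bat\s+(?:the\s+)?age\s+(?:of\s+)?(\d{1,3})\b"), "exact"),
    (re.compile(r"\b(\d{1,3})[\s-]+years?[\s-]+old\b"), "exact"),
    (re.compile(r"\b(\d{1,3})\s*y\.?o\.?(?!\w)"), "exact"),
    (re.compile(r"\baged\s+(\d{1,3})\b"), "exact"),
    (re.compile(r"\bin\s+(?:his|her|their)\s+(\d{1,2})0'?s\b"), "decade"),
)


def extract_age(sentence: Sentence, doc_id: str = "") -> list[AgeMention]:
    """Pattern-based age extraction: "at age 62", "62 years old", "62 y.o.",
    "aged 62", and decades "in his 50s" (value 50, kind decade).  Values
    outside [0, 130] are rejected."""
    low = sentence.text.casefold()
    base = sentence.span[0]
    out: list[AgeMention] = []
    taken: list[Span] = []
    for pattern, kind in _AGE_PATTERNS:
        for m in pattern.finditer(low):
            span = (base + m.start(), base + m.end())
            if any(span[0] < t1 and t0 < span[1] for t0, t1 in taken):
                continue
            value = int(m.group(1)) * (10 if kind == "decade" else 1)
            if not 0 <= value <= 130:
                continue
            taken.append(span)
            out.append(AgeMention(doc_id, sentence.sent_id, span, value, kind))
    out.sort(key=lambda a: a.span)
    return out
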