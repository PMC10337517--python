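"""Document segmentation: family-history section, sentences, clauses, cues.

All coordinates are 0-based, half-open character intervals.  Sentence and
chunk (clause) identifiers are 0-based ordinals.  Segmentation is fully
deterministic so downstream entity/relation output is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

Span = tuple[int, int]

#: Section headers recognized as the start of the family-history section.
DEFAULT_FH_HEADERS = ("FAMILY HISTORY", "FAMILY HX", "FH")

#: Coreference cue defaults: the singular pronouns plus minimal plural
#: extension and the negative-plural cue.  Configurable; longest cue wins.
DEFAULT_CUE_SET = ("he", "she", "his", "her", "they", "them", "none of them")

#: Abbreviations that never terminate a sentence.
_ABBREVIATIONS = (
    "dr.", "mr.", "mrs.", "ms.", "vs.", "e.g.", "i.e.", "etc.", "y.o.", "yo.",
    "approx.", "no.", "st.",
)


@dataclass(frozen=True)
class Section:
    """A named region of a document, e.g. the FAMILY HISTORY section."""

    name: str
    span: Span
    fallback: bool = False  # true when no header matched and the whole
    # document is used

    def __post_init__(self) -> None:
        if self.span[0] > self.span[1]:
            raise ValueError(f"invalid section span {self.span}")


@dataclass(frozen=True)
class Sentence:
    sent_id: int
    span: Span  # offsets into the *document* text
    text: str


@dataclass(frozen=True)
class Clause:
    sent_id: int
    chunk_id: int
    span: Span  # offsets into the document text, within the sentence span


@dataclass(frozen=True)
class CoreferenceCue:
    cue: str
    span: Span  # offsets into the document text


@dataclass
class Document:
    doc_id: str
    text: str
    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


_HEADER_LINE_RE = re.compile(r"^[ \t]*([A-Z][A-Z /&-]{1,40})[ \t]*:", re.MULTILINE)


def find_family_history_section(
    document: Document, headers: Sequence[str] = DEFAULT_FH_HEADERS
) -> Section:
    """Locate the family-history section of a note.

    The section runs from the first matching header (case-insensitive, at the
    start of a line, followed by a colon) to the next all-caps ``NAME:``
    header line or the end of text.  When no header matches, the whole
    document is returned with the ``fallback`` flag set.
    """
    text = document.text
    pattern = re.compile(
        r"^[ \t]*(" + "|".join(re.escape(h) for h in headers) + r")[ \t]*:",
        re.IGNORECASE | re.MULTILINE,
    )
    m = pattern.search(text)
    if m is None:
        return Section("", (0, len(text)), fallback=True)
    start = m.end()
    nxt = _HEADER_LINE_RE.search(text, pos=start)
    end = nxt.start() if nxt else len(text)
    return Section(m.group(1).upper(), (start, end))


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True when the '.' at ``dot_pos`` lies inside a guarded abbreviation
    (covers internal dots too, e.g. the first dot of "y.o.")."""
    for abbr in _ABBREVIATIONS:
        for k, ch in enumerate(abbr):
            if ch != ".":
                continue
            start = dot_pos - k
            if start < 0:
                continue
            if text[start : start + len(abbr)].casefold() == abbr and (
                start == 0 or not text[start - 1].isalnum()
            ):
                return True
    return False


def segment_sentences(text: str, offset: int = 0) -> list[Sentence]:
    """Deterministic sentence split on ``. ! ? \\n`` with abbreviation guards.

    ``offset`` shifts spans so they index into an enclosing document.  Spans
    cover the trimmed sentence text; inter-sentence whitespace is not part of
    any sentence.
    """
    boundaries: list[int] = []  # index one past each sentence terminator
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            boundaries.append(i + 1)
        elif ch in "!?":
            boundaries.append(i + 1)
        elif ch == ".":
            # guard abbreviations and decimal/ordinal numbers like "3.5"
            nxt = text[i + 1] if i + 1 < n else ""
            if _is_abbreviation(text, i):
                pass
            elif nxt.isdigit() and i > 0 and text[i - 1].isdigit():
                pass
            else:
                boundaries.append(i + 1)
        i += 1
    boundaries.append(n)

    sentences: list[Sentence] = []
    prev = 0
    for b in boundaries:
        raw = text[prev:b]
        stripped = raw.strip()
        if stripped:
            start = prev + (len(raw) - len(raw.lstrip()))
            end = start + len(stripped)
            sentences.append(
                Sentence(len(sentences), (offset + start, offset + end), stripped)
            )
        prev = b
    return sentences


def split_clauses(
    sentence: Sentence, fm_spans: Sequence[Span] = ()
) -> list[Clause]:
    """Split a sentence into clauses for co-occurrence linking.

    Semicolons always split.  A comma or ``" and "`` splits only when a
    family-member mention starts *after* the delimiter — so an observation
    list attached to a single family member ("diabetes and hypertension")
    stays in one clause, while "mother has X and father has Y" splits.
    Clause spans partition the sentence span.
    """
    start, end = sentence.span
    text = sentence.text
    cut_points: list[int] = []  # document offsets where a new clause begins

    for m in re.finditer(r";", text):
        cut_points.append(start + m.end())
    for m in re.finditer(r",|\band\b", text):
        delim_end = start + m.end()
        if any(fs >= delim_end for fs, _ in fm_spans):
            cut_points.append(delim_end)

    cut_points = sorted(set(cut_points))
    clauses: list[Clause] = []
    prev = start
    for cp in cut_points:
        if prev < cp:
            clauses.append(Clause(sentence.sent_id, len(clauses), (prev, cp)))
            prev = cp
    if prev < end or not clauses:
        clauses.append(Clause(sentence.sent_id, len(clauses), (prev, end)))
    return clauses


def detect_coreference_cues(
    sentence: Sentence, cue_set: Iterable[str] = DEFAULT_CUE_SET
) -> list[CoreferenceCue]:
    """Case-insensitive whole-token cue matches; multi-word cues matched
    first so "none of them" yields one cue, not "them"."""
    cues = sorted(cue_set, key=len, reverse=True)
    found: list[CoreferenceCue] = []
    taken: list[Span] = []
    start, _ = sentence.span
    low = sentence.text.casefold()
    for cue in cues:
        pattern = re.compile(r"\b" + re.escape(cue.casefold()) + r"\b")
        for m in pattern.finditer(low):
            span = (start + m.start(), start + m.end())
            if any(span[0] < t1 and t0 < span[1] for t0, t1 in taken):
                continue
            taken.append(span)
            found.append(CoreferenceCue(cue.casefold(), span))
    found.sort(key=lambda c: c.span)
    return found
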