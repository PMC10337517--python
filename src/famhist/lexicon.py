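"""Family-history semantic lexicon: data model, TSV I/O, filtering and statistics.

The lexicon is the system's knowledge base: a dictionary of surface *variants*
(including raw EHR typos such as ``typediabetes``) mapped to UMLS concept
unique identifiers (CUIs), optional SNOMED-CT codes, preferred terms and UMLS
semantic types.  Only eleven disorder/finding semantic types are admissible as
family-history concepts; ``T050`` (experimental model of disease) is always
excluded.

File dialect: 5-column TSV ``variant  cui  snomed_code  preferred_term
semantic_type_code``, UTF-8, LF line endings, optional header row (detected by
a first field equal to ``variant``).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

logger = logging.getLogger(__name__)

#: The 11 UMLS semantic types admissible as family-history concepts
#: (disorder/finding group, excluding T050 "experimental model of disease").
FH_ELIGIBLE_TYPES: frozenset[str] = frozenset(
    {
        "T019",  # Congenital abnormality
        "T020",  # Acquired abnormality
        "T037",  # Injury or poisoning
        "T047",  # Disease or syndrome
        "T048",  # Mental or behavioral dysfunction
        "T049",  # Cell or molecular dysfunction
        "T190",  # Anatomical abnormality
        "T191",  # Neoplastic process
        "T033",  # Finding
        "T046",  # Pathologic function
        "T184",  # Sign or symptom
    }
)

SEMANTIC_TYPE_LABELS: dict[str, str] = {
    "T019": "Congenital abnormality",
    "T020": "Acquired abnormality",
    "T037": "Injury or poisoning",
    "T047": "Disease or syndrome",
    "T048": "Mental or behavioral dysfunction",
    "T049": "Cell or molecular dysfunction",
    "T190": "Anatomical abnormality",
    "T191": "Neoplastic process",
    "T033": "Finding",
    "T046": "Pathologic function",
    "T184": "Sign or symptom",
}

_CUI_RE = re.compile(r"^C[0-9]{7}$")
_STYPE_RE = re.compile(r"^T[0-9]{3}$")
_SNOMED_RE = re.compile(r"^[0-9]+$")

PathLike = Union[str, Path]


def normalize_variant(text: str) -> str:
    """Normalize a surface variant: case-fold, strip, collapse whitespace.

    Deliberately no stemming or spelling correction — EHR typo variants are
    first-class lexicon content.
    """
    return " ".join(text.casefold().split())


@dataclass(frozen=True)
class SemanticType:
    """A UMLS semantic type (``Txxx`` code plus human-readable label)."""

    code: str
    label: str = ""

    def __post_init__(self) -> None:
        if not _STYPE_RE.match(self.code):
            raise ValueError(f"invalid semantic type code: {self.code!r}")
        if not self.label:
            object.__setattr__(
                self, "label", SEMANTIC_TYPE_LABELS.get(self.code, "")
            )

    @property
    def fh_eligible(self) -> bool:
        return self.code in FH_ELIGIBLE_TYPES


@dataclass(frozen=True)
class LexiconEntry:
    """One variant→concept dictionary row.

    ``variant`` is stored normalized (case-folded, whitespace collapsed);
    ``snomed_code`` may be empty when no mapping file has been applied.
    """

    variant: str
    cui: str
    snomed_code: str
    preferred_term: str
    semantic_type: SemanticType

    def __post_init__(self) -> None:
        norm = normalize_variant(self.variant)
        if not norm:
            raise ValueError("variant empty after normalization")
        object.__setattr__(self, "variant", norm)
        if not _CUI_RE.match(self.cui):
            raise ValueError(f"invalid CUI: {self.cui!r}")
        if self.snomed_code and not _SNOMED_RE.match(self.snomed_code):
            raise ValueError(f"invalid SNOMED code: {self.snomed_code!r}")
        if not self.semantic_type.fh_eligible:
            raise ValueError(
                f"semantic type {self.semantic_type.code} is not FH-eligible"
            )


@dataclass
class LexiconStats:
    """Size statistics: distinct CUIs, entries, SNOMED codes, variants/CUI."""

    n_cuis: int
    n_variants: int
    n_snomed: int
    avg_variants_per_cui: float
    empty: bool = False

    @staticmethod
    def from_counts(n_cuis: int, n_variants: int, n_snomed: int = 0) -> "LexiconStats":
        """Compute the ratio statistic from externally supplied counts."""
        if n_cuis <= 0:
            return LexiconStats(0, n_variants, n_snomed, 0.0, empty=True)
        return LexiconStats(
            n_cuis, n_variants, n_snomed, round(n_variants / n_cuis, 2)
        )


class Lexicon:
    """A collection of :class:`LexiconEntry` with variant and concept indexes.

    ``variant_index`` maps each normalized variant to every entry sharing that
    surface form (a variant may be ambiguous across CUIs); ``concept_index``
    maps each CUI to its variants.  Exact duplicate ``(variant, cui)`` pairs
    collapse silently to one entry.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self._entries: dict[tuple[str, str], LexiconEntry] = {}
        self.variant_index: dict[str, list[LexiconEntry]] = {}
        self.concept_index: dict[str, list[str]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexiconEntry) -> None:
        key = (entry.variant, entry.cui)
        if key in self._entries:
            return
        self._entries[key] = entry
        self.variant_index.setdefault(entry.variant, []).append(entry)
        self.concept_index.setdefault(entry.cui, []).append(entry.variant)

    @property
    def entries(self) -> list[LexiconEntry]:
        return list(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return set(self._entries) == set(other._entries) and all(
            self._entries[k] == other._entries[k] for k in self._entries
        )

    def lookup(self, variant: str) -> list[LexiconEntry]:
        """Entries for a (raw or normalized) variant, sorted by CUI."""
        hits = self.variant_index.get(normalize_variant(variant), [])
        return sorted(hits, key=lambda e: e.cui)


_HEADER = ("variant", "cui", "snomed_code", "preferred_term", "semantic_type_code")


def _open_source(source: Union[PathLike, IO[str]]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def load_lexicon(source: Union[PathLike, IO[str]], strict: bool = False) -> Lexicon:
    """Read a lexicon TSV.

    Rows violating an invariant (bad CUI, ineligible semantic type, wrong
    column count ...) are skipped with a warning, or raise ``ValueError``
    naming the line number when ``strict`` is true.  A header row is detected
    by a first field equal to ``variant``.
    """
    stream, owned = _open_source(source)
    lex = Lexicon()
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().casefold() == "variant":
                continue
            try:
                if len(fields) != 5:
                    raise ValueError(
                        f"expected 5 tab-delimited fields, got {len(fields)}"
                    )
            except ValueError as exc:
                if strict:
                    raise ValueError(f"line {lineno}: {exc}") from None
                logger.warning("skipping line %d: %s", lineno, exc)
                continue
            variant, cui, snomed, pref, stype = (f.strip() for f in fields)
            try:
                lex.add(
                    LexiconEntry(variant, cui, snomed, pref, SemanticType(stype))
                )
            except ValueError as exc:
                if strict:
                    raise ValueError(f"line {lineno}: {exc}") from None
                logger.warning("skipping line %d: %s", lineno, exc)
    finally:
        if owned:
            stream.close()
    return lex


def write_lexicon(lexicon: Lexicon, sink: Union[PathLike, IO[str]]) -> None:
    """Write a lexicon as header + data rows; round-trips through
    :func:`load_lexicon` up to entry order."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="\n") as fh:
            write_lexicon(lexicon, fh)
        return
    sink.write("\t".join(_HEADER) + "\n")
    for e in lexicon:
        sink.write(
            "\t".join(
                (e.variant, e.cui, e.snomed_code, e.preferred_term, e.semantic_type.code)
            )
            + "\n"
        )


def filter_by_semantic_type(lexicon: Lexicon, allowed: Iterable[str]) -> Lexicon:
    """Keep exactly the entries whose semantic type code is in ``allowed``."""
    allowed_set = set(allowed)
    if not allowed_set:
        raise ValueError("allowed semantic type set must be non-empty")
    return Lexicon(e for e in lexicon if e.semantic_type.code in allowed_set)


def lexicon_stats(lexicon: Lexicon) -> LexiconStats:
    """Distinct CUIs, distinct (variant, cui) entries, distinct non-empty
    SNOMED codes, and the mean number of variants per CUI (2 decimals)."""
    n_cuis = len(lexicon.concept_index)
    n_variants = len(lexicon)
    n_snomed = len({e.snomed_code for e in lexicon if e.snomed_code})
    return LexiconStats.from_counts(n_cuis, n_variants, n_snomed)


def apply_snomed_mapping(
    lexicon: Lexicon, mapping: Mapping[str, str]
) -> Lexicon:
    """Fill in SNOMED codes from a CUI→code mapping.

    Entries with a mapped CUI gain the code; unmapped entries keep their
    current (possibly empty) code; no entry is added or removed.  The mapping
    is distributed separately because SNOMED-CT content is license-restricted.
    """
    out = Lexicon()
    for e in lexicon:
        code = mapping.get(e.cui, e.snomed_code)
        if code and not _SNOMED_RE.match(code):
            logger.warning("ignoring malformed SNOMED code %r for %s", code, e.cui)
            code = e.snomed_code
        out.add(
            LexiconEntry(e.variant, e.cui, code, e.preferred_term, e.semantic_type)
        )
    return out


def load_snomed_mapping(source: Union[PathLike, IO[str]]) -> dict[str, str]:
    """Read a 2-column (cui, snomed_code) TSV; malformed rows are skipped
    with a warning."""
    stream, owned = _open_source(source)
    mapping: dict[str, str] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not _CUI_RE.match(fields[0]) or not _SNOMED_RE.match(fields[1]):
                logger.warning("skipping malformed mapping row %d: %r", lineno, line)
                continue
            mapping[fields[0]] = fields[1]
    finally:
        if owned:
            stream.close()
    return mapping


def loads_lexicon(text: str, strict: bool = False) -> Lexicon:
    """Parse a lexicon from an in-memory TSV string."""
    return load_lexicon(io.StringIO(text), strict=strict)
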