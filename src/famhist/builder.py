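"""Corpus-driven lexicon construction.

The pipeline mirrors how a dictionary is grown from a raw clinical corpus:

1. a *mention source* proposes candidate family-history mention strings from
   patient-tagged text segments (in production a fine-tuned NER model; here a
   pluggable adapter contract with dictionary-backed reference and noisy
   implementations),
2. mentions are deduplicated with corpus frequency and distinct-patient
   counts,
3. a *normalizer* maps each mention to candidate concepts (CUI, preferred
   term, semantic type) — the adapter contract for a clinical-problem
   standardization service,
4. candidates are screened to the admissible disorder/finding semantic types,
5. frequent mentions that failed normalization (seen in at least 20 distinct
   patients by default) enter a manual curation queue whose decisions are
   replayed from a TSV,
6. the lexicon is enriched with additional variants of its existing concepts
   from an external variant resource; no new concepts are introduced.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Protocol, Sequence, Union

from .entities import ObservationMatcher
from .lexicon import (
    FH_ELIGIBLE_TYPES,
    Lexicon,
    LexiconEntry,
    LexiconStats,
    SemanticType,
    lexicon_stats,
    normalize_variant,
)
from .textprep import segment_sentences

logger = logging.getLogger(__name__)

DEFAULT_MIN_PATIENTS = 20


@dataclass
class RawMention:
    """A candidate mention aggregated over the corpus."""

    text: str
    frequency: int
    n_patients: int

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("mention text must be non-empty")
        if self.n_patients > self.frequency:
            raise ValueError("n_patients cannot exceed frequency")


Candidate = tuple[str, str, str]  # (cui, preferred_term, semantic_type_code)


@dataclass
class NormalizationResult:
    mention: str
    candidates: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (cui, preferred_term, semantic_type_code, source: auto|manual)
    failed: bool = False  # adapter error, distinct from "no candidates"


@dataclass
class CurationItem:
    mention: str
    n_patients: int
    frequency: int
    status: str = "pending"  # pending | mapped | rejected
    cui: str = ""


class MentionSourceAdapter(Protocol):
    """Contract: text segment -> candidate mention strings with positions."""

    def __call__(self, text: str) -> list[tuple[str, int, int]]: ...


class NormalizerAdapter(Protocol):
    """Contract: mention text -> candidate concepts; pure function."""

    def __call__(self, mention: str) -> list[Candidate]: ...


# ---------------------------------------------------------------------------
# shipped adapters
# ---------------------------------------------------------------------------

class DictionaryMentionSource:
    """Reference mention source: proposes spans the lexicon itself matches.

    Deterministic for a fixed corpus and lexicon, which makes the pipeline's
    conservation properties checkable end to end.
    """

    def __init__(self, lexicon: Lexicon) -> None:
        self._matcher = ObservationMatcher(lexicon)

    def __call__(self, text: str) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for sent in segment_sentences(text):
            for m in self._matcher.match(sent):
                out.append((m.text, m.span[0], m.span[1]))
        return out


class NoisyMentionSource:
    """Reference source plus deterministic typo injection.

    With the configured probability a proposed mention is replaced by a
    concatenation typo (internal spaces dropped, as in ``typediabetes``-style
    EHR artifacts), emulating the unnormalizable surface forms a model dredges
    from raw notes.
    """

    def __init__(self, lexicon: Lexicon, typo_rate: float = 0.3, seed: int = 0):
        self._inner = DictionaryMentionSource(lexicon)
        self.typo_rate = typo_rate
        self.seed = seed

    def __call__(self, text: str) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for mention, start, end in self._inner(text):
            rng = random.Random(f"{self.seed}:{mention}")  # per-surface determinism
            if " " in mention and rng.random() < self.typo_rate:
                mention = mention.replace(" ", "")
            out.append((mention, start, end))
        return out


class LexiconNormalizer:
    """Reference normalizer backed by a lexicon: exact-variant lookup."""

    def __init__(self, lexicon: Lexicon) -> None:
        self._lexicon = lexicon

    def __call__(self, mention: str) -> list[Candidate]:
        return [
            (e.cui, e.preferred_term, e.semantic_type.code)
            for e in self._lexicon.lookup(mention)
        ]


class TableNormalizer:
    """Normalizer backed by an explicit mention -> candidates table."""

    def __init__(self, table: dict[str, list[Candidate]]) -> None:
        self._table = {normalize_variant(k): v for k, v in table.items()}

    def __call__(self, mention: str) -> list[Candidate]:
        return list(self._table.get(normalize_variant(mention), []))


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def collect_mentions(
    adapter: MentionSourceAdapter,
    corpus: Iterable[tuple[str, str]],
) -> list[RawMention]:
    """Run the mention source over (patient_id, text) segments and aggregate.

    Mentions are deduplicated by normalized text; occurrence counts and
    distinct-patient counts are accumulated.  An adapter failure on a segment
    skips that segment with a warning.
    """
    freq: dict[str, int] = {}
    patients: dict[str, set[str]] = {}
    for patient_id, text in corpus:
        try:
            found = adapter(text)
        except Exception as exc:  # noqa: BLE001 — adapter contract boundary
            logger.warning("mention source failed on a segment of %s: %s",
                           patient_id, exc)
            continue
        for mention, _start, _end in found:
            key = normalize_variant(mention)
            if not key:
                continue
            freq[key] = freq.get(key, 0) + 1
            patients.setdefault(key, set()).add(patient_id)
    return [
        RawMention(text, freq[text], len(patients[text]))
        for text in sorted(freq, key=lambda t: (-freq[t], t))
    ]


def normalize_mentions(
    adapter: NormalizerAdapter,
    mentions: Sequence[RawMention],
) -> list[NormalizationResult]:
    """One result per mention, candidate order preserved from the adapter;
    an adapter error yields empty candidates with the ``failed`` flag."""
    results: list[NormalizationResult] = []
    for m in mentions:
        try:
            cands = adapter(m.text)
        except Exception as exc:  # noqa: BLE001
            logger.warning("normalizer failed on %r: %s", m.text, exc)
            results.append(NormalizationResult(m.text, [], failed=True))
            continue
        results.append(
            NormalizationResult(
                m.text, [(c[0], c[1], c[2], "auto") for c in cands]
            )
        )
    return results


def screen_semantic_types(
    results: Sequence[NormalizationResult],
    allowed: Iterable[str] = FH_ELIGIBLE_TYPES,
) -> list[NormalizationResult]:
    """Drop candidates whose semantic type is not admissible; mentions left
    with no candidates route to the curation queue."""
    allowed_set = set(allowed)
    screened: list[NormalizationResult] = []
    for r in results:
        kept = [c for c in r.candidates if c[2] in allowed_set]
        screened.append(NormalizationResult(r.mention, kept, failed=r.failed))
    return screened


def build_curation_queue(
    mentions: Sequence[RawMention],
    results: Sequence[NormalizationResult],
    min_patients: int = DEFAULT_MIN_PATIENTS,
) -> list[CurationItem]:
    """Queue unnormalized mentions seen across at least ``min_patients``
    distinct patients, most widespread first."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    by_mention = {r.mention: r for r in results}
    queue = [
        CurationItem(m.text, m.n_patients, m.frequency)
        for m in mentions
        if not by_mention.get(m.text, NormalizationResult(m.text)).candidates
        and m.n_patients >= min_patients
    ]
    queue.sort(key=lambda c: (-c.n_patients, c.mention))
    return queue


_DECISION_STATUSES = {"mapped", "rejected"}


def load_curation_decisions(
    source: Union[str, Path],
) -> dict[str, tuple[str, str]]:
    """Read a curation decision TSV (mention, cui, status)."""
    decisions: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(Path(source).read_text("utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("mention\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 3 or fields[2] not in _DECISION_STATUSES:
            logger.warning("skipping malformed decision row %d: %r", lineno, line)
            continue
        decisions[normalize_variant(fields[0])] = (fields[1], fields[2])
    return decisions


def apply_curation_decisions(
    queue: Sequence[CurationItem],
    decisions: dict[str, tuple[str, str]],
    concept_info: Optional[Callable[[str], Optional[Candidate]]] = None,
) -> list[CurationItem]:
    """Replay manual decisions onto the queue (idempotent).

    ``concept_info`` optionally resolves a CUI to (cui, preferred term,
    semantic type) so the curated entry carries full concept metadata.
    """
    resolved: list[CurationItem] = []
    for item in queue:
        decision = decisions.get(item.mention)
        if decision is None:
            resolved.append(item)
            continue
        cui, status = decision
        resolved.append(
            CurationItem(item.mention, item.n_patients, item.frequency,
                         status=status, cui=cui if status == "mapped" else "")
        )
    return resolved


def enrich_variants(lexicon: Lexicon, variant_source: Lexicon) -> Lexicon:
    """Add variants of *existing* concepts from an external clinical variant
    resource; concepts absent from the lexicon are never introduced."""
    out = Lexicon(lexicon.entries)
    for entry in variant_source:
        if entry.cui in lexicon.concept_index:
            out.add(entry)
    return out


# ---------------------------------------------------------------------------
# orchestration and report
# ---------------------------------------------------------------------------

@dataclass
class BuilderReport:
    n_mentions: int
    n_auto_normalized: int
    n_curated: int
    stats: LexiconStats

    @property
    def pct_auto_normalized(self) -> float:
        if self.n_mentions == 0:
            return 0.0
        return round(100.0 * self.n_auto_normalized / self.n_mentions, 2)

    def as_dict(self) -> dict:
        return {
            "n_mentions": self.n_mentions,
            "n_auto_normalized": self.n_auto_normalized,
            "pct_auto_normalized": self.pct_auto_normalized,
            "n_curated": self.n_curated,
            "n_cuis": self.stats.n_cuis,
            "n_variants": self.stats.n_variants,
            "n_snomed": self.stats.n_snomed,
            "avg_variants_per_cui": self.stats.avg_variants_per_cui,
        }


def auto_normalized_percent(n_auto: int, n_total: int) -> float:
    """Share of unique mentions the normalizer resolved, as a percentage
    reported to 2 decimals."""
    if n_total == 0:
        return 0.0
    return round(100.0 * n_auto / n_total, 2)


@dataclass
class BuildOutcome:
    lexicon: Lexicon
    report: BuilderReport
    mentions: list[RawMention]
    screened: list[NormalizationResult]
    queue: list[CurationItem]
    provenance: dict[tuple[str, str], str]  # (variant, cui) -> auto|manual|enrichment


def build_lexicon(
    corpus: Iterable[tuple[str, str]],
    mention_source: MentionSourceAdapter,
    normalizer: NormalizerAdapter,
    allowed_types: Iterable[str] = FH_ELIGIBLE_TYPES,
    min_patients: int = DEFAULT_MIN_PATIENTS,
    decisions: Optional[dict[str, tuple[str, str]]] = None,
    variant_source: Optional[Lexicon] = None,
    concept_info: Optional[Callable[[str], Optional[Candidate]]] = None,
) -> BuildOutcome:
    """Run the full construction pipeline and return the lexicon with a
    report and complete per-entry provenance."""
    mentions = collect_mentions(mention_source, corpus)
    results = normalize_mentions(normalizer, mentions)
    screened = screen_semantic_types(results, allowed_types)
    queue = build_curation_queue(mentions, screened, min_patients)
    if decisions:
        queue = apply_curation_decisions(queue, decisions, concept_info)

    lexicon = Lexicon()
    provenance: dict[tuple[str, str], str] = {}
    n_auto = 0
    for r in screened:
        if not r.candidates:
            continue
        n_auto += 1
        for cui, pref, stype, _source in r.candidates:
            entry = LexiconEntry(r.mention, cui, "", pref, SemanticType(stype))
            lexicon.add(entry)
            provenance.setdefault((entry.variant, cui), "auto")

    n_curated = 0
    for item in queue:
        if item.status != "mapped":
            continue
        info = concept_info(item.cui) if concept_info else None
        pref, stype = (info[1], info[2]) if info else ("", "T047")
        entry = LexiconEntry(item.mention, item.cui, "", pref, SemanticType(stype))
        lexicon.add(entry)
        provenance.setdefault((entry.variant, item.cui), "manual")
        n_curated += 1

    if variant_source is not None:
        enriched = enrich_variants(lexicon, variant_source)
        for e in enriched:
            provenance.setdefault((e.variant, e.cui), "enrichment")
        lexicon = enriched

    report = BuilderReport(
        n_mentions=len(mentions),
        n_auto_normalized=n_auto,
        n_curated=n_curated,
        stats=lexicon_stats(lexicon),
    )
    return BuildOutcome(lexicon, report, mentions, screened, queue, provenance)


def read_corpus_tsv(source: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a (patient_id, text) corpus TSV."""
    segments: list[tuple[str, str]] = []
    for line in Path(source).read_text("utf-8").splitlines():
        if not line.strip() or line.startswith("patient_id\t"):
            continue
        patient_id, _, text = line.partition("\t")
        segments.append((patient_id, text))
    return segments
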