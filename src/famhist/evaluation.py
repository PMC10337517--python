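"""Challenge-style scoring and lexicon-coverage evaluation.

Task 1 scores entities (family members with side of family, observations,
living status, ages); task 2 scores relations, optionally requiring the
certainty attribute to agree.  Coverage evaluates the lexicon itself against
gold entities: variant-level recall counts entities whose surface text
partially matches a lexicon variant, concept-level recall credits concepts
present in the lexicon even when the exact surface variant is missing.

Gold files are plain TSVs:

* entities: ``doc_id  type  category_or_cui  side  certainty  start  end``
* relations: ``doc_id  fm_category  side  target_kind  target  certainty``
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from .entities import NONNEGATED, match_key
from .lexicon import Lexicon
from .pipeline import ExtractionResult

_CUI_RE = re.compile(r"^C[0-9]{7}$")

ENTITY_TYPES = ("family_member", "observation", "living_status", "age")


@dataclass(frozen=True)
class GoldEntity:
    doc_id: str
    etype: str  # one of ENTITY_TYPES
    label: str  # FM category, observation CUI (or text), status, or age value
    side: str = "NA"
    certainty: str = NONNEGATED
    start: int = -1  # -1 when span unavailable
    end: int = -1
    text: str = ""  # surface text when available (used by coverage)


@dataclass(frozen=True)
class GoldRelation:
    doc_id: str
    fm_category: str
    side: str
    target_kind: str  # observation | living_status
    target: str  # CUI for observations, status for living status
    certainty: str = NONNEGATED


@dataclass
class ScoreReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": round(self.precision, 4),
            "recall": round(self.recall, 4),
            "f1": round(self.f1, 4),
        }


@dataclass
class CoverageReport:
    """Lexicon coverage counts and the two recall levels.

    ``fn_concepts_present`` counts *concepts* behind false-negative entities
    that the lexicon does contain (a variant gap, not a concept gap);
    ``fn_concepts_missing`` counts false-negative entities whose concept is
    absent from the lexicon entirely.
    """

    tp_entities: int
    fn_entities: int
    tp_concepts: int
    fn_concepts_present: int
    fn_concepts_missing: int

    @property
    def variant_recall(self) -> float:
        total = self.tp_entities + self.fn_entities
        return self.tp_entities / total if total else 0.0

    @property
    def concept_recall(self) -> float:
        covered = self.tp_concepts + self.fn_concepts_present
        total = covered + self.fn_concepts_missing
        return covered / total if total else 0.0

    def as_dict(self) -> dict:
        return {
            "tp_entities": self.tp_entities,
            "fn_entities": self.fn_entities,
            "tp_concepts": self.tp_concepts,
            "fn_concepts_present": self.fn_concepts_present,
            "fn_concepts_missing": self.fn_concepts_missing,
            "variant_recall": round(self.variant_recall, 4),
            "concept_recall": round(self.concept_recall, 4),
        }


# ---------------------------------------------------------------------------
# entity scoring
# ---------------------------------------------------------------------------

def _spans_overlap(a: GoldEntity, b: GoldEntity) -> bool:
    if a.start < 0 or b.start < 0:
        return False
    return a.start < b.end and b.start < a.end


def _entities_compatible(gold: GoldEntity, pred: GoldEntity, match_mode: str) -> bool:
    if gold.etype != pred.etype or gold.doc_id != pred.doc_id:
        return False
    if gold.etype == "family_member":
        return gold.label == pred.label and gold.side == pred.side
    if gold.etype == "observation":
        if match_mode == "exact":
            return (gold.start, gold.end) == (pred.start, pred.end) and (
                gold.label == pred.label
            )
        # partial: any character overlap, or concept equality without spans
        if gold.start >= 0 and pred.start >= 0:
            return _spans_overlap(gold, pred) or gold.label == pred.label
        return gold.label == pred.label
    # living_status / age: label equality
    return gold.label == pred.label


def _max_bipartite(
    gold: Sequence[GoldEntity],
    pred: Sequence[GoldEntity],
    match_mode: str,
) -> int:
    """Maximum one-to-one matching size (Kuhn's augmenting paths); iteration
    order by position keeps the pairing deterministic."""
    match_of_pred: dict[int, int] = {}

    def try_assign(gi: int, visited: set[int]) -> bool:
        for pi, p in enumerate(pred):
            if pi in visited or not _entities_compatible(gold[gi], p, match_mode):
                continue
            visited.add(pi)
            if pi not in match_of_pred or try_assign(match_of_pred[pi], visited):
                match_of_pred[pi] = gi
                return True
        return False

    for gi in range(len(gold)):
        try_assign(gi, set())
    return len(match_of_pred)


def score_entities(
    gold: Iterable[GoldEntity],
    pred: Iterable[GoldEntity],
    match_mode: str = "partial",
) -> dict[str, ScoreReport]:
    """Score predicted entities against gold, per type plus micro-average.

    Each gold item matches at most one prediction (maximum one-to-one
    pairing).  Family members require category and side equality; partial
    observation matching credits any character-span overlap, falling back to
    concept equality when spans are unavailable.
    """
    gold = list(gold)
    pred = list(pred)
    reports = {t: ScoreReport() for t in ENTITY_TYPES}
    buckets: dict[tuple[str, str], tuple[list[GoldEntity], list[GoldEntity]]] = {}
    for g in gold:
        buckets.setdefault((g.doc_id, g.etype), ([], []))[0].append(g)
    for p in pred:
        buckets.setdefault((p.doc_id, p.etype), ([], []))[1].append(p)
    for (_, etype), (gs, ps) in sorted(buckets.items()):
        gs.sort(key=lambda e: (e.start, e.label))
        ps.sort(key=lambda e: (e.start, e.label))
        tp = _max_bipartite(gs, ps, match_mode)
        rep = reports.setdefault(etype, ScoreReport())
        rep.tp += tp
        rep.fp += len(ps) - tp
        rep.fn += len(gs) - tp
    micro = ScoreReport(
        tp=sum(r.tp for r in reports.values()),
        fp=sum(r.fp for r in reports.values()),
        fn=sum(r.fn for r in reports.values()),
    )
    reports["micro"] = micro
    return reports


# ---------------------------------------------------------------------------
# relation scoring
# ---------------------------------------------------------------------------

def _relation_key(r: GoldRelation, with_certainty: bool) -> tuple:
    target = r.target if _CUI_RE.match(r.target) else r.target.casefold()
    base = (r.doc_id, r.fm_category, r.side, r.target_kind, target)
    return base + (r.certainty,) if with_certainty else base


def score_relations(
    gold: Iterable[GoldRelation],
    pred: Iterable[GoldRelation],
    with_certainty: bool = False,
) -> ScoreReport:
    """Set-based relation scoring after deduplication.

    A relation matches when family-member category, side of family and the
    normalized target agree; ``with_certainty`` additionally requires the
    negated/nonnegated attribute to agree.
    """
    gset = {_relation_key(r, with_certainty) for r in gold}
    pset = {_relation_key(r, with_certainty) for r in pred}
    tp = len(gset & pset)
    return ScoreReport(tp=tp, fp=len(pset) - tp, fn=len(gset) - tp)


# ---------------------------------------------------------------------------
# lexicon coverage
# ---------------------------------------------------------------------------

def coverage(
    gold_entities: Iterable[tuple[str, str]],
    lexicon: Lexicon,
    min_token_overlap: int = 1,
) -> CoverageReport:
    """Coverage of gold (text, concept) pairs by the lexicon.

    An entity is a true positive when its text shares at least
    ``min_token_overlap`` tokens with some lexicon variant (partial match).
    False negatives split by whether their concept exists in the lexicon
    under any variant.
    """
    variant_tokens: set[str] = set()
    for variant in lexicon.variant_index:
        variant_tokens.update(match_key(variant).split())

    tp_entities = 0
    fn_present_concepts: set[str] = set()
    fn_missing_entities = 0
    fn_entities = 0
    tp_concepts: set[str] = set()
    for text, concept in gold_entities:
        tokens = set(match_key(text).split())
        if len(tokens & variant_tokens) >= min_token_overlap:
            tp_entities += 1
            tp_concepts.add(concept)
        else:
            fn_entities += 1
            if concept in lexicon.concept_index:
                fn_present_concepts.add(concept)
            else:
                fn_missing_entities += 1
    return CoverageReport(
        tp_entities=tp_entities,
        fn_entities=fn_entities,
        tp_concepts=len(tp_concepts),
        fn_concepts_present=len(fn_present_concepts),
        fn_concepts_missing=fn_missing_entities,
    )


# ---------------------------------------------------------------------------
# adapters from extraction results, and TSV I/O
# ---------------------------------------------------------------------------

def entities_from_result(result: ExtractionResult) -> list[GoldEntity]:
    """Predicted entity set of an extraction, in gold-entity shape.

    Spouse/in-law family-member mentions are recorded by the extractor but
    are not family-history entities, so they are not emitted for scoring.
    """
    out: list[GoldEntity] = []
    for fm in result.family_members:
        if fm.is_spouse_or_inlaw:
            continue
        out.append(GoldEntity(result.doc_id, "family_member", fm.category,
                              fm.side, NONNEGATED, fm.span[0], fm.span[1],
                              fm.text))
    for ob in result.observations:
        out.append(GoldEntity(result.doc_id, "observation", ob.cui, "NA",
                              ob.certainty, ob.span[0], ob.span[1], ob.text))
    for ls in result.living_statuses:
        out.append(GoldEntity(result.doc_id, "living_status", ls.status, "NA",
                              ls.certainty, ls.span[0], ls.span[1]))
    for age in result.ages:
        out.append(GoldEntity(result.doc_id, "age", str(age.value), "NA",
                              NONNEGATED, age.span[0], age.span[1]))
    return out


def relations_from_result(result: ExtractionResult) -> list[GoldRelation]:
    return [
        GoldRelation(r.doc_id, r.fm_category, r.fm_side, r.target_kind,
                     r.target_cui or r.target_text, r.certainty)
        for r in result.relations
    ]


PathLike = Union[str, Path]


def write_gold_entities(entities: Iterable[GoldEntity], sink: Union[PathLike, IO[str]]) -> None:
    _write_tsv(
        sink,
        ("doc_id", "type", "category_or_cui", "side", "certainty", "start", "end"),
        ((e.doc_id, e.etype, e.label, e.side, e.certainty, str(e.start), str(e.end))
         for e in entities),
    )


def read_gold_entities(source: Union[PathLike, IO[str]]) -> list[GoldEntity]:
    rows = _read_tsv(source, 7)
    return [
        GoldEntity(r[0], r[1], r[2], r[3], r[4], int(r[5]), int(r[6]))
        for r in rows
    ]


def write_gold_relations(relations: Iterable[GoldRelation], sink: Union[PathLike, IO[str]]) -> None:
    _write_tsv(
        sink,
        ("doc_id", "fm_category", "side", "target_kind", "target", "certainty"),
        ((r.doc_id, r.fm_category, r.side, r.target_kind, r.target, r.certainty)
         for r in relations),
    )


def read_gold_relations(source: Union[PathLike, IO[str]]) -> list[GoldRelation]:
    rows = _read_tsv(source, 6)
    return [GoldRelation(*r) for r in rows]


def _write_tsv(sink, header: tuple[str, ...], rows: Iterable[tuple[str, ...]]) -> None:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="\n") as fh:
            _write_tsv(fh, header, rows)
        return
    sink.write("\t".join(header) + "\n")
    for row in rows:
        sink.write("\t".join(row) + "\n")


def _read_tsv(source, n_fields: int) -> list[tuple[str, ...]]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return _read_tsv(fh, n_fields)
    rows: list[tuple[str, ...]] = []
    for i, line in enumerate(source):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = tuple(line.split("\t"))
        if i == 0 and fields[0] == "doc_id":
            continue
        if len(fields) != n_fields:
            raise ValueError(f"line {i + 1}: expected {n_fields} fields")
        rows.append(fields)
    return rows


def report_to_json(reports: dict[str, ScoreReport]) -> str:
    return json.dumps({k: v.as_dict() for k, v in reports.items()}, indent=2)
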