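"""Output writers: entity/relation CSV and FHIR-style JSON.

CSV column orders are fixed contracts:

* entities: ``file_name, sentence_id, chunk_id, entity_type, concept,
  certainty``
* relations: ``file_name, family_member, side_of_family, observation_text,
  certainty``

The FHIR-style output emits one ``FamilyMemberHistory``-shaped JSON object
per family chain, validated against the schema shipped in
``data/fhir_family_history.schema.json``.  SNOMED codes appear only when the
separately distributed CUI→SNOMED mapping file has been applied (SNOMED-CT
content is license-restricted).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from .pipeline import ExtractionResult
from .relations import FamilyChain

PathLike = Union[str, Path]

ENTITY_COLUMNS = ("file_name", "sentence_id", "chunk_id", "entity_type",
                  "concept", "certainty")
RELATION_COLUMNS = ("file_name", "family_member", "side_of_family",
                    "observation_text", "certainty")


@dataclass(frozen=True)
class EntityRecord:
    file_name: str
    sentence_id: int
    chunk_id: int
    entity_type: str  # family_member | observation | living_status | age
    concept: str  # category, CUI (| SNOMED), status, or age value
    certainty: str

    def row(self) -> tuple[str, ...]:
        return (self.file_name, str(self.sentence_id), str(self.chunk_id),
                self.entity_type, self.concept, self.certainty)


@dataclass(frozen=True)
class RelationRecord:
    file_name: str
    family_member: str
    side_of_family: str
    observation_text: str
    certainty: str

    def row(self) -> tuple[str, ...]:
        return (self.file_name, self.family_member, self.side_of_family,
                self.observation_text, self.certainty)


def entity_records(
    result: ExtractionResult,
    snomed_mapping: Optional[Mapping[str, str]] = None,
) -> list[EntityRecord]:
    """Flatten an extraction into entity records.

    Observation concepts render as ``CUI`` or ``CUI|SNOMED`` when a mapping
    supplies a code.  Spouse/in-law mentions are not family-history entities
    and are omitted.
    """
    records: list[EntityRecord] = []
    fname = result.doc_id
    for fm in result.family_members:
        if fm.is_spouse_or_inlaw:
            continue
        records.append(EntityRecord(fname, fm.sent_id, 0, "family_member",
                                    fm.category, "nonnegated"))
    for ob in result.observations:
        concept = ob.cui
        snomed = (snomed_mapping or {}).get(ob.cui, ob.snomed_code)
        if snomed:
            concept = f"{ob.cui}|{snomed}"
        records.append(EntityRecord(fname, ob.sent_id, ob.chunk_id,
                                    "observation", concept, ob.certainty))
    for ls in result.living_statuses:
        records.append(EntityRecord(fname, ls.sent_id, ls.chunk_id,
                                    "living_status", ls.status, ls.certainty))
    for age in result.ages:
        records.append(EntityRecord(fname, age.sent_id, 0, "age",
                                    str(age.value), "nonnegated"))
    return records


def relation_records(result: ExtractionResult) -> list[RelationRecord]:
    return [
        RelationRecord(result.doc_id, r.fm_category, r.fm_side,
                       r.target_text, r.certainty)
        for r in result.relations
    ]


def _write_csv(sink: Union[PathLike, IO[str]], columns: Sequence[str],
               rows: Iterable[tuple[str, ...]]) -> None:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            _write_csv(fh, columns, rows)
        return
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(columns)
    writer.writerows(rows)


def write_entities(records: Iterable[EntityRecord],
                   sink: Union[PathLike, IO[str]],
                   fmt: str = "csv") -> None:
    if fmt != "csv":
        raise ValueError(f"unknown entity output format {fmt!r}")
    _write_csv(sink, ENTITY_COLUMNS, (r.row() for r in records))


def write_relations(records: Iterable[RelationRecord],
                    sink: Union[PathLike, IO[str]],
                    fmt: str = "csv") -> None:
    if fmt != "csv":
        raise ValueError(f"unknown relation output format {fmt!r}")
    _write_csv(sink, RELATION_COLUMNS, (r.row() for r in records))


def read_entities(source: Union[PathLike, IO[str]]) -> list[EntityRecord]:
    return [
        EntityRecord(r["file_name"], int(r["sentence_id"]), int(r["chunk_id"]),
                     r["entity_type"], r["concept"], r["certainty"])
        for r in _read_csv(source, ENTITY_COLUMNS)
    ]


def read_relations(source: Union[PathLike, IO[str]]) -> list[RelationRecord]:
    return [
        RelationRecord(r["file_name"], r["family_member"],
                       r["side_of_family"], r["observation_text"],
                       r["certainty"])
        for r in _read_csv(source, RELATION_COLUMNS)
    ]


def _read_csv(source, columns: Sequence[str]) -> list[dict[str, str]]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return _read_csv(fh, columns)
    reader = csv.DictReader(source)
    if reader.fieldnames != list(columns):
        raise ValueError(f"expected columns {list(columns)}, got {reader.fieldnames}")
    return list(reader)


# ---------------------------------------------------------------------------
# FHIR-style JSON
# ---------------------------------------------------------------------------

def chain_to_fhir(chain: FamilyChain,
                  snomed_mapping: Optional[Mapping[str, str]] = None) -> dict:
    """One FamilyMemberHistory-shaped object for a family chain."""
    conditions = []
    deceased = False
    for t in chain.targets:
        if t.kind == "living_status" and t.text == "Dead":
            deceased = True
        code: dict[str, str] = {"text": t.text}
        if t.cui:
            code["cui"] = t.cui
            snomed = (snomed_mapping or {}).get(t.cui, "")
            if snomed:
                code["snomed"] = snomed
        conditions.append({"code": code, "certainty": t.certainty,
                           "kind": t.kind})
    obj: dict = {
        "resourceType": "FamilyMemberHistory",
        "patient": {"reference": chain.doc_id},
        "relationship": {"text": chain.fm_category, "side": chain.fm_side},
        "condition": conditions,
    }
    if deceased:
        obj["deceased"] = True
    if chain.ages:
        obj["age"] = [a.value for a in chain.ages]
    return obj


def write_fhir(chains: Iterable[FamilyChain],
               sink: Union[PathLike, IO[str]],
               snomed_mapping: Optional[Mapping[str, str]] = None) -> None:
    """Write all chains as a JSON array of FamilyMemberHistory-style objects,
    each validated against the shipped schema before writing."""
    objs = [chain_to_fhir(c, snomed_mapping) for c in chains]
    schema = load_fhir_schema()
    for obj in objs:
        errors = validate_against_schema(obj, schema)
        if errors:
            raise ValueError(f"FHIR-style output failed validation: {errors}")
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(json.dumps(objs, indent=2) + "\n", encoding="utf-8")
    else:
        json.dump(objs, sink, indent=2)


def load_fhir_schema() -> dict:
    text = (
        resources.files("famhist")
        .joinpath("data/fhir_family_history.schema.json")
        .read_text("utf-8")
    )
    return json.loads(text)


_TYPE_CHECKS = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "boolean": bool,
}


def validate_against_schema(obj, schema: dict, path: str = "$") -> list[str]:
    """Minimal structural validator for the shipped schema subset
    (type / required / properties / items / enum)."""
    errors: list[str] = []
    expected = schema.get("type")
    if expected:
        py_type = _TYPE_CHECKS[expected]
        if not isinstance(obj, py_type) or (
            py_type is int and isinstance(obj, bool)
        ):
            return [f"{path}: expected {expected}, got {type(obj).__name__}"]
    if "enum" in schema and obj not in schema["enum"]:
        errors.append(f"{path}: {obj!r} not in {schema['enum']}")
    if expected == "object":
        for req in schema.get("required", ()):
            if req not in obj:
                errors.append(f"{path}: missing required key {req!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(
                    validate_against_schema(obj[key], subschema, f"{path}.{key}")
                )
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(obj):
            errors.extend(
                validate_against_schema(item, schema["items"], f"{path}[{i}]")
            )
    return errors
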