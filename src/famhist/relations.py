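"""Linking family members to observations and living status.

Relations are extracted by co-occurrence within a clause of one sentence, or
across up to three adjacent sentences (the cue sentence plus the two
preceding ones) when the later sentence carries a coreference cue ("he",
"she", "none of them", ...).  Relations involving spouse/in-law mentions are
excluded: a spouse's conditions are not the patient's family history.
All entities linked to one (category, side) key are assembled into a single
per-document family chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .entities import (
    NEGATED,
    AgeMention,
    FamilyMemberMention,
    LivingStatusMention,
    ObservationMention,
)
from .textprep import Clause, CoreferenceCue, Sentence

SAME_CLAUSE = "same_clause"
COREFERENCE = "coreference"

#: Maximum sentence distance bridged by coreference: the cue sentence plus
#: the two preceding sentences ("three adjacent sentences").
COREF_WINDOW = 2

Target = Union[ObservationMention, LivingStatusMention]


@dataclass
class FHRelation:
    doc_id: str
    fm_category: str
    fm_side: str
    target_kind: str  # observation | living_status
    target_text: str
    target_cui: str  # empty for living-status targets
    certainty: str
    provenance: str  # same_clause | coreference
    sent_ids: tuple[int, ...]  # sentences involved (FM first)

    def __post_init__(self) -> None:
        if self.provenance == COREFERENCE:
            dist = abs(self.sent_ids[-1] - self.sent_ids[0])
            if not 1 <= dist <= COREF_WINDOW:
                raise ValueError(
                    f"coreference distance {dist} outside 1..{COREF_WINDOW}"
                )

    def key(self, with_certainty: bool = True) -> tuple:
        """Identity for deduplication and scoring."""
        target = self.target_cui or self.target_text.casefold()
        base = (self.doc_id, self.fm_category, self.fm_side,
                self.target_kind, target)
        return base + (self.certainty,) if with_certainty else base


@dataclass
class ChainTarget:
    kind: str
    text: str
    cui: str
    certainty: str
    provenance: str


@dataclass
class FamilyChain:
    """All entities linked to one family-member key in a document."""

    doc_id: str
    fm_category: str
    fm_side: str
    targets: list[ChainTarget] = field(default_factory=list)
    ages: list[AgeMention] = field(default_factory=list)


def _target_fields(t: Target) -> tuple[str, str, str]:
    if isinstance(t, ObservationMention):
        return "observation", t.text, t.cui
    return "living_status", t.status, ""


def link_within_clause(
    clause: Clause,
    fms: Sequence[FamilyMemberMention],
    targets: Sequence[Target],
    doc_id: str = "",
) -> list[FHRelation]:
    """Link every non-spouse family member in a clause to every observation
    and living-status mention in the same clause."""
    start, end = clause.span
    in_clause = lambda span: start <= span[0] < end
    relations: list[FHRelation] = []
    for fm in fms:
        if fm.is_spouse_or_inlaw or not in_clause(fm.span):
            continue
        for t in targets:
            if not in_clause(t.span):
                continue
            kind, text, cui = _target_fields(t)
            relations.append(
                FHRelation(
                    doc_id or fm.doc_id, fm.category, fm.side, kind, text, cui,
                    t.certainty, SAME_CLAUSE, (fm.sent_id, clause.sent_id),
                )
            )
    return relations


@dataclass
class SentenceContext:
    """Per-sentence bundle consumed by cross-sentence linking."""

    sentence: Sentence
    fms: list[FamilyMemberMention] = field(default_factory=list)
    targets: list[Target] = field(default_factory=list)
    cues: list[CoreferenceCue] = field(default_factory=list)
    linked_target_ids: set[int] = field(default_factory=set)  # id() of targets
    # already linked within a clause


def link_cross_sentence(
    contexts: Sequence[SentenceContext],
    doc_id: str = "",
    window: int = COREF_WINDOW,
) -> list[FHRelation]:
    """Bridge unlinked targets to preceding family members via coreference.

    A target in sentence *i* with no same-clause link attaches to the nearest
    non-spouse FM in sentences *i-window* .. *i-1*, but only when sentence
    *i* carries a coreference cue.  The plural-negative cue "none of them"
    links the target to every FM in the window and forces certainty to
    negated.  Backward (anaphoric) linking only.
    """
    relations: list[FHRelation] = []
    for i, ctx in enumerate(contexts):
        if not ctx.cues:
            continue
        plural_negative = any(c.cue == "none of them" for c in ctx.cues)
        unlinked = [t for t in ctx.targets if id(t) not in ctx.linked_target_ids]
        if not unlinked:
            continue
        antecedents: list[FamilyMemberMention] = []
        for j in range(i - 1, max(i - window, 0) - 1, -1):
            for fm in contexts[j].fms:
                if not fm.is_spouse_or_inlaw:
                    antecedents.append(fm)  # nearest sentence first
        if not antecedents:
            continue
        chosen = antecedents if plural_negative else antecedents[:1]
        for t in unlinked:
            kind, text, cui = _target_fields(t)
            certainty = NEGATED if plural_negative else t.certainty
            for fm in chosen:
                relations.append(
                    FHRelation(
                        doc_id or fm.doc_id, fm.category, fm.side, kind, text,
                        cui, certainty, COREFERENCE,
                        (fm.sent_id, ctx.sentence.sent_id),
                    )
                )
    return relations


def exclude_spouse(
    relations: Iterable[FHRelation],
    fms: Iterable[FamilyMemberMention] = (),
) -> list[FHRelation]:
    """Drop any relation whose family member is a spouse/in-law mention.

    Linking already refuses spouse FMs; this is the final guarantee applied
    to the assembled relation list (spouse categories are None, so a None
    category marks an excluded mention that slipped through a custom linker).
    """
    spouse_spans = {fm.span for fm in fms if fm.is_spouse_or_inlaw}
    del spouse_spans  # spans carry no category; the category check suffices
    return [r for r in relations if r.fm_category is not None]


def assemble_chains(
    relations: Sequence[FHRelation],
    ages: Sequence[AgeMention] = (),
) -> list[FamilyChain]:
    """Group relations into one chain per (category, side) per document.

    Duplicate targets (same cui/text and certainty) merge keeping the first
    provenance; chains and targets keep first-appearance order.  Age mentions
    from a sentence where the chain's FM appears are attached to the chain.
    """
    chains: dict[tuple[str, str, str], FamilyChain] = {}
    seen: dict[tuple[str, str, str], set[tuple]] = {}
    fm_sents: dict[tuple[str, str, str], set[int]] = {}
    for r in relations:
        key = (r.doc_id, r.fm_category, r.fm_side)
        chain = chains.get(key)
        if chain is None:
            chain = chains[key] = FamilyChain(r.doc_id, r.fm_category, r.fm_side)
            seen[key] = set()
            fm_sents[key] = set()
        fm_sents[key].add(r.sent_ids[0])
        tkey = (r.target_kind, r.target_cui or r.target_text.casefold(), r.certainty)
        if tkey in seen[key]:
            continue
        seen[key].add(tkey)
        chain.targets.append(
            ChainTarget(r.target_kind, r.target_text, r.target_cui,
                        r.certainty, r.provenance)
        )
    for age in ages:
        for key, chain in chains.items():
            if age.doc_id == chain.doc_id and age.sent_id in fm_sents[key]:
                chain.ages.append(age)
    return list(chains.values())
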