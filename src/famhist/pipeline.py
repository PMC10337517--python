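"""End-to-end extraction: note text in, entities + relations + chains out.

Stages: family-history section location → sentence segmentation → entity
recognition (family members, lexicon observations, living status, ages) →
clause splitting and certainty assignment → within-clause linking →
cue-gated cross-sentence linking → spouse exclusion → chain assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .entities import (
    AgeMention,
    FamilyMemberMention,
    LivingStatusMention,
    ObservationMatcher,
    ObservationMention,
    detect_certainty,
    extract_age,
    extract_living_status,
    recognize_family_members,
)
from .lexicon import Lexicon
from .relations import (
    COREF_WINDOW,
    FamilyChain,
    FHRelation,
    SentenceContext,
    assemble_chains,
    exclude_spouse,
    link_cross_sentence,
    link_within_clause,
)
from .textprep import (
    DEFAULT_CUE_SET,
    DEFAULT_FH_HEADERS,
    Clause,
    Document,
    Section,
    Sentence,
    detect_coreference_cues,
    find_family_history_section,
    segment_sentences,
    split_clauses,
)


@dataclass
class ExtractionResult:
    doc_id: str
    section: Section
    sentences: list[Sentence]
    family_members: list[FamilyMemberMention]
    observations: list[ObservationMention]
    living_statuses: list[LivingStatusMention]
    ages: list[AgeMention]
    relations: list[FHRelation]
    chains: list[FamilyChain]

    @property
    def entity_count(self) -> int:
        return (
            len([f for f in self.family_members if not f.is_spouse_or_inlaw])
            + len(self.observations)
            + len(self.living_statuses)
            + len(self.ages)
        )


@dataclass
class ExtractorConfig:
    headers: Sequence[str] = DEFAULT_FH_HEADERS
    cue_set: Sequence[str] = DEFAULT_CUE_SET
    coref_window: int = COREF_WINDOW
    map_extended: bool = False


class Extractor:
    """Reusable extractor holding the compiled lexicon matcher."""

    def __init__(self, lexicon: Lexicon, config: Optional[ExtractorConfig] = None):
        self.lexicon = lexicon
        self.config = config or ExtractorConfig()
        self._matcher = ObservationMatcher(lexicon)

    def extract(self, document: Document) -> ExtractionResult:
        cfg = self.config
        section = find_family_history_section(document, cfg.headers)
        body = document.text[section.span[0] : section.span[1]]
        sentences = segment_sentences(body, offset=section.span[0])

        contexts: list[SentenceContext] = []
        all_fms: list[FamilyMemberMention] = []
        all_obs: list[ObservationMention] = []
        all_living: list[LivingStatusMention] = []
        all_ages: list[AgeMention] = []
        relations: list[FHRelation] = []

        for sent in sentences:
            fms = recognize_family_members(
                sent, document.doc_id, map_extended=cfg.map_extended
            )
            obs = self._matcher.match(sent, document.doc_id)
            living = extract_living_status(sent, document.doc_id)
            ages = extract_age(sent, document.doc_id)
            cues = detect_coreference_cues(sent, cfg.cue_set)
            clauses = split_clauses(sent, [fm.span for fm in fms])

            targets = list(obs) + list(living)
            for t in targets:
                clause = _containing_clause(clauses, t.span)
                t.chunk_id = clause.chunk_id
                t.certainty = detect_certainty(document.text, t.span, clause)

            ctx = SentenceContext(sent, fms, targets, cues)
            for clause in clauses:
                relations.extend(
                    link_within_clause(clause, fms, targets, document.doc_id)
                )
                # a clause owned by any FM — spouse included — claims its
                # targets: spouse conditions are recorded, never re-linked
                clause_fms = [f for f in fms if _in_span(clause.span, f.span)]
                if clause_fms:
                    for t in targets:
                        if _in_span(clause.span, t.span):
                            ctx.linked_target_ids.add(id(t))

            contexts.append(ctx)
            all_fms.extend(fms)
            all_obs.extend(obs)
            all_living.extend(living)
            all_ages.extend(ages)

        relations.extend(
            link_cross_sentence(contexts, document.doc_id, cfg.coref_window)
        )
        relations = exclude_spouse(relations, all_fms)
        chains = assemble_chains(relations, all_ages)
        return ExtractionResult(
            document.doc_id, section, sentences, all_fms, all_obs,
            all_living, all_ages, relations, chains,
        )


def _in_span(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] < outer[1]


def _containing_clause(clauses: Sequence[Clause], span: tuple[int, int]) -> Clause:
    for clause in clauses:
        if _in_span(clause.span, span):
            return clause
    return clauses[-1]


def extract_document(
    document: Document,
    lexicon: Lexicon,
    config: Optional[ExtractorConfig] = None,
) -> ExtractionResult:
    """Run the full pipeline on one document."""
    return Extractor(lexicon, config).extract(document)
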