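"""Synthetic family-history notes with self-annotating gold standard.

The real FH challenge corpora are distributed under data-use agreements, so
every stage of this package is exercised instead on generated notes that
emulate the constructs the extraction rules target: single-clause
family-member/observation statements, observation lists, bounded
cross-sentence coreference, negation, spouse distractors, living status and
ages.  Because each document is assembled from templates whose semantics are
known, the gold entities and relations are emitted alongside the text.

An ``adversarial`` switch adds constructs the rules deliberately do not
cover (cataphora, coreference at distance three) whose gold relations the
extractor is expected to miss — useful for checking that recall degrades
rather than silently inflating.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .entities import NEGATED, NONNEGATED
from .evaluation import (
    GoldEntity,
    GoldRelation,
    write_gold_entities,
    write_gold_relations,
)
from .lexicon import (
    FH_ELIGIBLE_TYPES,
    Lexicon,
    LexiconEntry,
    SemanticType,
    write_lexicon,
)
from .textprep import Document

# condition name pool for the mini-lexicon; all surface forms are free of
# family-member terms, pronouns, and living-status/negation cues
_CONDITIONS = (
    "diabetes", "hypertension", "colon cancer", "breast cancer", "asthma",
    "stroke", "arthritis", "depression", "melanoma", "leukemia",
    "osteoporosis", "emphysema", "glaucoma", "anemia", "migraine",
    "epilepsy", "lymphoma", "cirrhosis", "dementia", "gout",
    "psoriasis", "scoliosis", "hemophilia", "sarcoidosis", "lupus",
    "hyperthyroidism", "pancreatitis", "endometriosis", "cardiomyopathy",
    "hemochromatosis",
)

_MODIFIERS = ("chronic", "severe", "early onset")

_GENDERED_FMS: tuple[tuple[str, str, str, str], ...] = (
    # surface, category, side, pronoun
    ("mother", "Mother", "NA", "She"),
    ("father", "Father", "NA", "He"),
    ("sister", "Sister", "NA", "She"),
    ("brother", "Brother", "NA", "He"),
    ("maternal grandmother", "Grandmother", "Maternal", "She"),
    ("paternal grandmother", "Grandmother", "Paternal", "She"),
    ("maternal grandfather", "Grandfather", "Maternal", "He"),
    ("paternal grandfather", "Grandfather", "Paternal", "He"),
    ("aunt", "Aunt", "NA", "She"),
    ("uncle", "Uncle", "NA", "He"),
    ("daughter", "Daughter", "NA", "She"),
    ("son", "Son", "NA", "He"),
)


@dataclass
class GenerationConfig:
    """Study conditions for corpus generation; the seed fixes the corpus
    byte-for-byte."""

    n_documents: int = 200
    seed: int = 0
    p_negation: float = 0.15
    p_coreference: float = 0.20
    p_spouse: float = 0.10
    p_obslist: float = 0.20
    p_living: float = 0.30
    p_age: float = 0.15
    n_concepts: int = 20
    max_variants: int = 4
    min_statements: int = 2
    max_statements: int = 5
    adversarial: bool = False

    def __post_init__(self) -> None:
        for name in ("p_negation", "p_coreference", "p_spouse", "p_obslist",
                     "p_living", "p_age"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    gold_entities: list[GoldEntity]
    gold_relations: list[GoldRelation]
    lexicon: Lexicon
    config: GenerationConfig
    n_coreference_gold: int = 0  # gold relations that need cross-sentence links
    n_adversarial_gold: int = 0  # gold relations the rules cannot reach


def make_mini_lexicon(
    n_concepts: int = 20, max_variants: int = 4, seed: int = 0
) -> Lexicon:
    """A synthetic mini-lexicon: C9xxxxxx CUIs over a realistic condition
    pool, 1..max_variants variants per concept including occasional
    concatenation typos (probability 0.2), FH-eligible semantic types only.

    Variants are globally unique across concepts, so dictionary matches are
    unambiguous by construction.
    """
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    n_concepts = min(n_concepts, len(_CONDITIONS))
    rng = random.Random(seed)
    stypes = sorted(FH_ELIGIBLE_TYPES)
    lex = Lexicon()
    used: set[str] = set()
    for i, base in enumerate(_CONDITIONS[:n_concepts]):
        cui = f"C9{i:06d}"
        stype = SemanticType(rng.choice(stypes))
        snomed = str(10000000 + i) if rng.random() < 0.5 else ""
        variants = [base]
        n_extra = rng.randint(0, max_variants - 1)
        pool = [f"{m} {base}" for m in _MODIFIERS]
        rng.shuffle(pool)
        variants.extend(pool[:n_extra])
        if " " in base and rng.random() < 0.2:
            variants.append(base.replace(" ", ""))  # "coloncancer"-style typo
        for v in variants[:max_variants]:
            if v in used:
                continue
            used.add(v)
            lex.add(LexiconEntry(v, cui, snomed, base.capitalize(), stype))
    return lex


class _DocBuilder:
    def __init__(self, doc_id: str, header: str = "FAMILY HISTORY:\n") -> None:
        self.doc_id = doc_id
        self.parts: list[str] = [header]
        self.offset = len(header)
        self.entities: list[GoldEntity] = []
        self.relations: list[GoldRelation] = []

    def add_sentence(self, chunks: Sequence[tuple[str, Optional[GoldEntity]]]) -> None:
        """Append one sentence given (text, optional gold entity) chunks;
        spans are filled in from the running offset."""
        pos = self.offset
        texts: list[str] = []
        for text, entity in chunks:
            if entity is not None:
                self.entities.append(
                    GoldEntity(entity.doc_id, entity.etype, entity.label,
                               entity.side, entity.certainty,
                               pos, pos + len(text), text)
                )
            texts.append(text)
            pos += len(text)
        sentence = "".join(texts)
        self.parts.append(sentence + " ")
        self.offset += len(sentence) + 1

    def build(self) -> Document:
        return Document(self.doc_id, "".join(self.parts).rstrip() + "\n")


def _pick_concept(rng: random.Random, lexicon: Lexicon,
                  exclude: frozenset[str] = frozenset()) -> tuple[str, str]:
    """(variant, cui) drawn uniformly over concepts then variants."""
    cuis = [c for c in sorted(lexicon.concept_index) if c not in exclude]
    cui = rng.choice(cuis)
    variant = rng.choice(sorted(lexicon.concept_index[cui]))
    return variant, cui


def generate_corpus(
    config: GenerationConfig, lexicon: Optional[Lexicon] = None
) -> SyntheticCorpus:
    """Generate documents plus gold annotations under the template inventory.

    Statement types are drawn per statement: spouse distractor (no gold
    relation), negated statement, cross-sentence coreference pair, an
    observation list, or a plain statement (optionally carrying living
    status and/or an age).  Pronouns in coreference pairs agree with the
    family member's gender so the cue mechanism, not gender resolution, is
    what gets exercised.
    """
    rng = random.Random(config.seed)
    if lexicon is None:
        lexicon = make_mini_lexicon(config.n_concepts, config.max_variants,
                                    seed=rng.randrange(2**31))
    docs: list[Document] = []
    all_entities: list[GoldEntity] = []
    all_relations: list[GoldRelation] = []
    n_coref = 0
    n_adv = 0

    for d in range(config.n_documents):
        doc_id = f"synth-{d:04d}"
        b = _DocBuilder(doc_id)
        n_statements = rng.randint(config.min_statements, config.max_statements)
        for _ in range(n_statements):
            r = rng.random()
            if r < config.p_spouse:
                _spouse_statement(b, rng, lexicon)
            elif r < config.p_spouse + config.p_negation:
                _negation_statement(b, rng, lexicon)
            elif r < config.p_spouse + config.p_negation + config.p_coreference:
                n_coref += _coreference_statement(b, rng, lexicon)
            elif (r < config.p_spouse + config.p_negation
                  + config.p_coreference + config.p_obslist):
                _obslist_statement(b, rng, lexicon)
            else:
                _plain_statement(b, rng, lexicon, config)
        if config.adversarial and rng.random() < 0.5:
            n_adv += _adversarial_statement(b, rng, lexicon)
        docs.append(b.build())
        all_entities.extend(b.entities)
        all_relations.extend(b.relations)

    return SyntheticCorpus(docs, all_entities, all_relations, lexicon, config,
                           n_coreference_gold=n_coref,
                           n_adversarial_gold=n_adv)


def _fm_chunk(doc_id: str, surface: str, category: str, side: str,
              capitalize: bool = True) -> tuple[str, GoldEntity]:
    text = surface.capitalize() if capitalize else surface
    return text, GoldEntity(doc_id, "family_member", category, side)


def _obs_chunk(doc_id: str, variant: str, cui: str,
               certainty: str = NONNEGATED) -> tuple[str, GoldEntity]:
    return variant, GoldEntity(doc_id, "observation", cui, "NA", certainty)


def _plain_statement(b: _DocBuilder, rng: random.Random, lexicon: Lexicon,
                     config: GenerationConfig) -> None:
    surface, category, side, _ = rng.choice(_GENDERED_FMS)
    fm = _fm_chunk(b.doc_id, surface, category, side)
    if rng.random() < config.p_living:
        if rng.random() < 0.5:
            status = "Alive"
            b.add_sentence([
                fm, (" is ", None),
                ("alive", GoldEntity(b.doc_id, "living_status", "Alive")),
                (" and well.", None),
            ])
        elif rng.random() < config.p_age:
            status = "Dead"
            age = rng.randint(40, 95)
            b.add_sentence([
                fm, (" ", None),
                ("died", GoldEntity(b.doc_id, "living_status", "Dead")),
                (" at age ", None),
                (str(age), GoldEntity(b.doc_id, "age", str(age))),
                (".", None),
            ])
        else:
            status = "Dead"
            b.add_sentence([
                fm, (" is ", None),
                ("deceased", GoldEntity(b.doc_id, "living_status", "Dead")),
                (".", None),
            ])
        b.relations.append(
            GoldRelation(b.doc_id, category, side, "living_status", status)
        )
        return
    variant, cui = _pick_concept(rng, lexicon)
    if rng.random() < config.p_age:
        age = rng.randint(20, 90)
        b.add_sentence([
            fm, (" was diagnosed with ", None),
            _obs_chunk(b.doc_id, variant, cui),
            (" at age ", None),
            (str(age), GoldEntity(b.doc_id, "age", str(age))),
            (".", None),
        ])
    else:
        b.add_sentence([fm, (" has ", None),
                        _obs_chunk(b.doc_id, variant, cui), (".", None)])
    b.relations.append(
        GoldRelation(b.doc_id, category, side, "observation", cui)
    )


def _obslist_statement(b: _DocBuilder, rng: random.Random, lexicon: Lexicon) -> None:
    surface, category, side, _ = rng.choice(_GENDERED_FMS)
    v1, c1 = _pick_concept(rng, lexicon)
    v2, c2 = _pick_concept(rng, lexicon, exclude=frozenset({c1}))
    b.add_sentence([
        _fm_chunk(b.doc_id, surface, category, side),
        (" has ", None), _obs_chunk(b.doc_id, v1, c1),
        (" and ", None), _obs_chunk(b.doc_id, v2, c2), (".", None),
    ])
    for cui in (c1, c2):
        b.relations.append(
            GoldRelation(b.doc_id, category, side, "observation", cui)
        )


def _negation_statement(b: _DocBuilder, rng: random.Random, lexicon: Lexicon) -> None:
    variant, cui = _pick_concept(rng, lexicon)
    if rng.random() < 0.5:
        surface, category, side, _ = rng.choice(_GENDERED_FMS)
        b.add_sentence([
            _fm_chunk(b.doc_id, surface, category, side),
            (" has no history of ", None),
            _obs_chunk(b.doc_id, variant, cui, NEGATED), (".", None),
        ])
        b.relations.append(
            GoldRelation(b.doc_id, category, side, "observation", cui, NEGATED)
        )
    else:
        # no family member: a negated entity with no relation
        b.add_sentence([
            ("No family history of ", None),
            _obs_chunk(b.doc_id, variant, cui, NEGATED), (".", None),
        ])


def _coreference_statement(b: _DocBuilder, rng: random.Random,
                           lexicon: Lexicon) -> int:
    surface, category, side, pronoun = rng.choice(_GENDERED_FMS)
    variant, cui = _pick_concept(rng, lexicon)
    b.add_sentence([
        _fm_chunk(b.doc_id, surface, category, side),
        (" is ", None),
        ("deceased", GoldEntity(b.doc_id, "living_status", "Dead")),
        (".", None),
    ])
    b.add_sentence([
        (pronoun + " had ", None),
        _obs_chunk(b.doc_id, variant, cui), (".", None),
    ])
    b.relations.append(
        GoldRelation(b.doc_id, category, side, "living_status", "Dead")
    )
    b.relations.append(
        GoldRelation(b.doc_id, category, side, "observation", cui)
    )
    return 1


def _spouse_statement(b: _DocBuilder, rng: random.Random, lexicon: Lexicon) -> None:
    variant, cui = _pick_concept(rng, lexicon)
    lead = rng.choice(("Her husband", "His wife"))
    # the spouse's condition is a real observation entity but never an FH
    # relation, and the spouse itself is not a family-history entity
    b.add_sentence([
        (lead + " has ", None),
        _obs_chunk(b.doc_id, variant, cui), (".", None),
    ])


def _adversarial_statement(b: _DocBuilder, rng: random.Random,
                           lexicon: Lexicon) -> int:
    """Constructs outside the rule inventory; their relations are real gold
    the extractor is expected to miss."""
    surface, category, side, pronoun = rng.choice(_GENDERED_FMS)
    variant, cui = _pick_concept(rng, lexicon)
    if rng.random() < 0.5:
        # cataphora: pronoun precedes the family member
        b.add_sentence([
            (pronoun + " had ", None),
            _obs_chunk(b.doc_id, variant, cui), (".", None),
        ])
        b.add_sentence([
            _fm_chunk(b.doc_id, surface, category, side),
            (" is ", None),
            ("deceased", GoldEntity(b.doc_id, "living_status", "Dead")),
            (".", None),
        ])
        b.relations.append(
            GoldRelation(b.doc_id, category, side, "living_status", "Dead")
        )
    else:
        # coreference at distance 3: outside the three-sentence window
        b.add_sentence([
            _fm_chunk(b.doc_id, surface, category, side),
            (" is ", None),
            ("deceased", GoldEntity(b.doc_id, "living_status", "Dead")),
            (".", None),
        ])
        b.relations.append(
            GoldRelation(b.doc_id, category, side, "living_status", "Dead")
        )
        b.add_sentence([("Chart was reviewed in detail.", None)])
        b.add_sentence([("Records were requested from an outside clinic.", None)])
        b.add_sentence([
            (pronoun + " had ", None),
            _obs_chunk(b.doc_id, variant, cui), (".", None),
        ])
    b.relations.append(
        GoldRelation(b.doc_id, category, side, "observation", cui)
    )
    return 1


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> None:
    """Write the corpus as a directory of .txt notes plus gold TSVs and the
    mini-lexicon TSV."""
    outdir = Path(outdir)
    notes = outdir / "notes"
    notes.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        (notes / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    write_gold_entities(corpus.gold_entities, outdir / "gold_entities.tsv")
    write_gold_relations(corpus.gold_relations, outdir / "gold_relations.tsv")
    write_lexicon(corpus.lexicon, outdir / "mini_lexicon.tsv")
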