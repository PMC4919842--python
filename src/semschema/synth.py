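"""Seeded generator of clinical-style reports with gold annotations.

Stands in for a hand-annotated report corpus so the extraction and
evaluation chain is testable offline.  Each report is a handful of templated,
radiology-flavoured carrier sentences; a *finding* sentence plants exactly
one target lexical variant drawn from one schema concept, optionally prefixed
by a negation cue and by the surface cues of the concept's assigned modifier
values.  The gold record is exactly what was planted (span, concept id,
modifier map), so with an undegraded lexicon the extraction engine recovers
every gold mention and modifier — the oracle anchoring the evaluation chain.

All randomness flows from a single seed; identical inputs reproduce the
corpus byte-for-byte.  ``degrade_lexicon`` removes a seeded, *nested*
fraction of variants of one kind (higher fractions remove supersets), which
makes recall provably non-increasing in the degradation fraction and mirrors
the effect of missing acronyms/abbreviations in a modifier file.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .datamodel import (
    Concept,
    ConceptCategory,
    LexicalVariant,
    NumericRange,
    Schema,
    TerminologyBinding,
    VariantKind,
    VariantSource,
    add_lexical_variant,
    create_concept,
    set_modifier_cue,
    set_semantic_modifier,
    set_semantic_type,
    set_shared_modifier,
)
from .errors import ValidationError
from .nlp_export import DEFAULT_SHARED_CUES
from .registry import ModifierRegistry, load_registry

NEGATED_CERTAINTY = "Definite_Negated_Existence"

# fixed carrier templates: (prefix, suffix)
_FINDING_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("there is ", "."),
    ("impression: ", "."),
    ("study demonstrates ", "."),
    ("", " is seen."),
    ("", " is identified on imaging."),
)

# carrier sentences with no planted content; vocabulary kept disjoint from the
# demo lexicon and the default cue tables
_DISTRACTORS: tuple[str, ...] = (
    "the examination was performed with standard technique.",
    "images were reviewed by the attending radiologist.",
    "the study was tolerated well.",
    "comparison was made with an earlier examination.",
    "technical quality was adequate for interpretation.",
    "flow waveforms appear symmetric throughout.",
)


@dataclass(frozen=True)
class GoldMention:
    span: tuple[int, int]
    category: str  # concept id
    modifiers: tuple[tuple[str, str], ...] = ()  # sorted (class/category, value token)

    def modifier_map(self) -> dict[str, str]:
        return dict(self.modifiers)


@dataclass
class GoldDocument:
    doc_id: str
    text: str
    mentions: list[GoldMention] = field(default_factory=list)


def _pick_variant(
    rng: random.Random, variants: list[LexicalVariant], abbreviation_rate: float
) -> LexicalVariant:
    abbrs = [v for v in variants if v.kind is VariantKind.ABBREVIATION]
    others = [v for v in variants if v.kind is not VariantKind.ABBREVIATION]
    if abbrs and (not others or rng.random() < abbreviation_rate):
        return rng.choice(abbrs)
    return rng.choice(others or abbrs)


def _negation_cues(schema: Schema) -> list[str]:
    cues = [v.text for v in schema.modifier_cues.get(NEGATED_CERTAINTY, [])]
    defaults = [lit for lit, rule in DEFAULT_SHARED_CUES[NEGATED_CERTAINTY] if rule == "forward"]
    return sorted(set(c.casefold() for c in cues) | set(defaults)) or defaults


def _modifier_cue_variants(schema: Schema, value_token: str, display: str) -> list[LexicalVariant]:
    cues = list(schema.modifier_cues.get(value_token, []))
    if not any(v.text.casefold() == display.casefold() for v in cues):
        cues.append(LexicalVariant(display))
    return cues


def _finding_sentence(
    rng: random.Random,
    schema: Schema,
    concept: Concept,
    negation_rate: float,
    abbreviation_rate: float,
) -> tuple[str, int, int, dict[str, str]]:
    """Returns (sentence text, target start, target end, gold modifier map)."""
    gold: dict[str, str] = {}
    parts: list[str] = []
    if rng.random() < negation_rate:
        parts.append(rng.choice(_negation_cues(schema)))
        gold["Certainty"] = NEGATED_CERTAINTY
    for assignment in concept.shared_modifiers:
        if assignment.category == "Certainty":
            continue  # certainty realization is governed by negation_rate
        token = assignment.value_token
        cue_defaults = DEFAULT_SHARED_CUES.get(token, ((assignment.value.casefold(), "forward"),))
        forward = [lit for lit, rule in cue_defaults if rule == "forward"]
        schema_cues = [v.text for v in schema.modifier_cues.get(token, [])]
        pool = schema_cues or forward
        if not pool:
            continue
        parts.append(rng.choice(sorted(pool)))
        gold[assignment.category] = token
    for assignment in concept.semantic_modifiers:
        cues = _modifier_cue_variants(schema, assignment.value_token, assignment.value_display())
        parts.append(_pick_variant(rng, cues, abbreviation_rate).text)
        gold[assignment.modifier_class] = assignment.value_token
    target = _pick_variant(rng, concept.variants, abbreviation_rate)
    prefix_words = " ".join(parts)
    phrase = (prefix_words + " " + target.text) if prefix_words else target.text
    t_prefix, t_suffix = rng.choice(_FINDING_TEMPLATES)
    start = len(t_prefix) + (len(prefix_words) + 1 if prefix_words else 0)
    sentence = t_prefix + phrase + t_suffix
    return sentence, start, start + len(target.text), gold


def generate_corpus(
    schema: Schema,
    n_reports: int,
    seed: int,
    distractor_rate: float = 0.2,
    abbreviation_rate: float = 0.5,
    negation_rate: float = 0.3,
) -> list[GoldDocument]:
    """Generate ``n_reports`` reports of 3-8 sentences each.

    Each non-distractor sentence plants one concept mention chosen uniformly
    over the schema's concepts; ``abbreviation_rate`` is the probability that
    a planted surface form (target or modifier cue) is an abbreviation when
    one exists, and ``negation_rate`` the probability a mention is negated
    with a certainty cue.  Fully reproducible per seed.
    """
    if n_reports < 1:
        raise ValidationError("n_reports must be >= 1")
    concepts = [c for c in schema.concepts if c.variants]
    if not concepts:
        raise ValidationError("schema has no concept with lexical variants; nothing to plant")
    rng = random.Random(seed)
    documents: list[GoldDocument] = []
    for i in range(n_reports):
        sentences: list[str] = []
        mentions: list[GoldMention] = []
        offset = 0
        for _ in range(rng.randint(3, 8)):
            if rng.random() < distractor_rate:
                sentence = rng.choice(_DISTRACTORS)
            else:
                concept = rng.choice(concepts)
                sentence, t_start, t_end, gold = _finding_sentence(
                    rng, schema, concept, negation_rate, abbreviation_rate
                )
                mentions.append(
                    GoldMention(
                        span=(offset + t_start, offset + t_end),
                        category=concept.id,
                        modifiers=tuple(sorted(gold.items())),
                    )
                )
            sentences.append(sentence)
            offset += len(sentence) + 1  # the joining space
        documents.append(
            GoldDocument(doc_id=f"report_{i:03d}", text=" ".join(sentences), mentions=mentions)
        )
    return documents


def degrade_lexicon(
    schema: Schema,
    drop_kind: VariantKind = VariantKind.ABBREVIATION,
    fraction: float = 0.0,
    seed: int = 0,
) -> Schema:
    """Return a copy of the schema with a seeded fraction of the variants of
    one kind removed (concept variants and modifier cues alike).

    Removals are *nested*: for a fixed seed, the variants dropped at a lower
    fraction are a subset of those dropped at a higher one, so downstream
    recall is non-increasing in ``fraction``.  The original schema is
    untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must be within [0, 1]")
    degraded = copy.deepcopy(schema)
    locations: list[tuple[str, str, str]] = []  # ("concept"|"cue", owner key, variant key)
    for concept in degraded.concepts:
        for v in concept.variants:
            if v.kind is drop_kind:
                locations.append(("concept", concept.id, v.key))
    for key, cues in sorted(degraded.modifier_cues.items()):
        for v in cues:
            if v.kind is drop_kind:
                locations.append(("cue", key, v.key))
    locations.sort()
    random.Random(seed).shuffle(locations)
    to_drop = set(locations[: round(fraction * len(locations))])
    for concept in degraded.concepts:
        concept.variants = [
            v for v in concept.variants
            if not (v.kind is drop_kind and ("concept", concept.id, v.key) in to_drop)
        ]
    degraded.modifier_cues = {
        key: [
            v for v in cues
            if not (v.kind is drop_kind and ("cue", key, v.key) in to_drop)
        ]
        for key, cues in degraded.modifier_cues.items()
    }
    return degraded


_WORDS = (
    "stenosis", "plaque", "bruit", "flow", "velocity", "lesion", "graft",
    "thrombus", "bulb", "lumen", "segment", "vessel", "calcification",
    "dissection", "murmur", "effusion", "nodule", "mass", "shadow", "signal",
)


def random_schema(
    seed: int | random.Random,
    registry: ModifierRegistry | None = None,
    max_concepts: int = 5,
) -> Schema:
    """A random but always-valid schema, built through the public authoring
    API; used for property-based round-trip testing."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    reg = registry or load_registry()
    schema = Schema(name=f"random schema {rng.randrange(10**6)}")
    for _ in range(rng.randint(1, max_concepts)):
        name = " ".join(rng.sample(_WORDS, rng.randint(1, 2)))
        category = ConceptCategory.PERSON if rng.random() < 0.15 else ConceptCategory.EVENT
        concept = create_concept(schema, name, category)
        eligible = [t for t in reg.semantic_types if t.category == category.value]
        semantic_type = rng.choice(eligible)
        set_semantic_type(concept, semantic_type.name, reg)
        for _ in range(rng.randint(0, 3)):
            kind = rng.choice(
                [VariantKind.SYNONYM, VariantKind.ABBREVIATION, VariantKind.MISSPELLING]
            )
            source = rng.choice(list(VariantSource))
            add_lexical_variant(concept, rng.choice(_WORDS), kind, source)
        if rng.random() < 0.4:
            concept.binding = TerminologyBinding(
                cui=f"C{rng.randrange(10**7):07d}",
                preferred_term=concept.name,
                definition=rng.choice([None, "a randomly generated definition"]),
            )
        for spec in semantic_type.classes:
            if rng.random() >= 0.35:
                continue
            if spec.unlimited and rng.random() < 0.5:
                lower = rng.randint(1, 50)
                value: object = NumericRange(
                    lower if rng.random() < 0.8 else None,
                    lower + rng.randint(0, 100),
                    rng.choice(["mg", "bpm", "%", ""]),
                )
            elif spec.values:
                value = rng.choice(spec.values)
            elif spec.closure != "CLOSED":
                value = rng.choice(_WORDS)
            else:
                continue
            set_semantic_modifier(concept, spec.name, value, reg)
        if category is ConceptCategory.EVENT:
            for cat, values in reg.shared_modifier_catalog().items():
                if rng.random() < 0.2:
                    set_shared_modifier(concept, cat, rng.choice(values), reg)
        for assignment in concept.semantic_modifiers:
            if rng.random() < 0.3:
                set_modifier_cue(
                    schema,
                    assignment.value_token,
                    rng.choice(_WORDS),
                    rng.choice([VariantKind.SYNONYM, VariantKind.ABBREVIATION]),
                )
    return schema


def write_corpus(documents: list[GoldDocument], out_dir: str | Path) -> Path:
    """Write plain-text reports plus a gold JSON sidecar; returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gold = {}
    for doc in documents:
        (out / f"{doc.doc_id}.txt").write_text(doc.text, "utf-8")
        gold[doc.doc_id] = [
            {"span": list(m.span), "category": m.category, "modifiers": m.modifier_map()}
            for m in doc.mentions
        ]
    sidecar = out / "gold.json"
    sidecar.write_text(json.dumps(gold, indent=2, ensure_ascii=False) + "\n", "utf-8")
    return sidecar


def load_corpus(corpus_dir: str | Path) -> list[GoldDocument]:
    root = Path(corpus_dir)
    gold = json.loads((root / "gold.json").read_text("utf-8"))
    documents = []
    for doc_id in sorted(gold):
        text = (root / f"{doc_id}.txt").read_text("utf-8")
        documents.append(
            GoldDocument(
                doc_id=doc_id,
                text=text,
                mentions=[
                    GoldMention(
                        span=tuple(m["span"]),
                        category=m["category"],
                        modifiers=tuple(sorted(m.get("modifiers", {}).items())),
                    )
                    for m in gold[doc_id]
                ],
            )
        )
    return documents
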