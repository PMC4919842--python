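"""Core data model: lexical variants, modifier assignments, concepts, schemas.

A *schema* is the target extraction template for a clinical NLP system: an
ordered collection of concepts, each combining an atomic concept (optionally
bound to a terminology record by CUI) with a semantic type, semantic and
shared modifier assignments, and the lexical variants (synonyms,
abbreviations, misspellings) by which it surfaces in text.

Authoring is constrained by the packaged modifier registry: a concept's
semantic type determines which semantic-modifier classes it may carry, and
shared modifiers come from closed category value sets.  PERSON concepts carry
only the Patient Demographic classes; shared modifiers apply to EVENT
concepts only.

All mutating operations validate eagerly and keep lists in a canonical order
(variants by kind then text; assignments by class/category name) so that
equality, JSON persistence and the OWL round trip are all order-insensitive.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from decimal import Decimal, InvalidOperation
from enum import Enum
from pathlib import Path
from typing import Any, Union

from ._text import collapse_ws, slug, token
from .errors import ConflictError, ParseError, RegistryLookupError, ValidationError
from .registry import ModifierRegistry, load_registry

SCHEMA_FORMAT = "semschema-schema"
SCHEMA_FORMAT_VERSION = 1

_CUI_RE = re.compile(r"^C\d+$")


class ConceptCategory(Enum):
    PERSON = "PERSON"
    EVENT = "EVENT"


class VariantKind(Enum):
    PREFERRED = "PREFERRED"
    SYNONYM = "SYNONYM"
    ABBREVIATION = "ABBREVIATION"
    MISSPELLING = "MISSPELLING"


class VariantSource(Enum):
    USER = "USER"
    TERMINOLOGY = "TERMINOLOGY"


_KIND_ORDER = {k: i for i, k in enumerate(VariantKind)}


@dataclass(frozen=True, order=False)
class LexicalVariant:
    """One surface form of a concept or modifier value."""

    text: str
    kind: VariantKind = VariantKind.SYNONYM
    source: VariantSource = VariantSource.USER

    def __post_init__(self) -> None:
        stripped = collapse_ws(self.text)
        if not stripped:
            raise ValidationError("lexical variant text must be non-empty")
        object.__setattr__(self, "text", stripped)

    @property
    def key(self) -> str:
        """Case/whitespace-insensitive deduplication key."""
        return self.text.casefold()

    def sort_key(self) -> tuple:
        return (_KIND_ORDER[self.kind], self.key, self.source.value)


@dataclass(frozen=True)
class NumericRange:
    """A numeric modifier value: closed, open-ended (one bound missing) or a
    point value (equal bounds), with a unit string."""

    lower: Decimal | None
    upper: Decimal | None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValidationError("numeric range requires at least one bound")
        for name in ("lower", "upper"):
            v = getattr(self, name)
            if v is not None and not isinstance(v, Decimal):
                object.__setattr__(self, name, Decimal(str(v)))
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValidationError(f"range lower bound {self.lower} exceeds upper bound {self.upper}")

    @property
    def is_point(self) -> bool:
        return self.lower is not None and self.lower == self.upper

    def display(self) -> str:
        unit = f" {self.unit}".rstrip()
        if self.is_point:
            return f"{self.lower}{unit}"
        if self.lower is None:
            return f"<{self.upper}{unit}"
        if self.upper is None:
            return f">{self.lower}{unit}"
        return f"{self.lower}-{self.upper}{unit}"

    def value_token(self) -> str:
        if self.is_point:
            core = f"{self.lower}"
        elif self.lower is None:
            core = f"Under {self.upper}"
        elif self.upper is None:
            core = f"Over {self.lower}"
        else:
            core = f"{self.lower} to {self.upper}"
        return token(f"{core} {self.unit}" if self.unit else core)


ModifierValue = Union[str, NumericRange]


def parse_numeric_range(
    lower_text: str | None, upper_text: str | None, unit: str = ""
) -> NumericRange:
    """Parse the two numeric boxes of a range input; empty boxes yield
    open-ended ranges, equal values a point value."""

    def _parse(text: str | None, which: str) -> Decimal | None:
        if text is None or not text.strip():
            return None
        try:
            return Decimal(text.strip())
        except InvalidOperation as exc:
            raise ParseError(f"{which} bound {text!r} is not a number") from exc

    lower = _parse(lower_text, "lower")
    upper = _parse(upper_text, "upper")
    if lower is None and upper is None:
        raise ValidationError("at least one bound of a numeric range must be given")
    return NumericRange(lower, upper, unit)


@dataclass(frozen=True)
class SemanticModifierAssignment:
    """A (modifier class, value) pair; the class must be allowed under the
    owning concept's semantic type."""

    modifier_class: str
    value: ModifierValue

    @property
    def value_token(self) -> str:
        v = self.value.value_token() if isinstance(self.value, NumericRange) else token(self.value)
        return f"{v}_{token(self.modifier_class)}"

    def value_display(self) -> str:
        return self.value.display() if isinstance(self.value, NumericRange) else self.value


@dataclass(frozen=True)
class SharedModifierAssignment:
    category: str
    value: str

    @property
    def value_token(self) -> str:
        return token(self.value)


@dataclass(frozen=True)
class TerminologyBinding:
    """Link to a terminology record: CUI ('C' + digits), its preferred term
    and optional definition."""

    cui: str
    preferred_term: str
    definition: str | None = None

    def __post_init__(self) -> None:
        if not _CUI_RE.match(self.cui):
            raise ValidationError(f"CUI {self.cui!r} does not match the 'C'+digits pattern")


@dataclass
class Concept:
    id: str
    name: str
    category: ConceptCategory
    semantic_type: str | None = None
    semantic_type_source: VariantSource | None = None
    binding: TerminologyBinding | None = None
    variants: list[LexicalVariant] = field(default_factory=list)
    semantic_modifiers: list[SemanticModifierAssignment] = field(default_factory=list)
    shared_modifiers: list[SharedModifierAssignment] = field(default_factory=list)

    def variants_of_kind(self, kind: VariantKind) -> list[LexicalVariant]:
        return [v for v in self.variants if v.kind == kind]

    def preferred_variant(self) -> LexicalVariant | None:
        pref = self.variants_of_kind(VariantKind.PREFERRED)
        return pref[0] if pref else None

    def semantic_modifier(self, modifier_class: str) -> SemanticModifierAssignment | None:
        for a in self.semantic_modifiers:
            if a.modifier_class.casefold() == modifier_class.casefold():
                return a
        return None

    def shared_modifier(self, category: str) -> SharedModifierAssignment | None:
        for a in self.shared_modifiers:
            if a.category.casefold() == category.casefold():
                return a
        return None


@dataclass
class Schema:
    """A named, ordered collection of concepts plus the cue lexicon for
    modifier values (``modifier_cues``: value token -> lexical variants used
    to recognise that value in text)."""

    name: str
    description: str | None = None
    concepts: list[Concept] = field(default_factory=list)
    modifier_cues: dict[str, list[LexicalVariant]] = field(default_factory=dict)
    created: str = ""
    modified: str = ""

    def __post_init__(self) -> None:
        now = _now_iso()
        if not self.created:
            self.created = now
        if not self.modified:
            self.modified = self.created

    def touch(self) -> None:
        self.modified = _now_iso()

    def concept(self, concept_id: str) -> Concept:
        for c in self.concepts:
            if c.id == concept_id:
                return c
        raise RegistryLookupError(f"no concept with id {concept_id!r} in schema {self.name!r}")

    def concept_by_name(self, name: str) -> Concept:
        hits = [c for c in self.concepts if c.name.casefold() == name.casefold()]
        if not hits:
            raise RegistryLookupError(f"no concept named {name!r} in schema {self.name!r}")
        if len(hits) > 1:
            raise RegistryLookupError(
                f"concept name {name!r} is ambiguous ({', '.join(c.id for c in hits)}); use the id"
            )
        return hits[0]


def _now_iso() -> str:
    return _dt.datetime.now(_dt.timezone.utc).replace(microsecond=0).isoformat()


# ---------------------------------------------------------------------------
# authoring operations
# ---------------------------------------------------------------------------

def create_concept(schema: Schema, name: str, category: ConceptCategory) -> Concept:
    """Add a fresh concept; its name is registered as the PREFERRED variant.

    Ids are sanitized names with a monotonic suffix on collision; names need
    not be unique, ids are the referential keys.
    """
    name = collapse_ws(name)
    if not name:
        raise ValidationError("concept name must be non-empty")
    base = slug(name)
    existing = {c.id for c in schema.concepts}
    cid, n = base, 1
    while cid in existing:
        n += 1
        cid = f"{base}_{n}"
    concept = Concept(id=cid, name=name, category=category)
    concept.variants.append(LexicalVariant(name, VariantKind.PREFERRED, VariantSource.USER))
    schema.concepts.append(concept)
    schema.touch()
    return concept


def set_semantic_type(
    concept: Concept,
    semantic_type: str,
    registry: ModifierRegistry | None = None,
    *,
    force: bool = False,
    source: VariantSource = VariantSource.USER,
) -> Concept:
    """Assign a semantic type.

    Fails atomically with :class:`ConflictError` if existing semantic-modifier
    assignments are not allowed under the new type, unless ``force`` strips
    the offenders.  Patient Demographic is reserved for PERSON concepts and
    vice versa.
    """
    reg = registry or load_registry()
    st = reg.semantic_type(semantic_type)
    if st.category != concept.category.value:
        raise ValidationError(
            f"semantic type {st.name!r} requires a {st.category} concept, but "
            f"{concept.name!r} is {concept.category.value}"
        )
    allowed = {spec.name.casefold() for spec in reg.allowed_modifier_classes(st.name)}
    offenders = [a.modifier_class for a in concept.semantic_modifiers
                 if a.modifier_class.casefold() not in allowed]
    if offenders and not force:
        raise ConflictError(
            f"cannot retype {concept.name!r} to {st.name!r}: existing modifier "
            f"assignment(s) {', '.join(offenders)} are not allowed under the new type",
            offenders=offenders,
        )
    if offenders:
        concept.semantic_modifiers = [
            a for a in concept.semantic_modifiers if a.modifier_class not in offenders
        ]
    concept.semantic_type = st.name
    concept.semantic_type_source = source
    return concept


def clear_semantic_type(concept: Concept) -> Concept:
    if concept.semantic_modifiers:
        raise ConflictError(
            "cannot clear the semantic type while semantic modifiers are assigned",
            offenders=[a.modifier_class for a in concept.semantic_modifiers],
        )
    concept.semantic_type = None
    concept.semantic_type_source = None
    return concept


def set_shared_modifier(
    concept: Concept, category: str, value: str, registry: ModifierRegistry | None = None
) -> Concept:
    """Assign a shared modifier (EVENT concepts only); one assignment per
    category, replace on repeat."""
    reg = registry or load_registry()
    if concept.category is not ConceptCategory.EVENT:
        raise ValidationError(
            f"shared modifiers apply to EVENT concepts only; {concept.name!r} is "
            f"{concept.category.value}"
        )
    canonical_category, values = reg.shared_category(category)
    canonical = reg.canonical_shared_value(canonical_category, value)
    if canonical is None:
        raise ValidationError(
            f"{value!r} is not a legal {canonical_category} value; legal values: "
            f"{', '.join(values)}"
        )
    concept.shared_modifiers = [
        a for a in concept.shared_modifiers if a.category != canonical_category
    ]
    concept.shared_modifiers.append(SharedModifierAssignment(canonical_category, canonical))
    concept.shared_modifiers.sort(key=lambda a: a.category)
    return concept


def set_semantic_modifier(
    concept: Concept,
    modifier_class: str,
    value: ModifierValue,
    registry: ModifierRegistry | None = None,
) -> Concept:
    """Assign a semantic modifier value.

    The class must be allowed under the concept's semantic type.  CLOSED
    classes accept only their enumerated members; OPEN classes accept the
    seeded members or free text; UNLIMITED classes accept free text or a
    :class:`NumericRange`.  One assignment per class, replace on repeat.
    """
    reg = registry or load_registry()
    if concept.semantic_type is None:
        raise ValidationError(
            f"assign a semantic type to {concept.name!r} before adding semantic modifiers"
        )
    spec = reg.modifier_class(modifier_class, concept.semantic_type)
    if isinstance(value, NumericRange):
        if not spec.unlimited:
            raise ValidationError(
                f"numeric ranges are only supported on value-typed (unlimited) classes; "
                f"{spec.name!r} is {spec.closure}"
            )
    else:
        value = collapse_ws(str(value))
        if not value:
            raise ValidationError("modifier value must be non-empty")
        if not spec.accepts(value):
            raise ValidationError(
                f"{value!r} is not a legal value for {spec.id!r}; legal values: "
                f"{', '.join(spec.values)}"
            )
        value = spec.canonical_value(value)
    concept.semantic_modifiers = [
        a for a in concept.semantic_modifiers if a.modifier_class != spec.name
    ]
    concept.semantic_modifiers.append(SemanticModifierAssignment(spec.name, value))
    concept.semantic_modifiers.sort(key=lambda a: a.modifier_class)
    return concept


def add_lexical_variant(
    concept: Concept,
    text: str,
    kind: VariantKind = VariantKind.SYNONYM,
    source: VariantSource = VariantSource.USER,
) -> Concept:
    """Add a lexical variant; duplicates (case/whitespace-insensitive) are
    dropped, and a new PREFERRED variant demotes the previous one to SYNONYM."""
    variant = LexicalVariant(text, kind, source)
    if any(v.key == variant.key for v in concept.variants):
        return concept
    if kind is VariantKind.PREFERRED:
        concept.variants = [
            replace(v, kind=VariantKind.SYNONYM) if v.kind is VariantKind.PREFERRED else v
            for v in concept.variants
        ]
    concept.variants.append(variant)
    concept.variants.sort(key=LexicalVariant.sort_key)
    return concept


def remove_lexical_variant(concept: Concept, text: str) -> Concept:
    key = collapse_ws(text).casefold()
    kept = [v for v in concept.variants if v.key != key]
    if len(kept) == len(concept.variants):
        raise RegistryLookupError(f"{concept.name!r} has no variant {text!r}")
    concept.variants = kept
    return concept


def set_modifier_cue(
    schema: Schema,
    value_token: str,
    text: str,
    kind: VariantKind = VariantKind.SYNONYM,
) -> Schema:
    """Register a surface cue for a modifier value (e.g. ``'l'`` as an
    abbreviation for the ``Left_Body_Side`` value)."""
    variant = LexicalVariant(text, kind, VariantSource.USER)
    cues = schema.modifier_cues.setdefault(value_token, [])
    if any(v.key == variant.key for v in cues):
        return schema
    cues.append(variant)
    cues.sort(key=LexicalVariant.sort_key)
    return schema


# ---------------------------------------------------------------------------
# representability checking
# ---------------------------------------------------------------------------

class Representability(Enum):
    COMPLETE = "COMPLETE"
    PARTIAL = "PARTIAL"
    UNSUPPORTED = "UNSUPPORTED"


#: reason codes
MISSING_MODIFIER_TYPE = "MISSING_MODIFIER_TYPE"
UNSUPPORTED_RELATION = "UNSUPPORTED_RELATION"
UNSUPPORTED_DISJUNCTION = "UNSUPPORTED_DISJUNCTION"


@dataclass(frozen=True)
class RepresentabilityReport:
    status: Representability
    reasons: tuple[str, ...] = ()
    details: tuple[str, ...] = ()


def check_representability(
    request: dict[str, Any], registry: ModifierRegistry | None = None
) -> RepresentabilityReport:
    """Decide whether a structured concept request is expressible as a single
    concept under the constrained model.

    Request layout (a plain mapping)::

        {"name": str, "category": "EVENT"|"PERSON", "semantic_type": str?,
         "semantic_modifiers": [{"class": str, "value": x} or {"class": str, "any_of": [...]}],
         "shared_modifiers":   [{"category": str, "value": x} or {..., "any_of": [...]}],
         "links": [subrequest, ...]}

    ``links`` express relations between concepts (not supported: the model has
    no concept-linking constructs, so the parts could only be created as
    separate concepts); ``any_of`` expresses a value disjunction (not
    supported at all).  Modifier classes absent from the taxonomy yield
    MISSING_MODIFIER_TYPE and a PARTIAL verdict.
    """
    reg = registry or load_registry()
    if not isinstance(request, dict) or "name" not in request:
        raise ParseError("request must be a mapping with at least a 'name' key")
    reasons: list[str] = []
    details: list[str] = []

    if request.get("links"):
        reasons.append(UNSUPPORTED_RELATION)
        details.append(
            "linked sub-concepts cannot be joined into a single concept; they could "
            "only be created as separate concepts"
        )
    semantic_type = request.get("semantic_type")
    if semantic_type is not None:
        try:
            reg.semantic_type(semantic_type)
        except RegistryLookupError:
            reasons.append(MISSING_MODIFIER_TYPE)
            details.append(f"semantic type {semantic_type!r} not in the taxonomy")
            semantic_type = None

    for item in request.get("semantic_modifiers", []):
        if not isinstance(item, dict) or "class" not in item:
            raise ParseError("each semantic modifier needs a 'class' key")
        if "any_of" in item:
            reasons.append(UNSUPPORTED_DISJUNCTION)
            details.append(f"disjunction over {item['class']!r} values is not representable")
            continue
        try:
            spec = reg.modifier_class(item["class"], semantic_type)
        except RegistryLookupError:
            reasons.append(MISSING_MODIFIER_TYPE)
            details.append(f"modifier class {item['class']!r} not available")
            continue
        value = item.get("value")
        if isinstance(value, str) and not spec.accepts(value):
            reasons.append(MISSING_MODIFIER_TYPE)
            details.append(f"value {value!r} outside the closed set of {spec.id!r}")

    for item in request.get("shared_modifiers", []):
        if not isinstance(item, dict) or "category" not in item:
            raise ParseError("each shared modifier needs a 'category' key")
        if "any_of" in item:
            reasons.append(UNSUPPORTED_DISJUNCTION)
            details.append(f"disjunction over {item['category']!r} values is not representable")
            continue
        try:
            canonical = reg.canonical_shared_value(item["category"], str(item.get("value", "")))
        except RegistryLookupError:
            reasons.append(MISSING_MODIFIER_TYPE)
            details.append(f"shared category {item['category']!r} not in the catalog")
            continue
        if canonical is None:
            reasons.append(MISSING_MODIFIER_TYPE)
            details.append(
                f"value {item.get('value')!r} outside the closed {item['category']} set"
            )

    unique_reasons = tuple(dict.fromkeys(reasons))
    if not unique_reasons:
        status = Representability.COMPLETE
    elif UNSUPPORTED_DISJUNCTION in unique_reasons:
        status = Representability.UNSUPPORTED
    else:
        status = Representability.PARTIAL
    return RepresentabilityReport(status, unique_reasons, tuple(details))


# ---------------------------------------------------------------------------
# schema validation and JSON persistence
# ---------------------------------------------------------------------------

def validate_schema(schema: Schema, registry: ModifierRegistry | None = None) -> list[str]:
    """Re-check every data-model invariant; returns a list of problems
    (empty when the schema is valid)."""
    reg = registry or load_registry()
    problems: list[str] = []
    seen_ids: set[str] = set()
    for c in schema.concepts:
        where = f"concept {c.id!r}"
        if c.id in seen_ids:
            problems.append(f"{where}: duplicate id")
        seen_ids.add(c.id)
        if len(c.variants_of_kind(VariantKind.PREFERRED)) > 1:
            problems.append(f"{where}: more than one PREFERRED variant")
        keys = [v.key for v in c.variants]
        if len(keys) != len(set(keys)):
            problems.append(f"{where}: duplicate lexical variants")
        if c.semantic_type is not None:
            try:
                st = reg.semantic_type(c.semantic_type)
            except RegistryLookupError:
                problems.append(f"{where}: unknown semantic type {c.semantic_type!r}")
                st = None
            if st is not None and st.category != c.category.value:
                problems.append(
                    f"{where}: semantic type {st.name!r} incompatible with category "
                    f"{c.category.value}"
                )
            allowed = {s.name for s in reg.allowed_modifier_classes(c.semantic_type)} if st else set()
        else:
            allowed = set()
        for a in c.semantic_modifiers:
            if c.semantic_type is None:
                problems.append(f"{where}: semantic modifier {a.modifier_class!r} without a type")
            elif a.modifier_class not in allowed:
                problems.append(
                    f"{where}: modifier class {a.modifier_class!r} not allowed under "
                    f"{c.semantic_type!r}"
                )
        classes = [a.modifier_class for a in c.semantic_modifiers]
        if len(classes) != len(set(classes)):
            problems.append(f"{where}: repeated semantic modifier class")
        if c.shared_modifiers and c.category is not ConceptCategory.EVENT:
            problems.append(f"{where}: shared modifiers on a non-EVENT concept")
        for a in c.shared_modifiers:
            if reg.canonical_shared_value(a.category, a.value) != a.value:
                problems.append(f"{where}: illegal shared value {a.value!r} for {a.category!r}")
        cats = [a.category for a in c.shared_modifiers]
        if len(cats) != len(set(cats)):
            problems.append(f"{where}: repeated shared modifier category")
    return problems


def _variant_to_json(v: LexicalVariant) -> dict:
    return {"text": v.text, "kind": v.kind.value, "source": v.source.value}


def _variant_from_json(d: dict) -> LexicalVariant:
    return LexicalVariant(d["text"], VariantKind(d["kind"]), VariantSource(d["source"]))


def _value_to_json(value: ModifierValue) -> Any:
    if isinstance(value, NumericRange):
        return {
            "lower": None if value.lower is None else str(value.lower),
            "upper": None if value.upper is None else str(value.upper),
            "unit": value.unit,
        }
    return value


def _value_from_json(raw: Any) -> ModifierValue:
    if isinstance(raw, dict):
        return NumericRange(
            None if raw["lower"] is None else Decimal(raw["lower"]),
            None if raw["upper"] is None else Decimal(raw["upper"]),
            raw.get("unit", ""),
        )
    return raw


def schema_to_dict(schema: Schema) -> dict:
    return {
        "format": SCHEMA_FORMAT,
        "version": SCHEMA_FORMAT_VERSION,
        "name": schema.name,
        "description": schema.description,
        "created": schema.created,
        "modified": schema.modified,
        "modifier_cues": {
            key: [_variant_to_json(v) for v in cues]
            for key, cues in sorted(schema.modifier_cues.items())
        },
        "concepts": [
            {
                "id": c.id,
                "name": c.name,
                "category": c.category.value,
                "semantic_type": c.semantic_type,
                "semantic_type_source": (
                    None if c.semantic_type_source is None else c.semantic_type_source.value
                ),
                "binding": (
                    None
                    if c.binding is None
                    else {
                        "cui": c.binding.cui,
                        "preferred_term": c.binding.preferred_term,
                        "definition": c.binding.definition,
                    }
                ),
                "variants": [_variant_to_json(v) for v in c.variants],
                "semantic_modifiers": [
                    {"class": a.modifier_class, "value": _value_to_json(a.value)}
                    for a in c.semantic_modifiers
                ],
                "shared_modifiers": [
                    {"category": a.category, "value": a.value} for a in c.shared_modifiers
                ],
            }
            for c in schema.concepts
        ],
    }


def schema_from_dict(data: dict) -> Schema:
    if data.get("format") != SCHEMA_FORMAT:
        raise ParseError(f"not a {SCHEMA_FORMAT} document (format={data.get('format')!r})")
    if data.get("version") != SCHEMA_FORMAT_VERSION:
        raise ParseError(f"unsupported schema format version {data.get('version')!r}")
    schema = Schema(
        name=data["name"],
        description=data.get("description"),
        created=data.get("created", ""),
        modified=data.get("modified", ""),
    )
    schema.modifier_cues = {
        key: sorted((_variant_from_json(v) for v in cues), key=LexicalVariant.sort_key)
        for key, cues in data.get("modifier_cues", {}).items()
    }
    for cd in data.get("concepts", []):
        binding = cd.get("binding")
        concept = Concept(
            id=cd["id"],
            name=cd["name"],
            category=ConceptCategory(cd["category"]),
            semantic_type=cd.get("semantic_type"),
            semantic_type_source=(
                None
                if cd.get("semantic_type_source") is None
                else VariantSource(cd["semantic_type_source"])
            ),
            binding=None if binding is None else TerminologyBinding(**binding),
            variants=sorted(
                (_variant_from_json(v) for v in cd.get("variants", [])),
                key=LexicalVariant.sort_key,
            ),
            semantic_modifiers=sorted(
                (
                    SemanticModifierAssignment(a["class"], _value_from_json(a["value"]))
                    for a in cd.get("semantic_modifiers", [])
                ),
                key=lambda a: a.modifier_class,
            ),
            shared_modifiers=sorted(
                (
                    SharedModifierAssignment(a["category"], a["value"])
                    for a in cd.get("shared_modifiers", [])
                ),
                key=lambda a: a.category,
            ),
        )
        schema.concepts.append(concept)
    return schema


def save_schema(schema: Schema, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(schema_to_dict(schema), indent=2, ensure_ascii=False) + "\n", "utf-8"
    )


def load_schema(path: str | Path) -> Schema:
    try:
        data = json.loads(Path(path).read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return schema_from_dict(data)


def referenced_value_tokens(schema: Schema) -> dict[str, tuple[str, str]]:
    """Map each modifier value token referenced by any concept to its
    (class-or-category name, display value)."""
    out: dict[str, tuple[str, str]] = {}
    for c in schema.concepts:
        for a in c.semantic_modifiers:
            out[a.value_token] = (a.modifier_class, a.value_display())
        for a in c.shared_modifiers:
            out[a.value_token] = (a.category, a.value)
    return out
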