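"""Modifier taxonomy registry.

The constrained authoring model rests on a fixed taxonomy: 12 semantic types,
each owning an ordered list of semantic-modifier classes, plus 7 shared
modifier categories (certainty, experiencer, temporality, contextual
aspect/modality, degree, permanence) available to every Event concept.  The
taxonomy ships as a packaged JSON file (``data/registry.json``) so it can be
audited without reading code, and is loaded once at import into an immutable
:class:`ModifierRegistry`.

Closure semantics per modifier class:

``CLOSED``
    the printed value set is complete; validation rejects anything else.
``OPEN``
    the declared cardinality exceeds the values that could be seeded; the
    seeded values are guaranteed members, and free-text values beyond the
    seed are accepted.
``UNLIMITED``
    a value-typed class (dosage, lab value, ...) accepting free text or a
    :class:`~semschema.datamodel.NumericRange`.

Same-named classes under different semantic types (e.g. *Severity* under
Problem and under Sign or Symptom) are distinct, type-scoped specs that
happen to share a value set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import pandas as pd

from ._text import token
from .errors import RegistryLookupError, SemSchemaError

UNLIMITED = "unlimited"

#: closure flags
CLOSED, OPEN = "CLOSED", "OPEN"


@dataclass(frozen=True)
class ModifierClassSpec:
    """One semantic-modifier class owned by one semantic type."""

    name: str
    owning_semantic_type: str
    declared_cardinality: int | str  # positive int or UNLIMITED
    closure: str  # CLOSED | OPEN | UNLIMITED
    values: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.closure == CLOSED and len(self.values) != self.declared_cardinality:
            raise SemSchemaError(
                f"CLOSED class {self.name!r} has {len(self.values)} values but "
                f"declared cardinality {self.declared_cardinality}"
            )
        if self.closure == "UNLIMITED" and self.declared_cardinality != UNLIMITED:
            raise SemSchemaError(f"UNLIMITED class {self.name!r} must declare 'unlimited'")

    @property
    def id(self) -> str:
        """Type-qualified identifier, e.g. ``'Problem/Severity'``."""
        return f"{self.owning_semantic_type}/{self.name}"

    @property
    def unlimited(self) -> bool:
        return self.closure == "UNLIMITED"

    def accepts(self, value: str) -> bool:
        """Whether a plain string value is legal for this class."""
        if self.closure == CLOSED:
            return value.casefold() in {v.casefold() for v in self.values}
        return bool(value.strip())

    def canonical_value(self, value: str) -> str:
        """Map a case-variant of a seeded value onto its canonical spelling."""
        for v in self.values:
            if v.casefold() == value.strip().casefold():
                return v
        return value.strip()


@dataclass(frozen=True)
class SemanticType:
    name: str
    category: str  # PERSON | EVENT — which concept category may carry this type
    classes: tuple[ModifierClassSpec, ...]


@dataclass(frozen=True)
class ModifierRegistry:
    semantic_types: tuple[SemanticType, ...]
    shared_catalog: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.semantic_types) == 0:
            raise SemSchemaError("registry is empty")

    # -- semantic types -----------------------------------------------------
    @property
    def type_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.semantic_types)

    def semantic_type(self, name: str) -> SemanticType:
        for t in self.semantic_types:
            if t.name == name:
                return t
        raise RegistryLookupError(
            f"unknown semantic type {name!r}; known types: {', '.join(self.type_names)}"
        )

    def allowed_modifier_classes(self, semantic_type: str) -> tuple[ModifierClassSpec, ...]:
        """The modifier classes a concept of this semantic type may carry,
        in stable (taxonomy) order."""
        return self.semantic_type(semantic_type).classes

    # -- modifier classes ---------------------------------------------------
    def modifier_class(self, modifier_class: str, semantic_type: str | None = None) -> ModifierClassSpec:
        """Resolve a class by name.

        ``modifier_class`` may be a type-qualified id (``'Problem/Severity'``)
        or a bare name; a bare name requires either ``semantic_type`` or that
        the name be unambiguous across the taxonomy up to shared value sets.
        """
        if "/" in modifier_class and semantic_type is None:
            semantic_type, modifier_class = modifier_class.split("/", 1)
        if semantic_type is not None:
            for spec in self.allowed_modifier_classes(semantic_type):
                if spec.name.casefold() == modifier_class.casefold():
                    return spec
            allowed = ", ".join(s.name for s in self.allowed_modifier_classes(semantic_type))
            raise RegistryLookupError(
                f"modifier class {modifier_class!r} is not available under semantic type "
                f"{semantic_type!r}; available classes: {allowed}"
            )
        hits = [s for s in self.iter_class_specs() if s.name.casefold() == modifier_class.casefold()]
        if not hits:
            raise RegistryLookupError(f"unknown modifier class {modifier_class!r}")
        distinct = {(s.name, s.declared_cardinality, s.closure, s.values) for s in hits}
        if len(distinct) > 1:
            ids = ", ".join(s.id for s in hits)
            raise RegistryLookupError(
                f"modifier class {modifier_class!r} is ambiguous across semantic types "
                f"({ids}); qualify it as 'Type/Class'"
            )
        return hits[0]

    def allowed_values(
        self, modifier_class: str, semantic_type: str | None = None
    ) -> tuple[tuple[str, ...], str, int | str]:
        """``(values, closure, declared_cardinality)`` for a class."""
        spec = self.modifier_class(modifier_class, semantic_type)
        return spec.values, spec.closure, spec.declared_cardinality

    def iter_class_specs(self) -> Iterator[ModifierClassSpec]:
        for t in self.semantic_types:
            yield from t.classes

    # -- shared modifiers ---------------------------------------------------
    def shared_modifier_catalog(self) -> dict[str, tuple[str, ...]]:
        return dict(self.shared_catalog)

    def shared_category(self, category: str) -> tuple[str, tuple[str, ...]]:
        for name, values in self.shared_catalog.items():
            if name.casefold() == category.casefold():
                return name, values
        raise RegistryLookupError(
            f"unknown shared modifier category {category!r}; known categories: "
            f"{', '.join(self.shared_catalog)}"
        )

    def canonical_shared_value(self, category: str, value: str) -> str | None:
        """Canonical spelling of a shared value, or None if not a member."""
        _, values = self.shared_category(category)
        for v in values:
            if v.casefold() == value.strip().casefold():
                return v
        return None

    # -- value-token resolution (used by the extraction engine) -------------
    def value_token_index(self) -> dict[str, str]:
        """Map value tokens to the modifier class/category they belong to.

        Shared values map as bare tokens (``'Definite_Negated_Existence' ->
        'Certainty'``); seeded semantic values map as ``Value_Class`` tokens
        (``'Mild_Severity' -> 'Severity'``).
        """
        index: dict[str, str] = {}
        for category, values in self.shared_catalog.items():
            for v in values:
                index[token(v)] = category
        for spec in self.iter_class_specs():
            for v in spec.values:
                index[f"{token(v)}_{token(spec.name)}"] = spec.name
        return index

    def class_tokens(self) -> dict[str, str]:
        """Map class-name tokens back to class display names."""
        return {token(s.name): s.name for s in self.iter_class_specs()}

    # -- reporting ----------------------------------------------------------
    def report(self) -> pd.DataFrame:
        """One row per (semantic type, modifier class): declared cardinality,
        seeded-value count and closure flag."""
        rows = [
            {
                "semantic_type": spec.owning_semantic_type,
                "modifier_class": spec.name,
                "declared_cardinality": spec.declared_cardinality,
                "n_seeded_values": len(spec.values),
                "closure": spec.closure,
            }
            for spec in self.iter_class_specs()
        ]
        if not rows:
            raise SemSchemaError("registry has no modifier classes; refusing partial report")
        return pd.DataFrame(rows)


def registry_report(registry: ModifierRegistry | None = None) -> pd.DataFrame:
    return (registry or load_registry()).report()


def _build(raw: dict) -> ModifierRegistry:
    types = []
    for t in raw["semantic_types"]:
        classes = tuple(
            ModifierClassSpec(
                name=c["name"],
                owning_semantic_type=t["name"],
                declared_cardinality=c["declared_cardinality"],
                closure=c["closure"],
                values=tuple(c["values"]),
            )
            for c in t["classes"]
        )
        types.append(SemanticType(name=t["name"], category=t["category"], classes=classes))
    shared = {k: tuple(v) for k, v in raw["shared_modifiers"].items()}
    return ModifierRegistry(semantic_types=tuple(types), shared_catalog=shared)


def load_registry() -> ModifierRegistry:
    """Load the packaged taxonomy. Pure: two loads compare equal."""
    text = resources.files("semschema").joinpath("data/registry.json").read_text("utf-8")
    return _build(json.loads(text))


#: The semantic type reserved for PERSON concepts.
PERSON_TYPE = "Patient Demographic"
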