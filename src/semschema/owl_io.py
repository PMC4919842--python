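"""OWL serialization of schemas and lossless re-import.

A schema exports to one OWL 2 ontology that imports the base *schema
ontology* (the fixed vocabulary of semantic-category classes, attribute
properties and shared-modifier value classes) and encodes:

* each concept as a named class, ``rdfs:subClassOf`` its semantic-category
  class (``mild aneurysm rdfs:subClassOf so:Problem``);
* concept metadata — preferred term, synonyms, abbreviations, misspellings,
  CUI, definition — as annotation properties;
* each semantic-modifier assignment as an existential restriction
  ``so:hasSemAttribute some Mild_Severity`` whose filler class is composed as
  ``ValueToken_ClassToken`` and subclasses the modifier-class class;
* each shared-modifier assignment as ``so:hasSharedAttribute some
  Definite_Negated_Existence``;
* numeric ranges as an existential restriction onto an intersection of the
  modifier-class class with ``so:hasLowerBound``/``so:hasUpperBound`` (and
  ``so:hasUnit``) value restrictions.

Axioms outside this dialect — hand-added classes, SWRL rules and the like —
are captured on import as an opaque *residue* graph and re-emitted verbatim
by the next export, so documents edited in an external OWL editor survive a
round trip.  Default serialization is RDF/XML; Turtle is the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.compare import graph_diff, to_canonical_graph, to_isomorphic
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS, XSD

from ._text import token
from .datamodel import (
    Concept,
    ConceptCategory,
    LexicalVariant,
    NumericRange,
    Schema,
    SemanticModifierAssignment,
    SharedModifierAssignment,
    TerminologyBinding,
    VariantKind,
    VariantSource,
)
from .errors import DialectError, ExportError, ParseError
from .registry import ModifierRegistry, load_registry

#: The schema-ontology namespace this dialect subclasses and imports.
SCHEMA_ONTOLOGY_IRI = "https://w3id.org/semschema/schema-ontology"
SO = Namespace(SCHEMA_ONTOLOGY_IRI + "#")

_SERIALIZATIONS = {"RDF_XML": "xml", "TURTLE": "turtle"}

# (kind, source) -> annotation property for concept lexical variants
_VARIANT_PROPS: dict[tuple[VariantKind, VariantSource], URIRef] = {
    (VariantKind.PREFERRED, VariantSource.USER): SO.preferredTerm,
    (VariantKind.PREFERRED, VariantSource.TERMINOLOGY): SO.importedPreferredTerm,
    (VariantKind.SYNONYM, VariantSource.USER): SO.synonym,
    (VariantKind.SYNONYM, VariantSource.TERMINOLOGY): SO.importedSynonym,
    (VariantKind.ABBREVIATION, VariantSource.USER): SO.abbreviation,
    (VariantKind.ABBREVIATION, VariantSource.TERMINOLOGY): SO.importedAbbreviation,
    (VariantKind.MISSPELLING, VariantSource.USER): SO.misspelling,
    (VariantKind.MISSPELLING, VariantSource.TERMINOLOGY): SO.importedMisspelling,
}
_VARIANT_PROPS_INV = {v: k for k, v in _VARIANT_PROPS.items()}

# kind -> annotation property for modifier-value cue variants (always USER)
_CUE_PROPS: dict[VariantKind, URIRef] = {
    VariantKind.PREFERRED: SO.cuePreferredTerm,
    VariantKind.SYNONYM: SO.cue,
    VariantKind.ABBREVIATION: SO.cueAbbreviation,
    VariantKind.MISSPELLING: SO.cueMisspelling,
}
_CUE_PROPS_INV = {v: k for k, v in _CUE_PROPS.items()}


@dataclass(frozen=True)
class OwlExportProfile:
    base_iri: str = "https://w3id.org/semschema/schemas/default#"
    schema_ontology_iri: str = SCHEMA_ONTOLOGY_IRI
    serialization: str = "RDF_XML"

    def __post_init__(self) -> None:
        if not (self.base_iri.endswith("#") or self.base_iri.endswith("/")):
            raise ExportError(f"base_iri must end in '/' or '#': {self.base_iri!r}")
        if "://" not in self.base_iri:
            raise ExportError(f"base_iri must be an absolute IRI: {self.base_iri!r}")
        if self.serialization not in _SERIALIZATIONS:
            raise ExportError(
                f"unknown serialization {self.serialization!r}; "
                f"choose one of {', '.join(_SERIALIZATIONS)}"
            )

    @property
    def ontology_iri(self) -> URIRef:
        return URIRef(self.base_iri.rstrip("#/"))


@dataclass
class ImportResult:
    schema: Schema
    residue: Graph
    profile: OwlExportProfile

    def __iter__(self):  # allow  schema, residue, profile = import_schema(...)
        return iter((self.schema, self.residue, self.profile))


def _bind_namespaces(g: Graph, profile: OwlExportProfile) -> None:
    g.bind("so", SO)
    g.bind("owl", OWL)
    g.bind("dcterms", DCTERMS)
    g.bind("", Namespace(profile.base_iri))


def _add_semantic_restriction(
    g: Graph, concept_iri: URIRef, assignment: SemanticModifierAssignment
) -> None:
    restriction = BNode()
    g.add((concept_iri, RDFS.subClassOf, restriction))
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, SO.hasSemAttribute))
    class_iri = SO[token(assignment.modifier_class)]
    value = assignment.value
    if isinstance(value, NumericRange):
        filler = BNode()
        g.add((filler, RDF.type, OWL.Class))
        members: list = [class_iri]
        if value.lower is not None:
            members.append(_value_restriction(g, SO.hasLowerBound, Literal(value.lower, datatype=XSD.decimal)))
        if value.upper is not None:
            members.append(_value_restriction(g, SO.hasUpperBound, Literal(value.upper, datatype=XSD.decimal)))
        if value.unit:
            members.append(_value_restriction(g, SO.hasUnit, Literal(value.unit)))
        Collection(g, _fresh_list_node(g, filler), members)
        g.add((restriction, OWL.someValuesFrom, filler))
    else:
        filler = SO[assignment.value_token]
        g.add((filler, RDF.type, OWL.Class))
        g.add((filler, RDFS.subClassOf, class_iri))
        g.add((filler, RDFS.label, Literal(value)))
        g.add((filler, SO.modifierClass, Literal(assignment.modifier_class)))
        g.add((restriction, OWL.someValuesFrom, filler))


def _fresh_list_node(g: Graph, filler: BNode) -> BNode:
    node = BNode()
    g.add((filler, OWL.intersectionOf, node))
    return node


def _value_restriction(g: Graph, prop: URIRef, literal: Literal) -> BNode:
    r = BNode()
    g.add((r, RDF.type, OWL.Restriction))
    g.add((r, OWL.onProperty, prop))
    g.add((r, OWL.hasValue, literal))
    return r


def _add_shared_restriction(
    g: Graph, concept_iri: URIRef, assignment: SharedModifierAssignment
) -> None:
    restriction = BNode()
    g.add((concept_iri, RDFS.subClassOf, restriction))
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, SO.hasSharedAttribute))
    filler = SO[assignment.value_token]
    g.add((filler, RDF.type, OWL.Class))
    g.add((filler, RDFS.subClassOf, SO[token(assignment.category)]))
    g.add((filler, RDFS.label, Literal(assignment.value)))
    g.add((restriction, OWL.someValuesFrom, filler))


def build_export_graph(
    schema: Schema,
    profile: OwlExportProfile | None = None,
    registry: ModifierRegistry | None = None,
    residue: Graph | None = None,
) -> Graph:
    """Serialize a schema to an rdflib graph (deterministic triple order)."""
    profile = profile or OwlExportProfile()
    untyped = [c.id for c in schema.concepts if c.semantic_type is None]
    if untyped:
        raise ExportError(
            "cannot export: concept(s) without a semantic type: " + ", ".join(untyped),
            offenders=untyped,
        )
    g = Graph()
    _bind_namespaces(g, profile)
    ont = profile.ontology_iri
    g.add((ont, RDF.type, OWL.Ontology))
    g.add((ont, OWL.imports, URIRef(profile.schema_ontology_iri)))
    g.add((ont, RDFS.label, Literal(schema.name)))
    if schema.description:
        g.add((ont, RDFS.comment, Literal(schema.description)))
    g.add((ont, DCTERMS.created, Literal(schema.created)))
    g.add((ont, DCTERMS.modified, Literal(schema.modified)))

    for index, concept in enumerate(schema.concepts):
        ciri = URIRef(profile.base_iri + concept.id)
        g.add((ciri, RDF.type, OWL.Class))
        g.add((ciri, RDFS.subClassOf, SO[token(concept.semantic_type)]))
        g.add((ciri, RDFS.label, Literal(concept.name)))
        g.add((ciri, SO.conceptId, Literal(concept.id)))
        g.add((ciri, SO.conceptCategory, Literal(concept.category.value)))
        g.add((ciri, SO.conceptIndex, Literal(index, datatype=XSD.integer)))
        if concept.semantic_type_source is not None:
            g.add((ciri, SO.semanticTypeSource, Literal(concept.semantic_type_source.value)))
        for variant in concept.variants:
            g.add((ciri, _VARIANT_PROPS[(variant.kind, variant.source)], Literal(variant.text)))
        if concept.binding is not None:
            g.add((ciri, SO.cui, Literal(concept.binding.cui)))
            g.add((ciri, SO.boundPreferredTerm, Literal(concept.binding.preferred_term)))
            if concept.binding.definition is not None:
                g.add((ciri, SO.definition, Literal(concept.binding.definition)))
        for assignment in concept.semantic_modifiers:
            _add_semantic_restriction(g, ciri, assignment)
        for assignment in concept.shared_modifiers:
            _add_shared_restriction(g, ciri, assignment)

    for key in sorted(schema.modifier_cues):
        node = SO[key]
        for cue in schema.modifier_cues[key]:
            g.add((node, _CUE_PROPS[cue.kind], Literal(cue.text)))

    if residue is not None:
        for triple in residue:
            g.add(triple)
    return g


def export_schema(
    schema: Schema,
    profile: OwlExportProfile | None = None,
    path: str | Path | None = None,
    registry: ModifierRegistry | None = None,
    residue: Graph | None = None,
) -> str:
    """Export a schema to an OWL document; returns the serialized text and
    writes it to ``path`` when given.  Output is stable for fixed input."""
    profile = profile or OwlExportProfile()
    g = build_export_graph(schema, profile, registry, residue=residue)
    # canonical blank-node labels + sorted triple insertion => stable bytes
    canonical = to_canonical_graph(g)
    stable = Graph()
    _bind_namespaces(stable, profile)
    for triple in sorted(canonical):
        stable.add(triple)
    text = stable.serialize(format=_SERIALIZATIONS[profile.serialization])
    if path is not None:
        Path(path).write_text(text, "utf-8")
    return text


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _parse_document(path: str | Path) -> Graph:
    g = Graph()
    text = Path(path).read_text("utf-8")
    errors = []
    for fmt in ("xml", "turtle"):
        try:
            g.parse(data=text, format=fmt)
            return g
        except Exception as exc:  # rdflib raises assorted parse exceptions
            errors.append(f"{fmt}: {exc}")
            g = Graph()
    raise ParseError(f"cannot parse {path} as RDF/XML or Turtle ({'; '.join(errors)})")


def _literal(g: Graph, subject, prop) -> str | None:
    value = g.value(subject, prop)
    return None if value is None else str(value)


def _parse_range_filler(g: Graph, filler, class_tokens: dict[str, str]) -> SemanticModifierAssignment:
    list_node = g.value(filler, OWL.intersectionOf)
    if list_node is None:
        raise DialectError("anonymous semantic-attribute filler without owl:intersectionOf")
    members = list(Collection(g, list_node))
    class_name = None
    lower = upper = None
    unit = ""
    for member in members:
        if isinstance(member, URIRef):
            local = str(member).rsplit("#", 1)[-1]
            class_name = class_tokens.get(local, local)
        else:
            prop = g.value(member, OWL.onProperty)
            raw = g.value(member, OWL.hasValue)
            if prop == SO.hasLowerBound:
                lower = Decimal(str(raw))
            elif prop == SO.hasUpperBound:
                upper = Decimal(str(raw))
            elif prop == SO.hasUnit:
                unit = str(raw)
    if class_name is None:
        raise DialectError("numeric-range filler names no modifier class")
    return SemanticModifierAssignment(class_name, NumericRange(lower, upper, unit))


def import_schema(path: str | Path, registry: ModifierRegistry | None = None) -> ImportResult:
    """Parse an OWL document in the dialect back into a schema.

    Returns the reconstructed :class:`Schema`, the *residue* graph of triples
    outside the modeled subset (preserved verbatim by the next export), and
    the :class:`OwlExportProfile` recovered from the document.
    """
    reg = registry or load_registry()
    g = _parse_document(path)

    so_used = any(str(t).startswith(str(SO)) for triple in g for t in triple)
    ontologies = sorted(set(g.subjects(RDF.type, OWL.Ontology)))
    imported = [o for o in ontologies if (o, OWL.imports, URIRef(SCHEMA_ONTOLOGY_IRI)) in g]
    if not imported and not so_used:
        raise DialectError(
            "document neither imports the schema ontology nor uses its vocabulary"
        )
    ont = imported[0] if imported else (ontologies[0] if ontologies else None)

    schema = Schema(
        name=_literal(g, ont, RDFS.label) or "",
        description=_literal(g, ont, RDFS.comment),
        created=_literal(g, ont, DCTERMS.created) or "",
        modified=_literal(g, ont, DCTERMS.modified) or "",
    )

    type_tokens = {token(t.name): t.name for t in reg.semantic_types}
    class_tokens = reg.class_tokens()
    shared_tokens = {
        token(v): (category, v)
        for category, values in reg.shared_modifier_catalog().items()
        for v in values
    }

    concept_nodes = sorted(
        set(g.subjects(SO.conceptId, None)),
        key=lambda n: int(g.value(n, SO.conceptIndex) or 0),
    )
    for node in concept_nodes:
        semantic_type = None
        for parent in g.objects(node, RDFS.subClassOf):
            if isinstance(parent, URIRef):
                local = str(parent).rsplit("#", 1)[-1]
                if local in type_tokens:
                    semantic_type = type_tokens[local]
        source_raw = _literal(g, node, SO.semanticTypeSource)
        cui = _literal(g, node, SO.cui)
        binding = None
        if cui is not None:
            binding = TerminologyBinding(
                cui=cui,
                preferred_term=_literal(g, node, SO.boundPreferredTerm) or "",
                definition=_literal(g, node, SO.definition),
            )
        variants = []
        for prop, (kind, source) in _VARIANT_PROPS_INV.items():
            for value in g.objects(node, prop):
                variants.append(LexicalVariant(str(value), kind, source))
        semantic_modifiers: list[SemanticModifierAssignment] = []
        shared_modifiers: list[SharedModifierAssignment] = []
        for parent in g.objects(node, RDFS.subClassOf):
            if not isinstance(parent, BNode) or (parent, RDF.type, OWL.Restriction) not in g:
                continue
            prop = g.value(parent, OWL.onProperty)
            filler = g.value(parent, OWL.someValuesFrom)
            if prop == SO.hasSemAttribute:
                if isinstance(filler, BNode):
                    semantic_modifiers.append(_parse_range_filler(g, filler, class_tokens))
                else:
                    class_name = _literal(g, filler, SO.modifierClass)
                    value = _literal(g, filler, RDFS.label)
                    if class_name is None or value is None:
                        raise DialectError(
                            f"semantic-attribute filler {filler} lacks class/value annotations"
                        )
                    semantic_modifiers.append(SemanticModifierAssignment(class_name, value))
            elif prop == SO.hasSharedAttribute:
                local = str(filler).rsplit("#", 1)[-1]
                if local not in shared_tokens:
                    raise DialectError(f"unknown shared-attribute filler {local!r}")
                shared_modifiers.append(SharedModifierAssignment(*shared_tokens[local]))
        concept = Concept(
            id=_literal(g, node, SO.conceptId) or "",
            name=_literal(g, node, RDFS.label) or "",
            category=ConceptCategory(_literal(g, node, SO.conceptCategory) or "EVENT"),
            semantic_type=semantic_type,
            semantic_type_source=None if source_raw is None else VariantSource(source_raw),
            binding=binding,
            variants=sorted(variants, key=LexicalVariant.sort_key),
            semantic_modifiers=sorted(semantic_modifiers, key=lambda a: a.modifier_class),
            shared_modifiers=sorted(shared_modifiers, key=lambda a: a.category),
        )
        schema.concepts.append(concept)

    cue_subjects: set[URIRef] = set()
    for prop in _CUE_PROPS_INV:
        cue_subjects.update(s for s in g.subjects(prop, None) if isinstance(s, URIRef))
    for subject in sorted(cue_subjects):
        key = str(subject).rsplit("#", 1)[-1]
        cues = [
            LexicalVariant(str(value), kind, VariantSource.USER)
            for prop, kind in _CUE_PROPS_INV.items()
            for value in g.objects(subject, prop)
        ]
        schema.modifier_cues[key] = sorted(cues, key=LexicalVariant.sort_key)

    profile = OwlExportProfile(
        base_iri=(str(ont) + "#") if ont is not None else OwlExportProfile().base_iri,
        schema_ontology_iri=(
            str(next(g.objects(ont, OWL.imports), URIRef(SCHEMA_ONTOLOGY_IRI)))
            if ont is not None
            else SCHEMA_ONTOLOGY_IRI
        ),
    )

    regenerated = build_export_graph(schema, profile, reg)
    _, in_first, _ = graph_diff(to_isomorphic(g), to_isomorphic(regenerated))
    residue = Graph()
    for triple in in_first:
        residue.add(triple)
    return ImportResult(schema=schema, residue=residue, profile=profile)


# ---------------------------------------------------------------------------
# the packaged schema-ontology stub
# ---------------------------------------------------------------------------

def schema_ontology_graph(registry: ModifierRegistry | None = None) -> Graph:
    """Build the minimal base ontology: category classes for the semantic
    types, classes for every modifier class and every catalogued value, and
    the attribute/annotation properties the dialect uses."""
    reg = registry or load_registry()
    g = Graph()
    g.bind("so", SO)
    g.bind("owl", OWL)
    ont = URIRef(SCHEMA_ONTOLOGY_IRI)
    g.add((ont, RDF.type, OWL.Ontology))
    g.add((ont, RDFS.label, Literal("Schema ontology stub (semantic types, modifier classes, shared values)")))
    for top in (SO.Event, SO.Person, SO.SemanticModifier, SO.SharedModifier):
        g.add((top, RDF.type, OWL.Class))
    for st in reg.semantic_types:
        tiri = SO[token(st.name)]
        g.add((tiri, RDF.type, OWL.Class))
        g.add((tiri, RDFS.subClassOf, SO.Person if st.category == "PERSON" else SO.Event))
        g.add((tiri, RDFS.label, Literal(st.name)))
        for spec in st.classes:
            ciri = SO[token(spec.name)]
            g.add((ciri, RDF.type, OWL.Class))
            g.add((ciri, RDFS.subClassOf, SO.SemanticModifier))
            g.add((ciri, RDFS.label, Literal(spec.name)))
            for value in spec.values:
                viri = SO[f"{token(value)}_{token(spec.name)}"]
                g.add((viri, RDF.type, OWL.Class))
                g.add((viri, RDFS.subClassOf, ciri))
                g.add((viri, RDFS.label, Literal(value)))
    for category, values in reg.shared_modifier_catalog().items():
        catiri = SO[token(category)]
        g.add((catiri, RDF.type, OWL.Class))
        g.add((catiri, RDFS.subClassOf, SO.SharedModifier))
        g.add((catiri, RDFS.label, Literal(category)))
        for value in values:
            viri = SO[token(value)]
            g.add((viri, RDF.type, OWL.Class))
            g.add((viri, RDFS.subClassOf, catiri))
            g.add((viri, RDFS.label, Literal(value)))
    for prop in (SO.hasSemAttribute, SO.hasSharedAttribute):
        g.add((prop, RDF.type, OWL.ObjectProperty))
    for prop in (SO.hasLowerBound, SO.hasUpperBound, SO.hasUnit):
        g.add((prop, RDF.type, OWL.DatatypeProperty))
    annotation_props = list(_VARIANT_PROPS.values()) + list(_CUE_PROPS.values()) + [
        SO.conceptId, SO.conceptCategory, SO.conceptIndex, SO.semanticTypeSource,
        SO.cui, SO.boundPreferredTerm, SO.definition, SO.modifierClass,
    ]
    for prop in annotation_props:
        g.add((prop, RDF.type, OWL.AnnotationProperty))
    return g


def write_schema_ontology(path: str | Path, registry: ModifierRegistry | None = None) -> None:
    Path(path).write_text(schema_ontology_graph(registry).serialize(format="pretty-xml"), "utf-8")
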