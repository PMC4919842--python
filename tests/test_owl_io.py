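import random

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from semschema.datamodel import ConceptCategory, Schema, create_concept
from semschema.errors import DialectError, ExportError, ParseError
from semschema.owl_io import (
    SO,
    OwlExportProfile,
    build_export_graph,
    export_schema,
    import_schema,
    schema_ontology_graph,
)
from semschema.synth import random_schema


def _restriction_fillers(graph, prop):
    for restriction in graph.subjects(OWL.onProperty, prop):
        yield graph.value(restriction, OWL.someValuesFrom)


class TestExport:
    def test_mild_aneurysm_restriction(self, demo_schema):
        g = build_export_graph(demo_schema)
        aneurysm = URIRef(OwlExportProfile().base_iri + "aneurysm")
        assert (aneurysm, RDFS.subClassOf, SO.Problem) in g
        fillers = set(_restriction_fillers(g, SO.hasSemAttribute))
        assert SO.Mild_Severity in fillers

    def test_negated_occlusion_shared_restriction(self, demo_schema):
        g = build_export_graph(demo_schema)
        assert SO.Definite_Negated_Existence in set(
            _restriction_fillers(g, SO.hasSharedAttribute)
        )

    def test_untyped_concept_blocks_export(self):
        schema = Schema(name="x")
        create_concept(schema, "mystery", ConceptCategory.EVENT)
        with pytest.raises(ExportError, match="mystery"):
            export_schema(schema)

    def test_concept_without_modifiers_has_no_restrictions(self, registry):
        schema = Schema(name="x")
        concept = create_concept(schema, "cough", ConceptCategory.EVENT)
        from semschema.datamodel import set_semantic_type

        set_semantic_type(concept, "Sign or Symptom", registry)
        g = build_export_graph(schema)
        assert not list(g.subjects(RDF.type, OWL.Restriction))
        ciri = URIRef(OwlExportProfile().base_iri + "cough")
        assert (ciri, SO.preferredTerm, Literal("cough")) in g

    def test_export_is_byte_deterministic(self, demo_schema, tmp_path):
        first = export_schema(demo_schema, path=tmp_path / "a.owl")
        second = export_schema(demo_schema, path=tmp_path / "b.owl")
        assert first == second
        assert (tmp_path / "a.owl").read_bytes() == (tmp_path / "b.owl").read_bytes()

    def test_each_concept_has_exactly_one_category_superclass(self, registry):
        rng = random.Random(5)
        type_iris = {SO[c] for c in (t.name for t in registry.semantic_types)}
        from semschema._text import token

        type_iris = {SO[token(t.name)] for t in registry.semantic_types}
        for _ in range(10):
            schema = random_schema(rng, registry)
            g = build_export_graph(schema)
            for concept in schema.concepts:
                node = URIRef(OwlExportProfile().base_iri + concept.id)
                supers = [o for o in g.objects(node, RDFS.subClassOf) if o in type_iris]
                assert len(supers) == 1

    def test_bad_profiles_rejected(self):
        with pytest.raises(ExportError):
            OwlExportProfile(base_iri="http://x/noanchor")
        with pytest.raises(ExportError):
            OwlExportProfile(serialization="OWL_FUNCTIONAL")


class TestImport:
    def test_demo_round_trip(self, demo_schema, tmp_path):
        path = tmp_path / "demo.owl"
        export_schema(demo_schema, path=path)
        result = import_schema(path)
        assert result.schema == demo_schema
        assert len(result.residue) == 0

    def test_turtle_round_trip(self, demo_schema, tmp_path):
        path = tmp_path / "demo.ttl"
        export_schema(demo_schema, OwlExportProfile(serialization="TURTLE"), path)
        result = import_schema(path)
        assert result.schema == demo_schema

    def test_empty_ontology_with_import_declaration(self, tmp_path):
        g = Graph()
        ont = URIRef("https://example.org/empty")
        g.add((ont, RDF.type, OWL.Ontology))
        g.add((ont, OWL.imports, URIRef(str(SO).rstrip("#"))))
        path = tmp_path / "empty.owl"
        path.write_text(g.serialize(format="xml"))
        result = import_schema(path)
        assert result.schema.concepts == []
        assert len(result.residue) == 0

    def test_foreign_document_rejected(self, tmp_path):
        g = Graph()
        g.add((URIRef("http://x/a"), RDF.type, OWL.Class))
        path = tmp_path / "foreign.owl"
        path.write_text(g.serialize(format="xml"))
        with pytest.raises(DialectError):
            import_schema(path)

    def test_unparseable_document(self, tmp_path):
        path = tmp_path / "junk.owl"
        path.write_text("this is not RDF at all <<<")
        with pytest.raises(ParseError):
            import_schema(path)

    def test_hand_added_class_survives_as_residue(self, demo_schema, tmp_path):
        path = tmp_path / "demo.owl"
        export_schema(demo_schema, path=path)
        g = Graph().parse(path)
        extra = URIRef("https://example.org/hand#PostopChange")
        g.add((extra, RDF.type, OWL.Class))
        g.add((extra, RDFS.label, Literal("hand added class")))
        edited = tmp_path / "edited.owl"
        edited.write_text(g.serialize(format="xml"))

        result = import_schema(edited)
        assert result.schema == demo_schema
        assert (extra, RDF.type, OWL.Class) in result.residue

        re_exported = export_schema(result.schema, result.profile, residue=result.residue)
        g2 = Graph().parse(data=re_exported, format="xml")
        assert (extra, RDFS.label, Literal("hand added class")) in g2


class TestRoundTripProperty:
    @settings(max_examples=60)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_import_export_identity(self, seed, tmp_path_factory):
        schema = random_schema(seed)
        path = tmp_path_factory.mktemp("owl") / "s.owl"
        export_schema(schema, path=path)
        result = import_schema(path)
        assert result.schema == schema
        assert len(result.residue) == 0


def test_schema_ontology_stub_contains_vocabulary(registry):
    g = schema_ontology_graph(registry)
    assert (SO.Problem, RDFS.subClassOf, SO.Event) in g
    assert (SO.Patient_Demographic, RDFS.subClassOf, SO.Person) in g
    assert (SO.Definite_Negated_Existence, RDFS.subClassOf, SO.Certainty) in g
    assert (SO.hasSemAttribute, RDF.type, OWL.ObjectProperty) in g
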