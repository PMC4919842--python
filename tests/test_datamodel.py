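import random
from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

from semschema.datamodel import (
    MISSING_MODIFIER_TYPE,
    UNSUPPORTED_DISJUNCTION,
    UNSUPPORTED_RELATION,
    ConceptCategory,
    NumericRange,
    Representability,
    Schema,
    VariantKind,
    add_lexical_variant,
    check_representability,
    create_concept,
    load_schema,
    parse_numeric_range,
    save_schema,
    set_semantic_modifier,
    set_semantic_type,
    set_shared_modifier,
    validate_schema,
)
from semschema.errors import ConflictError, ParseError, RegistryLookupError, ValidationError
from semschema.synth import random_schema


@pytest.fixture()
def schema():
    return Schema(name="test")


class TestCreateConcept:
    def test_name_becomes_preferred_variant(self, schema):
        concept = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
        preferred = concept.preferred_variant()
        assert preferred is not None and preferred.text == "aneurysm"
        assert concept.semantic_type is None and concept.binding is None
        assert concept.semantic_modifiers == [] and concept.shared_modifiers == []

    @pytest.mark.parametrize("name", ["", "   "])
    def test_empty_name_rejected(self, schema, name):
        with pytest.raises(ValidationError):
            create_concept(schema, name, ConceptCategory.EVENT)

    def test_duplicate_names_get_distinct_ids(self, schema):
        a = create_concept(schema, "occlusion", ConceptCategory.EVENT)
        b = create_concept(schema, "occlusion", ConceptCategory.EVENT)
        assert a.id != b.id
        assert a.name == b.name == "occlusion"


class TestSetSemanticType:
    def test_problem_enables_course_and_severity(self, schema, registry):
        concept = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
        set_semantic_type(concept, "Problem", registry)
        classes = [s.name for s in registry.allowed_modifier_classes(concept.semantic_type)]
        assert classes == ["Course", "Severity"]

    def test_demographic_type_requires_person(self, schema, registry):
        concept = create_concept(schema, "smith", ConceptCategory.EVENT)
        with pytest.raises(ValidationError):
            set_semantic_type(concept, "Patient Demographic", registry)
        person = create_concept(schema, "jones", ConceptCategory.PERSON)
        with pytest.raises(ValidationError):
            set_semantic_type(person, "Problem", registry)

    def test_unknown_type(self, schema, registry):
        concept = create_concept(schema, "x", ConceptCategory.EVENT)
        with pytest.raises(RegistryLookupError):
            set_semantic_type(concept, "NotAType", registry)

    def test_retype_conflict_names_offenders_and_force_strips(self, schema, registry):
        concept = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
        set_semantic_type(concept, "Problem", registry)
        set_semantic_modifier(concept, "Severity", "mild", registry)
        with pytest.raises(ConflictError) as err:
            set_semantic_type(concept, "Encounter", registry)
        assert err.value.offenders == ["Severity"]
        assert concept.semantic_type == "Problem"  # atomic failure
        set_semantic_type(concept, "Encounter", registry, force=True)
        assert concept.semantic_type == "Encounter"
        assert concept.semantic_modifiers == []


class TestSharedModifiers:
    def test_negated_occlusion(self, schema, registry):
        concept = create_concept(schema, "occlusion", ConceptCategory.EVENT)
        set_shared_modifier(concept, "Certainty", "Definite Negated Existence", registry)
        assignment = concept.shared_modifier("Certainty")
        assert assignment.value == "Definite Negated Existence"
        assert assignment.value_token == "Definite_Negated_Existence"

    def test_illegal_value_lists_the_legal_four(self, schema, registry):
        concept = create_concept(schema, "occlusion", ConceptCategory.EVENT)
        with pytest.raises(ValidationError) as err:
            set_shared_modifier(concept, "Certainty", "maybe", registry)
        message = str(err.value)
        for value in registry.shared_modifier_catalog()["Certainty"]:
            assert value in message

    def test_replacement_keeps_single_assignment(self, schema, registry):
        concept = create_concept(schema, "occlusion", ConceptCategory.EVENT)
        set_shared_modifier(concept, "Certainty", "Probable Existence", registry)
        set_shared_modifier(concept, "Certainty", "Definite Existence", registry)
        certainty = [a for a in concept.shared_modifiers if a.category == "Certainty"]
        assert len(certainty) == 1 and certainty[0].value == "Definite Existence"

    def test_person_concept_rejected(self, schema, registry):
        person = create_concept(schema, "jones", ConceptCategory.PERSON)
        with pytest.raises(ValidationError):
            set_shared_modifier(person, "Certainty", "Definite Existence", registry)


class TestSemanticModifiers:
    def test_mild_severity(self, schema, registry):
        concept = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
        set_semantic_type(concept, "Problem", registry)
        set_semantic_modifier(concept, "Severity", "mild", registry)
        assert concept.semantic_modifier("Severity").value_token == "Mild_Severity"

    def test_dosage_range(self, schema, registry):
        concept = create_concept(schema, "ibuprofen", ConceptCategory.EVENT)
        set_semantic_type(concept, "Medication", registry)
        set_semantic_modifier(concept, "Dosage", NumericRange(80, 100, "mg"), registry)
        value = concept.semantic_modifier("Dosage").value
        assert (value.lower, value.upper, value.unit) == (Decimal(80), Decimal(100), "mg")

    def test_class_not_allowed_for_type(self, schema, registry):
        concept = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
        set_semantic_type(concept, "Problem", registry)
        with pytest.raises(RegistryLookupError, match="Course"):
            set_semantic_modifier(concept, "Medication Route", "oral", registry)

    def test_closed_class_rejects_nonmember(self, schema, registry):
        concept = create_concept(schema, "bulb", ConceptCategory.EVENT)
        set_semantic_type(concept, "Anatomical Site", registry)
        with pytest.raises(ValidationError):
            set_semantic_modifier(concept, "Body Side", "middle", registry)

    def test_open_class_accepts_unseeded_value(self, schema, registry):
        concept = create_concept(schema, "stenosis", ConceptCategory.EVENT)
        set_semantic_type(concept, "Disease Disorder", registry)
        set_semantic_modifier(concept, "Course", "fluctuating", registry)
        assert concept.semantic_modifier("Course").value == "fluctuating"

    def test_range_on_enumerated_class_rejected(self, schema, registry):
        concept = create_concept(schema, "stenosis", ConceptCategory.EVENT)
        set_semantic_type(concept, "Disease Disorder", registry)
        with pytest.raises(ValidationError):
            set_semantic_modifier(concept, "Severity", NumericRange(70, 80, "%"), registry)

    def test_requires_semantic_type_first(self, schema, registry):
        concept = create_concept(schema, "x", ConceptCategory.EVENT)
        with pytest.raises(ValidationError):
            set_semantic_modifier(concept, "Severity", "mild", registry)


class TestParseNumericRange:
    def test_closed_range(self):
        r = parse_numeric_range("80", "100", "mg")
        assert (r.lower, r.upper, r.unit) == (Decimal(80), Decimal(100), "mg")
        assert r.display() == "80-100 mg"

    def test_open_ended(self):
        assert parse_numeric_range("80", None, "mg").display() == ">80 mg"
        assert parse_numeric_range(None, "80", "mg").display() == "<80 mg"

    def test_point_value(self):
        r = parse_numeric_range("80", "80", "mg")
        assert r.is_point and r.display() == "80 mg"

    def test_errors(self):
        with pytest.raises(ValidationError):
            parse_numeric_range(None, None, "mg")
        with pytest.raises(ValidationError):
            parse_numeric_range("100", "80", "mg")
        with pytest.raises(ParseError):
            parse_numeric_range("eighty", "100", "mg")


class TestLexicalVariants:
    def test_add_and_kind_filter(self, schema):
        concept = create_concept(schema, "ibuprofen", ConceptCategory.EVENT)
        add_lexical_variant(concept, "Advil", VariantKind.SYNONYM)
        add_lexical_variant(concept, "ICA", VariantKind.ABBREVIATION)
        assert "Advil" in [v.text for v in concept.variants]
        assert [v.text for v in concept.variants_of_kind(VariantKind.ABBREVIATION)] == ["ICA"]

    def test_case_insensitive_dedup(self, schema):
        concept = create_concept(schema, "ibuprofen", ConceptCategory.EVENT)
        add_lexical_variant(concept, "Advil", VariantKind.SYNONYM)
        add_lexical_variant(concept, "advil", VariantKind.SYNONYM)
        add_lexical_variant(concept, "  Advil ", VariantKind.MISSPELLING)
        assert sum(v.key == "advil" for v in concept.variants) == 1

    def test_empty_text_rejected(self, schema):
        concept = create_concept(schema, "x", ConceptCategory.EVENT)
        with pytest.raises(ValidationError):
            add_lexical_variant(concept, "   ")

    def test_single_preferred_variant(self, schema):
        concept = create_concept(schema, "temperature", ConceptCategory.EVENT)
        add_lexical_variant(concept, "temp", VariantKind.PREFERRED)
        assert len(concept.variants_of_kind(VariantKind.PREFERRED)) == 1
        assert concept.preferred_variant().text == "temp"


class TestRepresentability:
    WORKED = [
        {"name": "aneurysm", "category": "EVENT", "semantic_type": "Problem"},
        {
            "name": "mild aneurysm",
            "category": "EVENT",
            "semantic_type": "Problem",
            "semantic_modifiers": [{"class": "Severity", "value": "mild"}],
        },
        {
            "name": "no occlusion",
            "category": "EVENT",
            "semantic_type": "Disease Disorder",
            "shared_modifiers": [{"category": "Certainty", "value": "Definite Negated Existence"}],
        },
        {
            "name": "80-100 mg ibuprofen",
            "category": "EVENT",
            "semantic_type": "Medication",
            "semantic_modifiers": [{"class": "Dosage", "value": "80-100 mg"}],
        },
    ]

    @pytest.mark.parametrize("request_dict", WORKED, ids=[w["name"] for w in WORKED])
    def test_worked_concepts_are_complete(self, registry, request_dict):
        report = check_representability(request_dict, registry)
        assert report.status is Representability.COMPLETE
        assert report.reasons == ()

    def test_compound_concept_needs_relation(self, registry):
        report = check_representability(
            {
                "name": "lab test positive for influenza",
                "links": [
                    {"name": "lab test positive", "semantic_type": "Lab/Test/Measurement"},
                    {"name": "influenza", "semantic_type": "Disease Disorder"},
                ],
            },
            registry,
        )
        assert report.status is not Representability.COMPLETE
        assert UNSUPPORTED_RELATION in report.reasons

    def test_value_disjunction_unsupported(self, registry):
        report = check_representability(
            {
                "name": "new or progressive infiltrate",
                "semantic_type": "Problem",
                "semantic_modifiers": [{"class": "Course", "any_of": ["new", "progressive"]}],
            },
            registry,
        )
        assert report.status is Representability.UNSUPPORTED
        assert UNSUPPORTED_DISJUNCTION in report.reasons

    def test_unknown_modifier_class_is_partial(self, registry):
        report = check_representability(
            {
                "name": "infiltrate with aeration",
                "semantic_type": "Problem",
                "semantic_modifiers": [{"class": "Aeration", "value": "poor"}],
            },
            registry,
        )
        assert report.status is Representability.PARTIAL
        assert MISSING_MODIFIER_TYPE in report.reasons

    def test_malformed_request(self, registry):
        with pytest.raises(ParseError):
            check_representability({"no_name": True}, registry)
        with pytest.raises(ParseError):
            check_representability({"name": "x", "semantic_modifiers": [{"value": "y"}]}, registry)


class TestPersistence:
    def test_json_round_trip(self, tmp_path, demo_schema):
        path = tmp_path / "schema.json"
        save_schema(demo_schema, path)
        assert load_schema(path) == demo_schema

    def test_random_schema_json_round_trip(self, tmp_path, registry):
        rng = random.Random(3)
        for _ in range(10):
            schema = random_schema(rng, registry)
            path = tmp_path / "s.json"
            save_schema(schema, path)
            assert load_schema(path) == schema

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"format": "other", "version": 1}')
        with pytest.raises(ParseError):
            load_schema(path)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_random_operation_sequences_keep_invariants(seed):
    """Any schema reachable through the public authoring API validates
    cleanly: modifier classes match the type, person/event exclusivity holds,
    ranges are ordered, at most one preferred variant."""
    schema = random_schema(seed)
    assert validate_schema(schema) == []
    for concept in schema.concepts:
        for assignment in concept.semantic_modifiers:
            value = assignment.value
            if isinstance(value, NumericRange):
                assert value.lower is not None or value.upper is not None
                if value.lower is not None and value.upper is not None:
                    assert value.lower <= value.upper
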