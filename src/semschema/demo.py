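"""The carotid-stenosis walkthrough schema.

Builds, through the public authoring API, the small neurovascular schema used
by the CLI ``demo`` command, the synthetic-corpus evaluation and the worked
examples: a mild aneurysm (Problem + Severity), an explicitly negated
occlusion (certainty: Definite Negated Existence), a worsening moderate
stenosis, the internal carotid artery with sidedness (Body Side) and the
"ICA"/"l" abbreviations whose removal is the classic cause of depressed
recall, and an 80-100 mg ibuprofen dosage range.
"""

from __future__ import annotations

from .datamodel import (
    ConceptCategory,
    NumericRange,
    Schema,
    VariantKind,
    create_concept,
    set_modifier_cue,
    set_semantic_modifier,
    set_shared_modifier,
)
from .registry import ModifierRegistry, load_registry
from .terminology import LocalLexicon, bind_concept, lookup, packaged_lexicon


def build_demo_schema(
    registry: ModifierRegistry | None = None, lexicon: LocalLexicon | None = None
) -> Schema:
    reg = registry or load_registry()
    lex = lexicon or packaged_lexicon()
    schema = Schema(
        name="carotid stenosis demo",
        description="Walkthrough schema: neurovascular findings with certainty, "
        "severity, sidedness and dosage modifiers.",
    )

    def bind_first(concept, query: str) -> None:
        bind_concept(concept, lookup(lex, query, limit=1)[0], reg)

    aneurysm = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
    bind_first(aneurysm, "aneurysm")  # maps to Problem
    set_semantic_modifier(aneurysm, "Severity", "mild", reg)

    occlusion = create_concept(schema, "occlusion", ConceptCategory.EVENT)
    bind_first(occlusion, "occlusion")  # maps to Disease Disorder
    set_shared_modifier(occlusion, "Certainty", "Definite Negated Existence", reg)

    stenosis = create_concept(schema, "stenosis", ConceptCategory.EVENT)
    bind_first(stenosis, "stenosis")
    set_semantic_modifier(stenosis, "Severity", "moderate", reg)
    set_semantic_modifier(stenosis, "Course", "worsened", reg)

    ica = create_concept(schema, "internal carotid artery", ConceptCategory.EVENT)
    # the user-entered abbreviation wins deduplication against the imported synonym
    from .datamodel import add_lexical_variant

    add_lexical_variant(ica, "ICA", VariantKind.ABBREVIATION)
    bind_first(ica, "internal carotid artery")  # maps to Anatomical Site
    set_semantic_modifier(ica, "Body Side", "left", reg)

    ibuprofen = create_concept(schema, "ibuprofen", ConceptCategory.EVENT)
    add_lexical_variant(ibuprofen, "Ibu", VariantKind.ABBREVIATION)
    bind_first(ibuprofen, "ibuprofen")  # maps to Medication
    set_semantic_modifier(ibuprofen, "Dosage", NumericRange(80, 100, "mg"), reg)

    # surface cues for modifier values (the value's own text is always a cue)
    set_modifier_cue(schema, "Left_Body_Side", "l", VariantKind.ABBREVIATION)
    set_modifier_cue(schema, "Left_Body_Side", "lt", VariantKind.ABBREVIATION)
    set_modifier_cue(schema, "Worsened_Course", "worsening")
    dosage = ibuprofen.semantic_modifier("Dosage")
    assert dosage is not None
    set_modifier_cue(schema, dosage.value_token, "80 to 100 mg")
    return schema
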