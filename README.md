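# semschema

Headless authoring of **clinical semantic schemas** — the target extraction
templates of rule-based clinical NLP systems — plus everything needed to use
and evaluate them: OWL serialization, marshalling into ConText-style
target/modifier lexicons, a minimal extraction engine, a synthetic annotated
corpus generator, and per-category recall evaluation.

## Who this is for

Building a clinical information-extraction pipeline normally requires a
domain expert (what counts as *mild aneurysm* or *no occlusion*) and an NLP
engineer (how to encode that computably). `semschema` encodes the constrained
schema model that bridges the two: a schema is a list of **concepts**, each

* an *atomic concept*, optionally normalized to a terminology record by CUI
  (Concept Unique Identifier, `C` + digits), with **lexical variants**
  (synonyms, abbreviations, misspellings) for surface matching;
* one of 12 **semantic types** (Problem, Medication, Vital Sign, …), which
  determines the **semantic modifiers** the concept may carry (Severity for a
  Problem, Dosage for a Medication, …), each with a declared value set;
* for Event concepts, **shared modifiers** from seven closed categories
  (certainty, experiencer, temporality, contextual aspect/modality, degree,
  permanence); Person concepts instead carry Patient Demographic modifiers.

Because the modifier taxonomy is fixed and machine-readable
(`semschema/data/registry.json`), every schema built here is guaranteed
expressible, serializable, and directly consumable by the bundled extraction
engine.

The model of extraction is the ConText family: target mentions are found by
case-insensitive word-boundary lexicon matching (longest match first), and
modifier cues assign values by directional, sentence-bounded scope — e.g. in
*"no occlusion"* the forward cue *no* marks the `occlusion` mention with
certainty `Definite_Negated_Existence`. The statistic reported is **recall**
per category — the fraction of gold mentions recovered — since the operative
question for a schema author is whether the lexical variants cover the text.

## Worked example

```bash
semschema demo --out demo_out --n 50 --seed 7
```

builds the carotid-stenosis walkthrough schema (a mild `aneurysm`, a negated
`occlusion`, a worsening moderate `stenosis`, the left `internal carotid
artery` with the abbreviation *ICA*, and 80–100 mg `ibuprofen`), exports
`schema.owl` and the two NLP lexicons, generates a 50-report synthetic gold
corpus, extracts, and prints:

```
Category                   Total Correct  Recall
Targets                      222     222  100 %
Body Side                     44      44  100 %
Certainty                     79      79  100 %
Course                        43      43  100 %
Dosage                        43      43  100 %
Severity                      85      85  100 %
```

Recall is exactly 100 % because the generator plants only strings the schema
knows — this is the oracle that validates the whole chain. Degrading the
lexicon (`semschema.synth.degrade_lexicon`) by removing abbreviation variants
such as *ICA* and *l* (sidedness: left) reproduces the classic failure mode
of terminology-derived lexicons: target and sidedness recall drop sharply
while certainty recall, whose cues have no abbreviations, stays high.

The same workflow is available programmatically:

```python
from semschema import (ConceptCategory, Schema, create_concept, lookup,
                       bind_concept, packaged_lexicon, set_semantic_modifier,
                       export_schema)

schema = Schema(name="carotid stenosis")
aneurysm = create_concept(schema, "aneurysm", ConceptCategory.EVENT)
bind_concept(aneurysm, lookup(packaged_lexicon(), "aneurysm")[0])  # CUI, synonyms, type
set_semantic_modifier(aneurysm, "Severity", "mild")
export_schema(schema, path="carotid.owl")
```

The exported ontology imports the base schema ontology, declares each concept
as a subclass of its semantic-category class, attaches metadata (preferred
term, synonyms, CUI, definition) as annotation properties, and encodes each
modifier assignment as an existential restriction — *mild aneurysm* carries
`hasSemAttribute some Mild_Severity`. Re-importing is lossless, and axioms
added by hand in an OWL editor (including SWRL rules) are preserved verbatim
as an opaque residue.

## Layout

| Module | Role |
| --- | --- |
| `semschema.datamodel` | concepts, variants, modifier assignments, schemas; validation; JSON persistence; representability checking |
| `semschema.registry` | the packaged modifier taxonomy and its query API |
| `semschema.terminology` | lexicon fixture format, ranked lookup, concept binding |
| `semschema.owl_io` | OWL export/import with residue pass-through |
| `semschema.nlp_export` | target/modifier lexicon marshalling (TSV/YAML) |
| `semschema.context_engine` | sentence segmentation, matching, modifier scoping |
| `semschema.synth` | seeded synthetic corpus generator and lexicon degradation |
| `semschema.evaluation` | per-category recall tables |
| `semschema.cli` | the `semschema` command |

See `docs/methods.md` for the model, conventions and limitations.
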