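# Methods

This note documents the model implemented by `semschema`, the conventions it
fixes where the design was genuinely open, what the synthetic evaluation does
and does not show, and known limitations.

## The schema model

A schema is an ordered list of concepts under a constrained type system.
Concepts are PERSON or EVENT; the 12 semantic types partition accordingly
(Patient Demographic is the single PERSON type). A concept's semantic type
fixes its admissible semantic-modifier classes; shared modifiers (Certainty,
Experiencer, Temporality, Contextual Aspect, Contextual Modality, Degree,
Permanence) apply to EVENT concepts only. Assignments are single-valued per
class/category with replace-on-repeat semantics: value disjunctions are
deliberately outside the model, and `check_representability` reports them as
`UNSUPPORTED_DISJUNCTION` (relations between concepts likewise as
`UNSUPPORTED_RELATION`, a PARTIAL verdict — the parts can still be created as
separate, unlinked concepts).

### The modifier taxonomy (`data/registry.json`)

Each semantic-modifier class carries a *declared cardinality* and a *closure
flag*:

* `CLOSED` — the value enumeration is complete (e.g. Body Side: right, left,
  bilateral); validation rejects anything else.
* `OPEN` — the declared cardinality exceeds the values that could be seeded
  from available documentation (e.g. Severity: declared 7, seeded mild,
  moderate, severe). Seeded values are guaranteed members; free text beyond
  the seed is accepted, because inventing the missing members would be
  fabrication while rejecting unknown ones would make the class unusable.
* `UNLIMITED` — value-typed classes (Dosage, Lab value, …) accepting free
  text or a `NumericRange`.

Same-named classes under different types (Severity under Problem and under
Sign or Symptom; Ordinal Interpretation with cardinality 35 under
Lab/Test/Measurement but 37 under Vital Sign) are distinct, type-scoped
specs; the registry transcribes rather than reconciles. The Patient
Demographic class list includes Race (UNLIMITED) alongside the tabulated
seven. Gender is declared with cardinality 2 but ships with an empty seed, so
it is OPEN.

### Numeric ranges

`NumericRange(lower, upper, unit)` holds `Decimal` bounds; one bound may be
absent (open-ended: ">80 mg" / "<80 mg") and equal bounds denote a point
value. Ranges are accepted **only on UNLIMITED classes**: enumerated severity
scales and similar dropdown classes cannot express "70–80 %", which mirrors a
real representational gap of dropdown-driven authoring rather than an
oversight.

## Terminology binding

`LocalLexicon` loads three TSV tables (terms with a preferred flag,
definitions, source semantic types) with full referential-integrity checking.
The packaged fixture under `data/synthetic_umls_subset/` is **synthetic**:
fabricated `C9xxxxxx` CUIs and a hand-curated record set sufficient for
offline testing; it is not derived from any licensed vocabulary. Lookup ranks
candidates exact > normalized (case/punctuation/whitespace folded) > token
subset > substring, ties broken by CUI — an invented but deterministic
convention, since candidate presentation order is otherwise unspecified.

Binding imports CUI, preferred term, definition and synonyms (marked
`source=TERMINOLOGY` so they remain individually deletable and are removed
wholesale on unbind), and assigns the mapped semantic type only when the
concept has none: a user's explicit choice is never silently overwritten.
Source semantic-type labels translate through `data/semantic_type_map.json`;
unmapped labels leave the concept untyped and raise
`UnmappedSemanticTypeWarning` rather than guessing.

## OWL dialect

Export produces one ontology importing the base schema-ontology IRI. Per
concept: a named class (`base_iri` + concept id), `rdfs:subClassOf` the
semantic-category class; annotation properties for name, category, variants
(separate properties per kind × source so the round trip is lossless), CUI,
definition, and an integer index preserving concept order. Modifier
assignments become existential restrictions: `hasSemAttribute some
<Value>_<Class>` for semantic values (the filler class subclasses the
modifier-class class and is annotated with its class and display value),
`hasSharedAttribute some <Value>` for shared values, and for numeric ranges a
`hasSemAttribute some (Class ⊓ hasLowerBound value x ⊓ hasUpperBound value y
⊓ hasUnit value u)` intersection. Modifier-value cue variants are annotation
triples on the filler class. The full dialect vocabulary is emitted by
`schema_ontology_graph()` / `write_schema_ontology()`.

Import reconstructs the schema and computes a **residue**: the graph
difference (blank-node aware, via rdflib's isomorphism machinery) between the
input document and a regeneration of the reconstructed schema. Residue
triples — hand-added classes, SWRL rules, any foreign axioms — are re-emitted
verbatim on the next export. Round-trip identity (`import(export(S)) == S`,
empty residue) is property-tested over randomized schemas.

Serialization is RDF/XML by default with Turtle as the alternative. Output is
canonicalized (deterministic blank-node labels, sorted triple insertion) and
byte-stable for a fixed input within a session; Turtle output is additionally
byte-stable across Python processes, while RDF/XML subject order can vary
between interpreter instances (the documents remain graph-isomorphic). No
reasoning or SWRL interpretation is performed, and nothing is fetched from
any IRI.

## NLP lexicons and the extraction engine

Marshalling flattens a schema into the two-file contract of ConText-style
engines. Targets: one entry per lexical variant, category = concept id,
regex auto-derived (escaped literal, internal whitespace → `\s+`,
word-boundary lookarounds, case-insensitive). Modifiers: one entry per
surface cue of every modifier value *referenced by the schema* (not the whole
registry), category = the value token (`Mild_Severity`,
`Definite_Negated_Existence`). Cues are the union of the schema's cue map and
packaged defaults; the value's own text is always a cue. Directions are this
package's convention, as the historical rule files' directions are not
standardized: pre-target shared cues (negation, temporality, …) run
*forward*, post-hoc status cues ("ruled out") *backward*, semantic values
*bidirectional*; conjunctions ("but", "however", …) are *terminate* cues.
Both file dialects (4-column TSV with one header line; YAML list of 4-key
maps) round-trip exactly; TSV rejects embedded tabs/newlines.

The engine is deliberately minimal and its rules are declared, not inferred
from any reference system: sentence-bounded scope cut by terminate cues, no
token-window limit, nearest in-scope cue per category wins, cues overlapping
the mention are ignored. Overlapping target candidates resolve longest-first,
then leftmost, then lexicographic category, making output independent of
lexicon entry order. Sentence segmentation splits on `.!?` and newline runs
with a small abbreviation guard list. Spans are 0-based half-open character
offsets. Matching and scoping are verified against independent brute-force
implementations (sliding-window comparison; explicit interval arithmetic) on
randomized sentences. A best-effort Knowtator-style stand-off XML writer is
provided for interoperability with annotation viewers; it is
schema-documented, not byte-compatible with any historical release.

## Synthetic corpus and evaluation

The generator emulates short imaging-report paragraphs only at the token
level: fixed carrier templates, one planted concept mention per finding
sentence, modifier cues planted before the target, and distractor sentences
with vocabulary disjoint from the demo lexicon. Defaults: 3–8 sentences per
report, `distractor_rate=0.2`, `abbreviation_rate=0.5` (probability a planted
surface form is an abbreviation when one exists), `negation_rate=0.3`
(probability a mention is negated, independent of the concept's own certainty
assignment). All randomness flows from one seed. Because gold records exactly
what was planted, an undegraded lexicon yields recall exactly 1.0 in every
category — the oracle anchoring the chain. What passing this does **not**
show: robustness to real clinical language (paraphrase, typos not in the
lexicon, cross-sentence reference, list structures); the generator measures
lexicon coverage, not language understanding, so recall on real reports will
be lower.

`degrade_lexicon` removes a seeded fraction of variants of one kind; the
removal sets are *nested* across fractions (a shuffled-prefix construction),
which makes recall provably non-increasing in the fraction. Degrading
abbreviations reproduces the characteristic error pattern: categories whose
cues include abbreviations ("ICA" for the artery, "l"/"lt" for sidedness)
collapse while categories with full-word cues (negation) degrade little.

Evaluation reports recall per category (a Targets row plus one row per
modifier category). A gold mention counts as found if a predicted mention of
the same category matches under the span policy — `overlap` by default, the
conservative IE convention, with `exact` available; a gold modifier value
counts only on found mentions. Precision is computed only on request.

## Problem sizes

Property suites use 200 randomized schemas for the OWL round trip, 1000
randomized sentences for engine/oracle agreement, and 50-report corpora
(~200 gold mentions) for the recall study; these sizes give stable
fractions while keeping the full suite around ten seconds.

## Known limitations

* No live terminology service client; the provider interface exists, but the
  only implementation is the local TSV fixture.
* The schema-ontology dialect (property IRIs, range encoding, cue
  annotations) is this package's own documented convention; other tools
  consuming schema-ontology files may use different IRIs.
* The engine omits uncertainty composition, windowed scope and graph output.
* `check_representability` judges structural expressibility only; it cannot
  judge whether a clinically adequate modifier *value* exists in an OPEN
  class's unseeded remainder.
* Multi-user storage, sharing and any GUI are out of scope; the schema store
  is a directory of JSON files.
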