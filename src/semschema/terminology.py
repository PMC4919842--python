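"""Terminology lookup and concept binding.

A *terminology provider* emulates the concept-normalization workflow against
a vocabulary such as the UMLS Metathesaurus: search candidate records for a
concept name, pick one, and import its CUI, preferred term, synonyms,
definition and semantic type into the concept under construction.  Everything
imported stays editable and removable on the concept.

The packaged provider is :class:`LocalLexicon`, loaded from three TSV tables
(terms, definitions, semantic types) in the fixture format documented below.
The packaged demo fixture (``data/synthetic_umls_subset/``) is a SYNTHETIC
stand-in for a real vocabulary subset: entirely fabricated CUIs and a small
hand-curated record set, sufficient to exercise lookup/binding offline.

Fixture format (UTF-8, one fixed header line per file):

``terms.tsv``        ``cui<TAB>term<TAB>preferred`` (``Y``/``N``; exactly one
                     ``Y`` row per CUI)
``definitions.tsv``  ``cui<TAB>definition``
``semtypes.tsv``     ``cui<TAB>semantic_type`` (source-vocabulary label)

Every CUI appearing in ``definitions.tsv`` or ``semtypes.tsv`` must appear in
``terms.tsv``.  Source semantic-type labels are translated to taxonomy types
through the packaged mapping table (``data/semantic_type_map.json``);
unmapped labels leave the concept untyped and raise
:class:`~semschema.errors.UnmappedSemanticTypeWarning`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ._text import normalize_term
from .datamodel import (
    Concept,
    TerminologyBinding,
    VariantKind,
    VariantSource,
    add_lexical_variant,
    set_semantic_type,
)
from .errors import IntegrityError, ParseError, UnmappedSemanticTypeWarning, ValidationError
from .registry import ModifierRegistry, load_registry


@dataclass(frozen=True)
class TerminologyRecord:
    cui: str
    preferred_term: str
    synonyms: tuple[str, ...] = ()
    definition: str | None = None
    source_semantic_type: str | None = None
    mapped_semantic_type: str | None = None

    @property
    def all_terms(self) -> tuple[str, ...]:
        return (self.preferred_term,) + self.synonyms


def load_semantic_type_map() -> dict[str, str]:
    text = resources.files("semschema").joinpath("data/semantic_type_map.json").read_text("utf-8")
    return json.loads(text)["map"]


def _read_tsv(path: Path, n_cols: int, header: str) -> list[tuple[int, list[str]]]:
    if not path.exists():
        raise ParseError(f"fixture table missing: {path}")
    rows: list[tuple[int, list[str]]] = []
    lines = path.read_text("utf-8").splitlines()
    if not lines:
        return rows  # an entirely empty file means zero records
    if lines[0].rstrip("\n") != header:
        raise ParseError(f"{path.name}: expected header {header!r}", line=1)
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != n_cols:
            raise ParseError(f"{path.name}: expected {n_cols} tab-separated columns", line=i)
        if any(not c.strip() for c in cols):
            raise ParseError(f"{path.name}: empty column", line=i)
        rows.append((i, [c.strip() for c in cols]))
    return rows


@dataclass
class LocalLexicon:
    """In-memory terminology provider over the TSV fixture format."""

    records: dict[str, TerminologyRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, cui: str) -> TerminologyRecord:
        if cui not in self.records:
            raise KeyError(cui)
        return self.records[cui]

    def lookup(self, query: str, limit: int = 10) -> list[TerminologyRecord]:
        return lookup(self, query, limit)


def load_lexicon(path: str | Path) -> LocalLexicon:
    """Load a fixture directory into a validated provider.

    Raises :class:`ParseError` (with line numbers) for malformed rows and
    :class:`IntegrityError` for CUIs referenced outside the terms table.
    """
    root = Path(path)
    terms = _read_tsv(root / "terms.tsv", 3, "cui\tterm\tpreferred")
    defs = _read_tsv(root / "definitions.tsv", 2, "cui\tdefinition")
    semtypes = _read_tsv(root / "semtypes.tsv", 2, "cui\tsemantic_type")

    preferred: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    for line_no, (cui, term, flag) in ((ln, tuple(c)) for ln, c in terms):
        if flag not in ("Y", "N"):
            raise ParseError(f"terms.tsv: preferred flag must be Y or N, got {flag!r}", line=line_no)
        if flag == "Y":
            if cui in preferred:
                raise ParseError(f"terms.tsv: second preferred term for {cui}", line=line_no)
            preferred[cui] = term
        else:
            synonyms.setdefault(cui, []).append(term)
    known = set(preferred) | set(synonyms)
    for cui in synonyms:
        if cui not in preferred:
            raise IntegrityError(f"terms.tsv: CUI {cui} has synonyms but no preferred term")

    definitions: dict[str, str] = {}
    for line_no, (cui, definition) in ((ln, tuple(c)) for ln, c in defs):
        if cui not in known:
            raise IntegrityError(f"definitions.tsv line {line_no}: dangling CUI {cui}")
        definitions[cui] = definition
    source_types: dict[str, str] = {}
    for line_no, (cui, label) in ((ln, tuple(c)) for ln, c in semtypes):
        if cui not in known:
            raise IntegrityError(f"semtypes.tsv line {line_no}: dangling CUI {cui}")
        source_types[cui] = label

    type_map = load_semantic_type_map()
    records = {
        cui: TerminologyRecord(
            cui=cui,
            preferred_term=preferred[cui],
            synonyms=tuple(synonyms.get(cui, ())),
            definition=definitions.get(cui),
            source_semantic_type=source_types.get(cui),
            mapped_semantic_type=type_map.get(source_types.get(cui, "")),
        )
        for cui in sorted(preferred)
    }
    return LocalLexicon(records=records)


def packaged_lexicon() -> LocalLexicon:
    """The packaged synthetic demo fixture."""
    return load_lexicon(resources.files("semschema").joinpath("data/synthetic_umls_subset"))


# ranking tiers, best first
_EXACT, _NORMALIZED, _TOKEN_SUBSET, _SUBSTRING = 0, 1, 2, 3


def _match_tier(query: str, term: str) -> int | None:
    if query.casefold() == term.casefold():
        return _EXACT
    nq, nt = normalize_term(query), normalize_term(term)
    if nq == nt:
        return _NORMALIZED
    q_tokens, t_tokens = set(nq.split()), set(nt.split())
    if q_tokens and q_tokens <= t_tokens:
        return _TOKEN_SUBSET
    if nq and nq in nt:
        return _SUBSTRING
    return None


def lookup(provider: LocalLexicon, query: str, limit: int = 10) -> list[TerminologyRecord]:
    """Ranked candidate search.

    Tiers: exact (case-insensitive) > normalized (punctuation/whitespace
    folded) > token subset > substring; ties broken lexicographically by CUI.
    Pure function of its inputs; an unmatched query yields an empty list.
    """
    if not query or not query.strip():
        raise ValidationError("lookup query must be non-empty")
    query = query.strip()
    scored: list[tuple[int, str]] = []
    for cui, record in provider.records.items():
        tiers = [t for t in (_match_tier(query, term) for term in record.all_terms) if t is not None]
        if tiers:
            scored.append((min(tiers), cui))
    scored.sort()
    return [provider.records[cui] for _, cui in scored[: max(0, limit)]]


def bind_concept(
    concept: Concept, record: TerminologyRecord, registry: ModifierRegistry | None = None
) -> Concept:
    """Bind a concept to a terminology record.

    Imports the CUI, preferred term and definition as the concept's binding
    and merges the record's terms into the variant set with
    ``source=TERMINOLOGY`` (existing variants win deduplication).  The mapped
    semantic type is assigned only if the concept has none — a user's explicit
    choice is never overwritten; an unmapped source type leaves the concept
    untyped and warns.
    """
    reg = registry or load_registry()
    concept.binding = TerminologyBinding(
        cui=record.cui, preferred_term=record.preferred_term, definition=record.definition
    )
    for term in record.all_terms:
        add_lexical_variant(concept, term, VariantKind.SYNONYM, VariantSource.TERMINOLOGY)
    if concept.semantic_type is None:
        if record.mapped_semantic_type is not None:
            set_semantic_type(
                concept, record.mapped_semantic_type, reg, source=VariantSource.TERMINOLOGY
            )
        else:
            warnings.warn(
                f"source semantic type {record.source_semantic_type!r} of {record.cui} has no "
                f"taxonomy mapping; {concept.name!r} is left untyped",
                UnmappedSemanticTypeWarning,
                stacklevel=2,
            )
    return concept


def unbind_concept(concept: Concept) -> Concept:
    """Remove the binding and everything it imported: terminology-sourced
    variants go away (user variants stay), and a terminology-assigned semantic
    type is cleared along with its modifier assignments."""
    concept.binding = None
    concept.variants = [v for v in concept.variants if v.source is not VariantSource.TERMINOLOGY]
    if concept.semantic_type_source is VariantSource.TERMINOLOGY:
        concept.semantic_modifiers = []
        concept.semantic_type = None
        concept.semantic_type_source = None
    return concept
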