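"""Marshal a schema into target/modifier lexicons for a ConText-style engine.

Rule-based clinical IE engines of the ConText family consume two files: a
*target* lexicon (regular expressions / lexical variants naming the concepts
to find) and a *modifier* lexicon (cues for certainty, anatomy, temporality,
... with a scope direction).  This module flattens a schema into that form:

* one target entry per lexical variant per concept, category = concept id;
* one modifier entry per surface cue of every modifier value referenced by
  any concept, category = the value token (``Definite_Negated_Existence``,
  ``Mild_Severity``); cues come from the schema's cue map merged with the
  packaged defaults for shared values, falling back to the value text itself;
* terminate entries ("but", "however", ...) that cut modifier scope.

Directions follow the package convention: certainty/temporality-style shared
cues run *forward* (pre-target, e.g. "no X"), post-hoc status cues run
*backward* ("X is ruled out"), and semantic modifier values (severity,
sidedness, dosage, ...) are *bidirectional*.

Two documented on-disk dialects are supported, both 4-field
(literal, category, regex, rule): a single-header TSV and a YAML list.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

from .datamodel import Schema, referenced_value_tokens
from .errors import ParseError, ValidationError
from .registry import ModifierRegistry, load_registry

RULES = ("", "forward", "backward", "bidirectional", "terminate")

#: category used for scope-terminating cues
TERMINATE_CATEGORY = "TERMINATE"

#: default surface cues for shared-modifier values: value token -> ((literal, rule), ...)
DEFAULT_SHARED_CUES: dict[str, tuple[tuple[str, str], ...]] = {
    "Definite_Negated_Existence": (
        ("no", "forward"),
        ("not", "forward"),
        ("without", "forward"),
        ("denies", "forward"),
        ("negative for", "forward"),
        ("absence of", "forward"),
        ("ruled out", "backward"),
    ),
    "Definite_Existence": (("definite", "forward"), ("confirmed", "forward")),
    "Probable_Existence": (
        ("probable", "forward"),
        ("possible", "forward"),
        ("likely", "forward"),
        ("suspected", "forward"),
    ),
    "Probable_Negated_Existence": (("unlikely", "forward"), ("doubt", "forward")),
    "Family_Member": (
        ("family history of", "forward"),
        ("mother", "forward"),
        ("father", "forward"),
    ),
    "Before": (
        ("history of", "forward"),
        ("previous", "forward"),
        ("prior", "forward"),
    ),
    "Overlap": (("current", "forward"), ("currently", "forward")),
    "After": (("planned", "forward"), ("scheduled for", "forward")),
    "Hypothetical": (("if", "forward"),),
    "Conditional": (("unless", "forward"),),
}

DEFAULT_TERMINATE_CUES: tuple[str, ...] = ("but", "however", "although", "aside from", "except")


def derive_regex(literal: str) -> str:
    """Word-boundary, whitespace-tolerant pattern for a lexical variant.

    Internal whitespace matches any whitespace run, so ``'r ica'`` matches
    "r  ica" but never the inside of "africa".
    """
    parts = [re.escape(p) for p in literal.split()]
    if not parts:
        raise ValidationError("cannot derive a pattern from an empty literal")
    return r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)"


@dataclass(frozen=True)
class LexiconEntry:
    literal: str
    category: str
    regex: str | None = None
    rule: str = ""

    def __post_init__(self) -> None:
        if not self.literal.strip():
            raise ValidationError("lexicon entry literal must be non-empty")
        if not self.category.strip():
            raise ValidationError("lexicon entry category must be non-empty")
        if self.rule not in RULES:
            raise ValidationError(f"unknown rule {self.rule!r}; legal rules: {RULES}")
        if self.regex is not None:
            try:
                re.compile(self.regex)
            except re.error as exc:
                raise ValidationError(f"regex {self.regex!r} does not compile: {exc}") from exc

    @property
    def pattern(self) -> str:
        return self.regex if self.regex is not None else derive_regex(self.literal)


def _entry_order(entry: LexiconEntry) -> tuple:
    return (entry.category, -len(entry.literal), entry.literal.casefold(), entry.rule)


def to_target_lexicon(schema: Schema) -> list[LexiconEntry]:
    """One entry per lexical variant per concept; longest variants first
    within a concept so greedy matchers prefer the most specific form."""
    if not schema.concepts:
        warnings.warn(f"schema {schema.name!r} has no concepts; target lexicon is empty")
    entries: list[LexiconEntry] = []
    for concept in schema.concepts:
        if not concept.variants:
            warnings.warn(f"concept {concept.id!r} has no lexical variants; skipped")
            continue
        for variant in concept.variants:
            entries.append(
                LexiconEntry(
                    literal=variant.text,
                    category=concept.id,
                    regex=derive_regex(variant.text),
                    rule="",
                )
            )
    return sorted(set(entries), key=_entry_order)


def _shared_rule(literal: str, value_token: str) -> str:
    for lit, rule in DEFAULT_SHARED_CUES.get(value_token, ()):
        if lit == literal.casefold():
            return rule
    return "forward"


def to_modifier_lexicon(
    schema: Schema,
    registry: ModifierRegistry | None = None,
    include_terminate: bool = True,
) -> list[LexiconEntry]:
    """Entries for every modifier value referenced by the schema's concepts.

    Cues are the union of the schema's cue map for that value and the
    packaged defaults (shared values) or the value text itself (semantic
    values); duplicates resolve in favour of the schema's cue.
    """
    reg = registry or load_registry()
    shared_categories = set(reg.shared_modifier_catalog())
    entries: list[LexiconEntry] = []
    for value_token, (owner, display) in sorted(referenced_value_tokens(schema).items()):
        is_shared = owner in shared_categories
        cues: dict[str, tuple[str, str]] = {}  # literal key -> (literal, rule)
        if is_shared:
            for literal, rule in DEFAULT_SHARED_CUES.get(
                value_token, ((display.casefold(), "forward"),)
            ):
                cues[literal.casefold()] = (literal, rule)
        else:
            cues[display.casefold()] = (display, "bidirectional")
        for cue in schema.modifier_cues.get(value_token, []):
            rule = _shared_rule(cue.text, value_token) if is_shared else "bidirectional"
            cues[cue.key] = (cue.text, rule)
        for literal, rule in cues.values():
            entries.append(
                LexiconEntry(
                    literal=literal,
                    category=value_token,
                    regex=derive_regex(literal),
                    rule=rule,
                )
            )
    if include_terminate and entries:
        for literal in DEFAULT_TERMINATE_CUES:
            entries.append(
                LexiconEntry(
                    literal=literal,
                    category=TERMINATE_CATEGORY,
                    regex=derive_regex(literal),
                    rule="terminate",
                )
            )
    return sorted(set(entries), key=_entry_order)


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

_TSV_HEADER = "literal\tcategory\tregex\trule"


def write_lexicons(
    entries: list[LexiconEntry], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write entries in the TSV (4 tab-separated columns, one header line) or
    YAML (list of 4-key maps) dialect; both round-trip through
    :func:`read_lexicons`."""
    path = Path(path)
    if dialect == "tsv":
        lines = [_TSV_HEADER]
        for e in entries:
            fields = (e.literal, e.category, e.regex or "", e.rule)
            for f in fields:
                if "\t" in f or "\n" in f:
                    raise ValidationError(
                        f"field {f!r} contains a tab/newline; not representable in the TSV "
                        "dialect (use YAML)"
                    )
            lines.append("\t".join(fields))
        path.write_text("\n".join(lines) + "\n", "utf-8")
    elif dialect == "yaml":
        payload = [
            {"literal": e.literal, "category": e.category, "regex": e.regex, "rule": e.rule}
            for e in entries
        ]
        path.write_text(yaml.safe_dump(payload, sort_keys=False, allow_unicode=True), "utf-8")
    else:
        raise ValidationError(f"unknown lexicon dialect {dialect!r} (tsv or yaml)")


def read_lexicons(path: str | Path, dialect: str = "tsv") -> list[LexiconEntry]:
    path = Path(path)
    if dialect == "tsv":
        lines = path.read_text("utf-8").splitlines()
        if not lines or lines[0] != _TSV_HEADER:
            raise ParseError(f"{path.name}: missing TSV lexicon header", line=1)
        entries = []
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path.name}: expected 4 columns", line=i)
            literal, category, regex, rule = cols
            entries.append(LexiconEntry(literal, category, regex or None, rule))
        return entries
    if dialect == "yaml":
        payload = yaml.safe_load(path.read_text("utf-8")) or []
        if not isinstance(payload, list):
            raise ParseError(f"{path.name}: YAML lexicon must be a list")
        return [
            LexiconEntry(d["literal"], d["category"], d.get("regex"), d.get("rule", ""))
            for d in payload
        ]
    raise ValidationError(f"unknown lexicon dialect {dialect!r} (tsv or yaml)")
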