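"""Minimal ConText-style extraction engine.

A small, declared-rules demonstration engine so schemas can be exercised
end-to-end: sentence segmentation, case-insensitive word-boundary target
matching (longest match first, then leftmost), and directional,
sentence-bounded modifier scoping — each modifier cue extends forward,
backward or both from its position to the sentence boundary or the nearest
terminate cue, and for each mention the *nearest* in-scope cue per modifier
category wins.  It is not a re-implementation of any particular engine's full
feature set (no uncertainty composition, no graph output).

Spans are 0-based, half-open character offsets into the document text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence
from xml.etree import ElementTree as ET
from xml.dom import minidom

from .nlp_export import TERMINATE_CATEGORY, LexiconEntry
from .registry import ModifierRegistry, load_registry

# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

#: tokens whose trailing period does not end a sentence
ABBREVIATION_GUARDS = frozenset(
    {"dr.", "mr.", "mrs.", "ms.", "prof.", "st.", "vs.", "etc.", "e.g.", "i.e.", "fig.", "approx."}
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)|\n+")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split on sentence terminators (``. ! ?`` and newline runs) with an
    abbreviation guard; the returned spans tile the text without overlap."""
    if not text:
        return []
    breaks: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        if m.group().startswith("."):
            prefix = text[: m.end()]
            tail = re.search(r"(\S+)$", prefix)
            if tail and tail.group(1).lower() in ABBREVIATION_GUARDS:
                continue
        breaks.append(m.end())
    if not breaks or breaks[-1] != len(text):
        breaks.append(len(text))
    spans: list[tuple[int, int]] = []
    start = 0
    for end in breaks:
        if text[start:end].strip():
            spans.append((start, end))
        elif spans:  # merge whitespace-only tails so spans keep tiling
            spans[-1] = (spans[-1][0], end)
        start = end
    if spans and spans[-1][1] != len(text):
        spans[-1] = (spans[-1][0], len(text))
    if spans:
        spans[0] = (0, spans[0][1])
    return spans


# ---------------------------------------------------------------------------
# mentions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mention:
    doc_id: str
    sentence_index: int
    span: tuple[int, int]
    text: str
    category: str


@dataclass(frozen=True)
class AnnotatedMention:
    mention: Mention
    modifiers: tuple[tuple[str, str], ...] = ()  # sorted (category-class, value-token) pairs

    def modifier_map(self) -> dict[str, str]:
        return dict(self.modifiers)


@dataclass
class CompiledLexicon:
    entries: list[LexiconEntry]
    patterns: list[re.Pattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = [re.compile(e.pattern, re.IGNORECASE) for e in self.entries]


def compile_lexicon(entries: Iterable[LexiconEntry]) -> CompiledLexicon:
    return CompiledLexicon(entries=list(entries))


def _candidates(
    text: str, span: tuple[int, int], lexicon: CompiledLexicon
) -> list[tuple[int, int, str, str]]:
    """All raw matches in the sentence: (start, end, category, rule)."""
    start, end = span
    found = []
    for entry, pattern in zip(lexicon.entries, lexicon.patterns):
        for m in pattern.finditer(text, start, end):
            found.append((m.start(), m.end(), entry.category, entry.rule))
    return found


def match_targets(
    text: str,
    sentence_span: tuple[int, int],
    lexicon: CompiledLexicon,
    doc_id: str = "doc",
    sentence_index: int = 0,
) -> list[Mention]:
    """Find target mentions in one sentence.

    Overlapping candidates resolve longest-match-first, then leftmost (then
    lexicographic category, for determinism); every character position ends
    up in at most one mention.  Output is independent of lexicon entry order.
    """
    candidates = _candidates(text, sentence_span, lexicon)
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    taken: list[tuple[int, int]] = []
    mentions = []
    for start, end, category, _rule in candidates:
        if any(start < t_end and t_start < end for t_start, t_end in taken):
            continue
        taken.append((start, end))
        mentions.append(
            Mention(
                doc_id=doc_id,
                sentence_index=sentence_index,
                span=(start, end),
                text=text[start:end],
                category=category,
            )
        )
    mentions.sort(key=lambda m: m.span)
    return mentions


def default_category_resolver(registry: ModifierRegistry | None = None) -> Callable[[str], str]:
    """Map a modifier-lexicon category (a value token) to its modifier
    class/category name: shared values by catalog lookup, semantic values by
    their ``Value_Class`` token suffix; unknown tokens map to themselves."""
    reg = registry or load_registry()
    index = reg.value_token_index()
    class_tokens = sorted(reg.class_tokens().items(), key=lambda kv: -len(kv[0]))

    def resolve(value_token: str) -> str:
        if value_token in index:
            return index[value_token]
        for ctoken, cname in class_tokens:
            if value_token.endswith("_" + ctoken):
                return cname
        return value_token

    return resolve


def apply_modifiers(
    text: str,
    sentence_span: tuple[int, int],
    mentions: Sequence[Mention],
    modifier_lexicon: CompiledLexicon,
    resolver: Callable[[str], str] | None = None,
) -> list[AnnotatedMention]:
    """Attach modifier values to mentions by directional cue scope.

    A *forward* cue scopes from its end to the sentence end, a *backward* cue
    from the sentence start to its beginning, a *bidirectional* cue both ways;
    a *terminate* cue truncates any scope crossing it.  Per modifier category
    the cue nearest to the mention wins; cues overlapping the mention itself
    are ignored.
    """
    resolve = resolver or default_category_resolver()
    sent_start, sent_end = sentence_span
    raw = _candidates(text, sentence_span, modifier_lexicon)
    terminates = sorted((s, e) for s, e, cat, rule in raw if rule == "terminate" or cat == TERMINATE_CATEGORY)
    cues = [(s, e, cat, rule) for s, e, cat, rule in raw
            if rule != "terminate" and cat != TERMINATE_CATEGORY]

    def scope(cue_start: int, cue_end: int, rule: str) -> tuple[int, int]:
        left, right = sent_start, sent_end
        for t_start, t_end in terminates:
            if t_end <= cue_start:
                left = max(left, t_end)
            elif t_start >= cue_end:
                right = min(right, t_start)
        if rule == "forward":
            return (cue_end, right)
        if rule == "backward":
            return (left, cue_start)
        return (left, right)  # bidirectional (and the default empty rule)

    annotated = []
    for mention in mentions:
        m_start, m_end = mention.span
        best: dict[str, tuple[int, str]] = {}  # class -> (distance, value token)
        for c_start, c_end, category, rule in sorted(cues):
            if c_start < m_end and m_start < c_end:
                continue  # cue overlaps the mention itself
            lo, hi = scope(c_start, c_end, rule)
            if not (m_start >= lo and m_end <= hi):
                continue
            distance = m_start - c_end if c_end <= m_start else c_start - m_end
            cls = resolve(category)
            if cls not in best or distance < best[cls][0]:
                best[cls] = (distance, category)
        annotated.append(
            AnnotatedMention(
                mention=mention,
                modifiers=tuple(sorted((cls, tok) for cls, (_d, tok) in best.items())),
            )
        )
    return annotated


# ---------------------------------------------------------------------------
# document/corpus level
# ---------------------------------------------------------------------------

def extract_document(
    doc_id: str,
    text: str,
    target_lexicon: CompiledLexicon,
    modifier_lexicon: CompiledLexicon,
    resolver: Callable[[str], str] | None = None,
) -> list[AnnotatedMention]:
    resolve = resolver or default_category_resolver()
    out: list[AnnotatedMention] = []
    for index, span in enumerate(segment_sentences(text)):
        mentions = match_targets(text, span, target_lexicon, doc_id=doc_id, sentence_index=index)
        out.extend(apply_modifiers(text, span, mentions, modifier_lexicon, resolve))
    return out


def extract_corpus(
    documents: dict[str, str],
    target_entries: Iterable[LexiconEntry],
    modifier_entries: Iterable[LexiconEntry],
    registry: ModifierRegistry | None = None,
) -> dict[str, list[AnnotatedMention]]:
    targets = compile_lexicon(target_entries)
    modifiers = compile_lexicon(modifier_entries)
    resolve = default_category_resolver(registry)
    return {
        doc_id: extract_document(doc_id, text, targets, modifiers, resolve)
        for doc_id, text in documents.items()
    }


def annotations_to_json(annotations: dict[str, list[AnnotatedMention]]) -> dict:
    return {
        doc_id: [
            {
                "span": list(a.mention.span),
                "text": a.mention.text,
                "category": a.mention.category,
                "sentence_index": a.mention.sentence_index,
                "modifiers": a.modifier_map(),
            }
            for a in items
        ]
        for doc_id, items in annotations.items()
    }


def annotations_from_json(data: dict) -> dict[str, list[AnnotatedMention]]:
    out: dict[str, list[AnnotatedMention]] = {}
    for doc_id, items in data.items():
        out[doc_id] = [
            AnnotatedMention(
                mention=Mention(
                    doc_id=doc_id,
                    sentence_index=item.get("sentence_index", 0),
                    span=tuple(item["span"]),
                    text=item["text"],
                    category=item["category"],
                ),
                modifiers=tuple(sorted(item.get("modifiers", {}).items())),
            )
            for item in items
        ]
    return out


def write_annotations(annotations: dict[str, list[AnnotatedMention]], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(annotations_to_json(annotations), indent=2, ensure_ascii=False) + "\n", "utf-8"
    )


def load_annotations(path: str | Path) -> dict[str, list[AnnotatedMention]]:
    return annotations_from_json(json.loads(Path(path).read_text("utf-8")))


def write_knowtator_xml(
    doc_id: str, annotations: Sequence[AnnotatedMention], path: str | Path
) -> None:
    """Best-effort stand-off annotation writer in a Knowtator-style XML
    layout (one ``annotation`` per mention, one ``classMention`` carrying the
    category and modifier slots).  Schema-documented, not byte-compatible
    with any particular historical tool release."""
    root = ET.Element("annotations", textSource=doc_id)
    for i, a in enumerate(annotations):
        mention_id = f"{doc_id}_mention_{i}"
        ann = ET.SubElement(root, "annotation")
        ET.SubElement(ann, "mention", id=mention_id)
        ET.SubElement(
            ann, "span", start=str(a.mention.span[0]), end=str(a.mention.span[1])
        )
        ET.SubElement(ann, "spannedText").text = a.mention.text
        cm = ET.SubElement(root, "classMention", id=mention_id)
        ET.SubElement(cm, "mentionClass", id=a.mention.category).text = a.mention.text
        for cls, value in a.modifiers:
            slot = ET.SubElement(cm, "hasSlotMention", slot=cls)
            slot.set("value", value)
    pretty = minidom.parseString(ET.tostring(root, encoding="unicode")).toprettyxml(indent="  ")
    Path(path).write_text(pretty, "utf-8")
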