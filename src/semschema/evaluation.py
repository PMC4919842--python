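"""Per-category recall of extraction output against gold annotations.

Recall — the proportion of gold mentions correctly identified — is the primary
statistic: the question a schema author cares about is whether the lexical
variants are sufficient to recover the concepts at all.  Precision is exposed
as an optional extra, off by default.

A gold target mention counts as found when a predicted mention of the same
category matches it under the span policy (``overlap``, the default, or
``exact``).  A gold modifier value counts as correct when its mention was
found *and* the matching prediction carries the same value for that modifier
category.  The report has one row for targets plus one per modifier category.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .context_engine import AnnotatedMention
from .errors import ValidationError
from .synth import GoldDocument

POLICIES = ("overlap", "exact")
TARGETS_ROW = "Targets"


@dataclass(frozen=True)
class RecallRow:
    category: str
    total: int
    correct: int
    precision: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.correct <= self.total:
            raise ValidationError("correct count must lie within [0, total]")

    @property
    def recall(self) -> float | None:
        return self.correct / self.total if self.total else None


def _spans_match(gold: tuple[int, int], pred: tuple[int, int], policy: str) -> bool:
    if policy == "exact":
        return gold == pred
    return gold[0] < pred[1] and pred[0] < gold[1]


def recall_by_category(
    gold: list[GoldDocument],
    predicted: dict[str, list[AnnotatedMention]],
    match_policy: str = "overlap",
    include_precision: bool = False,
) -> list[RecallRow]:
    """Compute the recall table.

    ``gold`` and ``predicted`` must cover the same document ids.  Rows come
    back with ``Targets`` first, then modifier categories sorted by name.
    """
    if match_policy not in POLICIES:
        raise ValidationError(f"unknown match policy {match_policy!r}; choose from {POLICIES}")
    gold_ids = {d.doc_id for d in gold}
    if gold_ids != set(predicted):
        missing = sorted(gold_ids ^ set(predicted))
        raise ValidationError(f"gold/predicted document ids differ: {', '.join(missing)}")

    target_total = target_correct = 0
    mod_total: dict[str, int] = {}
    mod_correct: dict[str, int] = {}
    matched_predictions = 0
    for doc in gold:
        preds = predicted[doc.doc_id]
        for mention in doc.mentions:
            target_total += 1
            hits = [
                p
                for p in preds
                if p.mention.category == mention.category
                and _spans_match(mention.span, p.mention.span, match_policy)
            ]
            if hits:
                target_correct += 1
            for category, value in mention.modifiers:
                mod_total[category] = mod_total.get(category, 0) + 1
                if any(p.modifier_map().get(category) == value for p in hits):
                    mod_correct[category] = mod_correct.get(category, 0) + 1
        if include_precision:
            for p in preds:
                if any(
                    m.category == p.mention.category
                    and _spans_match(m.span, p.mention.span, match_policy)
                    for m in doc.mentions
                ):
                    matched_predictions += 1

    n_predictions = sum(len(v) for v in predicted.values())
    precision = (
        (matched_predictions / n_predictions if n_predictions else None)
        if include_precision
        else None
    )
    rows = [RecallRow(TARGETS_ROW, target_total, target_correct, precision)]
    for category in sorted(mod_total):
        rows.append(RecallRow(category, mod_total[category], mod_correct.get(category, 0)))
    return rows


def rows_to_dataframe(rows: list[RecallRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "total": r.total,
                "correct": r.correct,
                "recall": float("nan") if r.recall is None else r.recall,
            }
            for r in rows
        ]
    )


def format_recall_table(rows: list[RecallRow]) -> str:
    lines = [f"{'Category':<24}{'Total':>8}{'Correct':>8}  Recall"]
    for r in rows:
        recall = "N/A" if r.recall is None else f"{100 * r.recall:.0f} %"
        lines.append(f"{r.category:<24}{r.total:>8}{r.correct:>8}  {recall}")
    return "\n".join(lines)
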