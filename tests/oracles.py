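"""Independent brute-force reference implementations used to cross-check the
extraction engine and the recall computation.

Deliberately naive: sliding-window string comparison for matching and
explicit per-cue interval arithmetic for scoping, sharing no code with the
engine beyond the declared tie-break policies.
"""

from __future__ import annotations


def _is_word(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def brute_force_candidates(text, span, entries):
    """All (start, end, category, rule) word-boundary literal matches."""
    lo, hi = span
    out = []
    for entry in entries:
        literal = entry.literal.casefold()
        n = len(literal)
        for start in range(lo, hi - n + 1):
            if text[start : start + n].casefold() != literal:
                continue
            if start > 0 and _is_word(text[start - 1]) and _is_word(literal[0]):
                continue
            end = start + n
            if end < len(text) and _is_word(text[end]) and _is_word(literal[-1]):
                continue
            out.append((start, end, entry.category, entry.rule))
    return out


def brute_force_match(text, span, entries):
    """Longest-first, then leftmost, then category selection; no two selected
    matches share a character position."""
    candidates = sorted(
        brute_force_candidates(text, span, entries),
        key=lambda c: (-(c[1] - c[0]), c[0], c[2]),
    )
    chosen = []
    for start, end, category, _ in candidates:
        if all(end <= s or e <= start for s, e, _c in chosen):
            chosen.append((start, end, category))
    return sorted(chosen)


def brute_force_modifiers(text, span, mention_span, entries, resolve):
    """Nearest in-scope cue per resolved category for one mention."""
    lo, hi = span
    raw = brute_force_candidates(text, span, entries)
    terminates = [(s, e) for s, e, c, r in raw if r == "terminate" or c == "TERMINATE"]
    m_start, m_end = mention_span
    best = {}
    for c_start, c_end, category, rule in sorted(raw):
        if rule == "terminate" or category == "TERMINATE":
            continue
        if c_start < m_end and m_start < c_end:
            continue
        left, right = lo, hi
        for t_start, t_end in terminates:
            if t_end <= c_start:
                left = max(left, t_end)
            elif t_start >= c_end:
                right = min(right, t_start)
        if rule == "forward":
            scope = (c_end, right)
        elif rule == "backward":
            scope = (left, c_start)
        else:
            scope = (left, right)
        if not (m_start >= scope[0] and m_end <= scope[1]):
            continue
        distance = m_start - c_end if c_end <= m_start else c_start - m_end
        cls = resolve(category)
        if cls not in best or distance < best[cls][0]:
            best[cls] = (distance, category)
    return {cls: tok for cls, (_d, tok) in best.items()}


def brute_force_recall(gold_docs, predicted, policy="overlap"):
    """Category -> (total, correct) by exhaustive pairwise comparison."""

    def match(a, b):
        return a == b if policy == "exact" else (a[0] < b[1] and b[0] < a[1])

    counts = {"Targets": [0, 0]}
    for doc in gold_docs:
        preds = predicted[doc.doc_id]
        for gm in doc.mentions:
            counts["Targets"][0] += 1
            hits = [
                p
                for p in preds
                if p.mention.category == gm.category and match(gm.span, p.mention.span)
            ]
            if hits:
                counts["Targets"][1] += 1
            for category, value in gm.modifiers:
                counts.setdefault(category, [0, 0])[0] += 1
                if any(dict(p.modifiers).get(category) == value for p in hits):
                    counts[category][1] += 1
    return {k: tuple(v) for k, v in counts.items()}
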