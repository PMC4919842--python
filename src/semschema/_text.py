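"""Token and identifier helpers shared across modules.

The OWL dialect composes class local names from value and modifier-class
tokens (``Mild_Severity``); the NLP lexicons reuse the same tokens as
categories, so target/modifier categories, OWL fillers, synthetic gold
annotations and evaluation rows all agree on one spelling.
"""

from __future__ import annotations

import re

_WORD_RE = re.compile(r"[A-Za-z0-9]+")


def token(text: str) -> str:
    """Upper-camel underscore token: ``'not abnormal' -> 'Not_Abnormal'``.

    Words already containing capitals keep them (``'ER' -> 'ER'``); all
    non-alphanumeric characters act as separators (``'N/A' -> 'N_A'``).
    """
    words = _WORD_RE.findall(text)
    if not words:
        raise ValueError(f"cannot tokenize {text!r}")
    return "_".join(w[:1].upper() + w[1:] for w in words)


def slug(text: str) -> str:
    """Lower-case identifier: ``'Internal Carotid Artery' -> 'internal_carotid_artery'``."""
    words = _WORD_RE.findall(text)
    if not words:
        raise ValueError(f"cannot slugify {text!r}")
    return "_".join(w.lower() for w in words)


def normalize_term(text: str) -> str:
    """Fold case, punctuation and whitespace for term comparison."""
    return " ".join(_WORD_RE.findall(text)).lower()


def collapse_ws(text: str) -> str:
    return " ".join(text.split())
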