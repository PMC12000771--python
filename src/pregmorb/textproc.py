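"""Normalisation, tokenisation and term-frequency reporting for EMR free text.

Semi-structured condition fields in maternity records hold short,
clinician-entered strings ("Asthma; Vit D deficiency (2019)") that must be
normalised before keyword extraction. The pipeline here is fixed:
``clean_text`` -> ``tokenize`` -> ``remove_stopwords`` -> ``term_frequencies``.

Cleaning lowercases, strips punctuation, and drops digit-only tokens while
preserving alphanumeric clinical abbreviations such as ``t2dm``.
"""

from __future__ import annotations

import string
from collections import Counter
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "clean_text",
    "tokenize",
    "remove_stopwords",
    "term_frequencies",
    "default_stopwords",
]

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def clean_text(raw: str) -> str:
    """Lowercase, replace punctuation with spaces, drop digit-only tokens.

    Runs of whitespace collapse to a single space; the result is stripped.
    Tokens that mix digits and letters (``t2dm``) are kept intact. Total
    function: any string, including empty, is accepted.
    """
    lowered = raw.lower().translate(_PUNCT_TABLE)
    kept = [tok for tok in lowered.split() if not tok.isdigit()]
    return " ".join(kept)


def tokenize(cleaned: str) -> list[str]:
    """Split cleaned text on whitespace, preserving order."""
    return cleaned.split()


def remove_stopwords(tokens: Iterable[str], stopwords: frozenset[str] | set[str]) -> list[str]:
    """Order-preserving filter removing tokens that appear in *stopwords*."""
    return [t for t in tokens if t not in stopwords]


def term_frequencies(
    corpus: Iterable[Sequence[str]], top_n: int
) -> list[tuple[str, int]]:
    """Top *top_n* (term, count) pairs over a tokenised corpus.

    Descending by count, ties broken lexicographically. Empty corpus gives
    an empty table.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(doc)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:top_n]


def default_stopwords() -> frozenset[str]:
    """Stopword list shipped with the package (one word per line, UTF-8)."""
    text = resources.files("pregmorb.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w and not w.startswith("#"))
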