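"""Rule-based morbidity extraction with exact phrase matching and fuzzy fallback.

Each record's free-text condition field is converted to a binary morbidity
profile in two phases:

1. **Phrase phase** — multi-token keywords are matched as contiguous token
   runs, longest phrase first; a matched span is consumed so its tokens
   cannot fire again ("iron deficiency anaemia" sets iron-deficiency anemia,
   not generic anemia). Exclusion phrases consume a span without setting any
   flag.
2. **Token phase** — each remaining token is compared exactly against all
   one-word keywords; on failure, a Levenshtein similarity fallback handles
   minor typos ("astma" -> asthma at similarity 83).

Overweight (25.0 <= BMI < 30 kg/m²), obesity (BMI >= 30) and advanced
maternal age (>= 35 years) are derived from the structured columns; the two
BMI flags are mutually exclusive by construction. Negation is deliberately
not modelled: the source fields record conditions only when present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .lexicon import MorbidityLexicon
from .textproc import clean_text, tokenize

__all__ = [
    "ExtractionConfig",
    "levenshtein_distance",
    "levenshtein_similarity",
    "match_conditions",
    "derive_bmi_flags",
    "derive_advanced_age",
    "extract_cohort",
    "burden_class_of",
    "BURDEN_NONE",
    "BURDEN_SINGLE",
    "BURDEN_MULTI",
]

BURDEN_NONE = "none"
BURDEN_SINGLE = "single"
BURDEN_MULTI = "multimorbidity"

REQUIRED_COLUMNS = ("record_id", "maternal_age", "bmi", "medical_conditions_text")


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds and derived-variable cutoffs for the extraction stage.

    ``default_fuzzy_threshold`` of 85 accepts one edit in a 7-letter token
    while rejecting short-token noise; tokens shorter than
    ``min_fuzzy_token_length`` are never fuzzy-matched. The burden count by
    default covers every lexicon condition plus the two BMI-derived flags
    but not advanced age or substance use, which the study tabulates as
    separate characteristics; pass ``conditions_counted_in_burden`` to
    change that.
    """

    default_fuzzy_threshold: int = 85
    min_fuzzy_token_length: int = 5
    overweight_lower: float = 25.0
    obese_lower: float = 30.0
    advanced_age_lower: float = 35.0
    conditions_counted_in_burden: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.default_fuzzy_threshold <= 100:
            raise ValueError("default_fuzzy_threshold must lie in [0, 100]")
        if self.overweight_lower >= self.obese_lower:
            raise ValueError("overweight_lower must be below obese_lower")

    def burden_set(self, lexicon: MorbidityLexicon) -> frozenset[str]:
        if self.conditions_counted_in_burden is not None:
            return self.conditions_counted_in_burden
        counted = set(lexicon.condition_ids) | {"overweight", "obesity"}
        counted -= {"advanced_age", "substance_use"}
        return frozenset(counted)


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute), iterative DP."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,  # deletion
                    current[j - 1] + 1,  # insertion
                    previous[j - 1] + (ca != cb),  # substitution
                )
            )
        previous = current
    return previous[-1]


def levenshtein_similarity(a: str, b: str) -> int:
    """Similarity score 0–100: ``round(100 * (1 - D/max(|a|, |b|)))``.

    Symmetric; 100 iff the tokens are equal. Raises on empty input — an
    empty token has no meaningful similarity to anything.
    """
    if not a or not b:
        raise ValueError("levenshtein_similarity requires non-empty tokens")
    longest = max(len(a), len(b))
    return int(math.floor(100.0 * (1.0 - levenshtein_distance(a, b) / longest) + 0.5))


def _fuzzy_could_reach(token: str, keyword: str, threshold: int) -> bool:
    # Length difference alone bounds attainable similarity; cheap pre-filter.
    longest = max(len(token), len(keyword))
    best = 100.0 * (1.0 - abs(len(token) - len(keyword)) / longest)
    return best >= threshold


def match_conditions(
    tokens: Sequence[str],
    lexicon: MorbidityLexicon,
    config: ExtractionConfig | None = None,
) -> dict[str, int]:
    """Map a cleaned token sequence to per-condition 0/1 flags.

    Tokens must already be cleaned and tokenised; stopwords are left in
    place (phrase keywords may contain them, and stray fillers simply fail
    to match). A condition's flag is 1 iff at least one keyword matched.
    """
    config = config or ExtractionConfig()
    flags = {cid: 0 for cid in lexicon.condition_ids}
    if not tokens:
        return flags

    n = len(tokens)
    consumed = [False] * n
    # Phase 1: contiguous phrase runs, longest first; exclusions win ties.
    for phrase, cid in lexicon.phrase_index():
        plen = len(phrase)
        if plen > n:
            continue
        i = 0
        while i + plen <= n:
            window = tuple(tokens[i : i + plen])
            if window == phrase and not any(consumed[i : i + plen]):
                for j in range(i, i + plen):
                    consumed[j] = True
                if cid is not None:
                    flags[cid] = 1
                i += plen
            else:
                i += 1

    # Phase 2: single tokens — exact, then fuzzy fallback.
    exact_index = lexicon.single_token_index()
    for i, tok in enumerate(tokens):
        if consumed[i]:
            continue
        owners = exact_index.get(tok)
        if owners:
            for cid in owners:
                flags[cid] = 1
            continue
        if len(tok) < config.min_fuzzy_token_length:
            continue
        for entry in lexicon:
            if flags[entry.condition_id]:
                continue
            threshold = (
                entry.fuzzy_threshold
                if entry.fuzzy_threshold is not None
                else config.default_fuzzy_threshold
            )
            for keyword in entry.single_tokens:
                if not _fuzzy_could_reach(tok, keyword, threshold):
                    continue
                if levenshtein_similarity(tok, keyword) >= threshold:
                    flags[entry.condition_id] = 1
                    break
    return flags


def derive_bmi_flags(
    bmi: float | None, config: ExtractionConfig | None = None
) -> tuple[int, int]:
    """(overweight, obesity) from prepregnancy BMI; missing -> (0, 0)."""
    config = config or ExtractionConfig()
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        return (0, 0)
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi >= config.obese_lower:
        return (0, 1)
    if bmi >= config.overweight_lower:
        return (1, 0)
    return (0, 0)


def derive_advanced_age(age: float | None, config: ExtractionConfig | None = None) -> int:
    """1 iff maternal age >= 35 years; missing -> 0."""
    config = config or ExtractionConfig()
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return 0
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return int(age >= config.advanced_age_lower)


def burden_class_of(count: int) -> str:
    if count == 0:
        return BURDEN_NONE
    if count == 1:
        return BURDEN_SINGLE
    return BURDEN_MULTI


def extract_cohort(
    records: pd.DataFrame,
    lexicon: MorbidityLexicon,
    config: ExtractionConfig | None = None,
    text_column: str = "medical_conditions_text",
) -> pd.DataFrame:
    """Extract one morbidity profile per record.

    Returns a DataFrame with ``record_id``, one 0/1 column per lexicon
    condition, the derived ``overweight``/``obesity``/``advanced_age``
    flags, ``morbidity_count`` and ``burden_class``. Raises on missing
    required columns.
    """
    config = config or ExtractionConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns and c != text_column]
    if text_column not in records.columns:
        missing.append(text_column)
    if missing:
        raise KeyError(f"input table is missing required columns: {sorted(set(missing))}")

    counted = config.burden_set(lexicon)
    rows = []
    for rec in records.itertuples(index=False):
        text = getattr(rec, text_column)
        tokens = tokenize(clean_text("" if pd.isna(text) else str(text)))
        flags = match_conditions(tokens, lexicon, config)
        bmi = getattr(rec, "bmi", None)
        bmi = None if pd.isna(bmi) else float(bmi)
        age = getattr(rec, "maternal_age", None)
        age = None if pd.isna(age) else float(age)
        overweight, obesity = derive_bmi_flags(bmi, config)
        flags["overweight"] = overweight
        flags["obesity"] = obesity
        flags["advanced_age"] = derive_advanced_age(age, config)
        count = sum(v for k, v in flags.items() if k in counted)
        rows.append(
            {
                "record_id": rec.record_id,
                **flags,
                "morbidity_count": count,
                "burden_class": burden_class_of(count),
            }
        )
    return pd.DataFrame(rows)
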