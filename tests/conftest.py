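import pandas as pd
import pytest

from pregmorb.extraction import ExtractionConfig
from pregmorb.lexicon import (
    LexiconEntry,
    MorbidityLexicon,
    default_complication_lexicon,
    default_morbidity_lexicon,
)
from pregmorb.synthetic import DEFAULT_CONDITION_PREVALENCES


@pytest.fixture(scope="session")
def lexicon() -> MorbidityLexicon:
    return default_morbidity_lexicon()


@pytest.fixture(scope="session")
def complication_lexicon() -> MorbidityLexicon:
    return default_complication_lexicon()


@pytest.fixture(scope="session")
def config() -> ExtractionConfig:
    return ExtractionConfig()


@pytest.fixture(scope="session")
def long_keyword_lexicon(lexicon) -> MorbidityLexicon:
    """Default lexicon restricted to single-token keywords of length >= 6.

    Used by the noisy-extraction benchmark: a single-character typo in a
    token of length >= 6 keeps Levenshtein similarity at >= 83, so fuzzy
    matching at threshold 80 should recover nearly all mentions.
    """
    entries = {}
    for e in lexicon:
        long_kws = tuple((t,) for t in e.single_tokens if len(t) >= 6)
        if long_kws:
            entries[e.condition_id] = LexiconEntry(
                e.condition_id, e.display_name, long_kws
            )
    return MorbidityLexicon(entries=entries)


@pytest.fixture(scope="session")
def long_keyword_prevalences(long_keyword_lexicon) -> dict[str, float]:
    return {
        cid: DEFAULT_CONDITION_PREVALENCES[cid]
        for cid in long_keyword_lexicon.condition_ids
    }


@pytest.fixture()
def tiny_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": ["r1", "r2", "r3"],
            "maternal_age": [28, 36, 41],
            "bmi": [22.0, 31.0, float("nan")],
            "parity": [0, 1, 2],
            "ethnicity": ["oceania", "caucasian", "other"],
            "medical_conditions_text": ["", "PCOS; hypothyroid", "Asthma,  DEPRESSION (2019)!!"],
            "complications_text": ["", "gdm", ""],
        }
    )
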