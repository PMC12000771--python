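"""Condition lexicons: curated keyword/phrase lists for rule-based extraction.

A lexicon maps a condition identifier (``thyroid_disease``) to the surface
forms clinicians write for it ("thyroid", "hypothyroidism", "graves
disease"). Multi-token keywords are matched as contiguous phrases; optional
exclusion phrases consume a span without setting the flag (e.g. "gestational
diabetes" under preexisting diabetes). All keywords are normalised through
the same cleaning rules as the input text, so matching is case- and
punctuation-insensitive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

from .textproc import clean_text

__all__ = [
    "LexiconEntry",
    "MorbidityLexicon",
    "LexiconError",
    "load_lexicon",
    "default_morbidity_lexicon",
    "default_complication_lexicon",
]


class LexiconError(ValueError):
    """Malformed lexicon file or schema violation."""


@dataclass(frozen=True)
class LexiconEntry:
    condition_id: str
    display_name: str
    keywords: tuple[tuple[str, ...], ...]  # each keyword as a token tuple
    exclusions: tuple[tuple[str, ...], ...] = ()
    fuzzy_threshold: int | None = None  # None -> inherit run default

    @property
    def single_tokens(self) -> tuple[str, ...]:
        return tuple(kw[0] for kw in self.keywords if len(kw) == 1)

    @property
    def phrases(self) -> tuple[tuple[str, ...], ...]:
        return tuple(kw for kw in self.keywords if len(kw) > 1)


@dataclass
class MorbidityLexicon:
    """Ordered collection of :class:`LexiconEntry`, keyed by condition id."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self.entries

    def __getitem__(self, condition_id: str) -> LexiconEntry:
        return self.entries[condition_id]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.entries)

    def single_token_index(self) -> dict[str, set[str]]:
        """token -> set of condition ids claiming it as a one-word keyword."""
        index: dict[str, set[str]] = {}
        for entry in self:
            for tok in entry.single_tokens:
                index.setdefault(tok, set()).add(entry.condition_id)
        return index

    def phrase_index(self) -> list[tuple[tuple[str, ...], str | None]]:
        """All multi-token keywords and all exclusions, longest first.

        Each item is ``(token_tuple, condition_id)`` for a keyword phrase or
        ``(token_tuple, None)`` for an exclusion. Exclusions sort before
        keywords of equal length so they take precedence on the same span.
        """
        items: list[tuple[tuple[str, ...], str | None]] = []
        for entry in self:
            for phrase in entry.phrases:
                items.append((phrase, entry.condition_id))
            for excl in entry.exclusions:
                items.append((excl, None))
        items.sort(key=lambda it: (-len(it[0]), it[1] is not None, it[0]))
        return items

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Mapping]) -> "MorbidityLexicon":
        if not isinstance(raw, Mapping) or not raw:
            raise LexiconError("lexicon document must be a non-empty mapping")
        entries: dict[str, LexiconEntry] = {}
        for cid, spec in raw.items():
            if cid in entries:
                raise LexiconError(f"duplicate condition id: {cid!r}")
            if not isinstance(spec, Mapping):
                raise LexiconError(f"entry for {cid!r} must be a mapping")
            keywords_raw = spec.get("keywords")
            if not keywords_raw:
                raise LexiconError(f"entry {cid!r} has an empty keyword list")
            keywords = []
            for kw in keywords_raw:
                norm = clean_text(str(kw))
                if not norm:
                    raise LexiconError(f"entry {cid!r}: keyword {kw!r} normalises to nothing")
                keywords.append(tuple(norm.split()))
            exclusions = tuple(
                tuple(clean_text(str(e)).split()) for e in spec.get("exclusions", []) or []
            )
            thr = spec.get("fuzzy_threshold")
            if thr is not None and not (0 <= int(thr) <= 100):
                raise LexiconError(f"entry {cid!r}: fuzzy_threshold outside [0, 100]")
            entries[cid] = LexiconEntry(
                condition_id=cid,
                display_name=str(spec.get("display_name", cid)),
                keywords=tuple(keywords),
                exclusions=exclusions,
                fuzzy_threshold=None if thr is None else int(thr),
            )
        return cls(entries=entries)


def load_lexicon(path: str | Path) -> MorbidityLexicon:
    """Load and validate a YAML lexicon file."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LexiconError(f"cannot parse lexicon file {path}: {exc}") from exc
    if raw is None:
        raise LexiconError(f"lexicon file {path} is empty")
    return MorbidityLexicon.from_mapping(raw)


def _load_packaged(name: str) -> MorbidityLexicon:
    text = resources.files("pregmorb.data").joinpath(name).read_text("utf-8")
    return MorbidityLexicon.from_mapping(yaml.safe_load(text))


def default_morbidity_lexicon() -> MorbidityLexicon:
    """The lexicon shipped with the package (~22 maternal conditions)."""
    return _load_packaged("morbidity_lexicon.yaml")


def default_complication_lexicon() -> MorbidityLexicon:
    """Obstetric/labour complication lexicon (same schema)."""
    return _load_packaged("complication_lexicon.yaml")
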