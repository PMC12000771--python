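"""Seeded synthetic maternity cohorts with recoverable ground truth.

The generator emulates the structure of a routinely collected maternity
dataset: structured columns (age, prepregnancy BMI, parity, ethnicity) plus
semi-structured free-text fields that list condition names only when a
condition is present and stay empty otherwise. Every record carries a known
truth — condition flags, latent comorbidity cluster, outcome label — so the
extraction, association and clustering stages can be scored against it.

Condition flags are drawn either independently from configured marginal
prevalences or from latent cluster profiles (mixture of Bernoulli product
profiles). The gestational-diabetes analogue outcome follows a logistic
model in the *true* flags, keeping measurement error (text noise) cleanly
separated from association truth. Text is rendered per record by choosing
one keyword per flagged condition and perturbing it with configurable
noise: single-character typos, random capitalisation, interleaved filler
stopwords and year-like numbers, and a bias toward abbreviated surface
forms.

Each record owns a private random stream derived from ``(seed, index)``, so
output is byte-identical regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import ExtractionConfig, derive_advanced_age, derive_bmi_flags
from .lexicon import MorbidityLexicon, default_complication_lexicon, default_morbidity_lexicon

__all__ = [
    "NoiseConfig",
    "ClusterSpec",
    "OutcomeModel",
    "SimulationConfig",
    "ConfigurationError",
    "LexiconCoverageError",
    "generate_cohort",
    "generate_truth",
    "render_condition_text",
    "DEFAULT_CONDITION_PREVALENCES",
    "DEFAULT_COMPLICATION_PREVALENCES",
    "DEFAULT_OUTCOME_MODEL",
    "AGE_BANDS",
    "BMI_BANDS",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


class LexiconCoverageError(KeyError):
    """A flagged condition has no entry in the rendering lexicon."""


# Marginal prevalences mirroring the published cohort's condition frequencies
# (e.g. vitamin deficiency ~29%, substance use ~12%, mental disorders ~9%).
DEFAULT_CONDITION_PREVALENCES: dict[str, float] = {
    "mental_disorders": 0.089,
    "pcos": 0.030,
    "cardiovascular_disease": 0.031,
    "substance_use": 0.124,
    "thyroid_disease": 0.074,
    "urinary_tract_infection": 0.020,
    "hypertension": 0.012,
    "vitamin_deficiency": 0.289,
    "asthma": 0.085,
    "other_respiratory_disease": 0.005,
    "blood_disorders": 0.099,
    "iron_deficiency_anemia": 0.027,
    "endometrial_disease": 0.040,
    "migraine": 0.026,
    "kidney_disease": 0.008,
    "bowel_disease": 0.006,
    "genital_herpes": 0.006,
    "hemorrhoids": 0.005,
    "autoimmune_disease": 0.007,
    "musculoskeletal_disease": 0.014,
    "infertility": 0.003,
    "preexisting_diabetes": 0.010,
}

# Non-outcome complication marginals (induction ~30%, cesarean ~29%, ...).
DEFAULT_COMPLICATION_PREVALENCES: dict[str, float] = {
    "induction": 0.301,
    "cesarean": 0.289,
    "scn_nicu": 0.181,
    "macrosomia": 0.089,
    "preterm": 0.084,
    "birth_defect": 0.051,
    "preeclampsia": 0.035,
    "pih": 0.023,
    "shoulder_dystocia": 0.022,
}

# Age bands and weights following the cohort's reported distribution;
# integer ages drawn uniformly inside the band.
AGE_BANDS: tuple[tuple[int, int, float], ...] = (
    (18, 24, 0.127),
    (25, 29, 0.285),
    (30, 34, 0.363),
    (35, 39, 0.182),
    (40, 45, 0.043),
)

# BMI bands [lower, upper) and weights; value drawn uniformly inside.
BMI_BANDS: tuple[tuple[float, float, float], ...] = (
    (16.0, 20.0, 0.086),
    (20.0, 25.0, 0.395),
    (25.0, 27.0, 0.137),
    (27.0, 30.0, 0.150),
    (30.0, 35.0, 0.129),
    (35.0, 45.0, 0.098),
)

ETHNICITY_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("caucasian", 0.038),
    ("oceania", 0.438),
    ("mena_africa", 0.061),
    ("south_central_asian", 0.300),
    ("se_ne_asian", 0.160),
    ("other", 0.003),
)

PARITY_WEIGHTS: tuple[tuple[int, float], ...] = ((0, 0.399), (1, 0.363), (2, 0.238))

_FILLER_WORDS = ("history", "of", "on", "in", "hx", "known", "since", "with")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-token text perturbation rates, each a probability in [0, 1]."""

    typo_rate: float = 0.0
    abbreviation_rate: float = 0.0
    filler_rate: float = 0.0
    uppercase_rate: float = 0.0

    def validate(self) -> None:
        for name in ("typo_rate", "abbreviation_rate", "filler_rate", "uppercase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"noise.{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ClusterSpec:
    """Latent comorbidity profiles: mixture weights + per-profile condition
    probabilities. Records drawn from profile ℓ get each condition
    independently with that profile's probability."""

    weights: tuple[float, ...]
    profiles: tuple[Mapping[str, float], ...]

    def validate(self) -> None:
        if len(self.weights) != len(self.profiles) or not self.profiles:
            raise ConfigurationError("cluster_spec: weights and profiles must align, L >= 1")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("cluster_spec.weights must sum to 1 within 1e-9")
        for i, prof in enumerate(self.profiles):
            for cid, p in prof.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"cluster_spec.profiles[{i}][{cid!r}] outside [0, 1]"
                    )


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for the simulated GDM outcome: logit(p) = intercept +
    sum over flagged conditions of their log odds ratios. Keys may include
    the derived flags (overweight, obesity, advanced_age)."""

    intercept: float
    log_odds_ratios: Mapping[str, float] = field(default_factory=dict)

    def probability(self, flags: Mapping[str, int]) -> float:
        logit = self.intercept + sum(
            lor for cid, lor in self.log_odds_ratios.items() if flags.get(cid, 0)
        )
        return 1.0 / (1.0 + math.exp(-logit))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


# Intercept calibrated once so the marginal outcome prevalence sits near the
# cohort's ~21% GDM under the default prevalences and effect sizes.
DEFAULT_OUTCOME_MODEL = OutcomeModel(
    intercept=_logit(0.135),
    log_odds_ratios={
        "obesity": math.log(2.2),
        "overweight": math.log(1.4),
        "advanced_age": math.log(1.8),
        "vitamin_deficiency": math.log(1.35),
        "thyroid_disease": math.log(1.4),
        "pcos": math.log(1.9),
        "preexisting_diabetes": math.log(3.0),
        "infertility": math.log(2.2),
    },
)


@dataclass(frozen=True)
class SimulationConfig:
    n_records: int = 1000
    condition_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCES)
    )
    outcome_model: OutcomeModel = DEFAULT_OUTCOME_MODEL
    cluster_spec: ClusterSpec | None = None
    noise: NoiseConfig = NoiseConfig()
    complication_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLICATION_PREVALENCES)
    )
    age_bands: tuple[tuple[int, int, float], ...] = AGE_BANDS
    bmi_bands: tuple[tuple[float, float, float], ...] = BMI_BANDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise ConfigurationError(f"n_records must be >= 1, got {self.n_records}")
        for cid, p in self.condition_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"condition_prevalences[{cid!r}] outside [0, 1]")
        for cid, p in self.complication_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"complication_prevalences[{cid!r}] outside [0, 1]")
        self.noise.validate()
        if self.cluster_spec is not None:
            self.cluster_spec.validate()
            for prof in self.cluster_spec.profiles:
                unknown = set(prof) - set(self.condition_prevalences)
                if unknown:
                    raise ConfigurationError(
                        f"cluster_spec profile names unknown conditions: {sorted(unknown)}"
                    )


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _weighted_choice(rng: np.random.Generator, weights: Sequence[float]) -> int:
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(len(w), p=w / w.sum()))


def _apply_typo(token: str, rng: np.random.Generator) -> str:
    if len(token) < 2:
        return token
    pos = int(rng.integers(len(token)))
    if rng.random() < 0.5:  # deletion
        return token[:pos] + token[pos + 1 :]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    repl = alphabet[int(rng.integers(26))]
    while repl == token[pos]:
        repl = alphabet[int(rng.integers(26))]
    return token[:pos] + repl + token[pos + 1 :]


def render_condition_text(
    flags: Mapping[str, int],
    lexicon: MorbidityLexicon,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> str:
    """Render flagged conditions into a semi-structured free-text field.

    Empty string when no flag is set (the empty-field convention). For each
    flagged condition, one keyword is drawn — biased toward the entry's
    shortest surface form with probability ``abbreviation_rate`` — then
    perturbed: each token suffers a single-character substitution or
    deletion with probability ``typo_rate`` and full uppercasing with
    probability ``uppercase_rate``; fillers (stopwords or a year) are
    interleaved with probability ``filler_rate`` per condition. Terms are
    joined with "; " and a trailing period appears at ``filler_rate``.
    """
    flagged = [cid for cid, v in flags.items() if v]
    if not flagged:
        return ""
    parts: list[str] = []
    for cid in flagged:
        if cid not in lexicon:
            raise LexiconCoverageError(f"flagged condition {cid!r} not in rendering lexicon")
        entry = lexicon[cid]
        keywords = entry.keywords
        if noise.abbreviation_rate > 0 and rng.random() < noise.abbreviation_rate:
            min_len = min(sum(len(t) for t in kw) for kw in keywords)
            pool = [kw for kw in keywords if sum(len(t) for t in kw) == min_len]
        else:
            pool = list(keywords)
        chosen = pool[int(rng.integers(len(pool)))]
        tokens = []
        for tok in chosen:
            if noise.typo_rate > 0 and rng.random() < noise.typo_rate:
                tok = _apply_typo(tok, rng)
            if noise.uppercase_rate > 0 and rng.random() < noise.uppercase_rate:
                tok = tok.upper()
            tokens.append(tok)
        if noise.filler_rate > 0 and rng.random() < noise.filler_rate:
            if rng.random() < 0.5:
                filler = _FILLER_WORDS[int(rng.integers(len(_FILLER_WORDS)))]
            else:
                filler = str(int(rng.integers(1990, 2024)))
            tokens.insert(int(rng.integers(len(tokens) + 1)), filler)
        parts.append(" ".join(tokens))
    text = "; ".join(parts)
    if noise.filler_rate > 0 and rng.random() < noise.filler_rate:
        text += "."
    return text


def _draw_flags(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, int], int]:
    cids = list(config.condition_prevalences)
    if config.cluster_spec is not None:
        cluster = _weighted_choice(rng, config.cluster_spec.weights)
        profile = config.cluster_spec.profiles[cluster]
        probs = np.array([profile.get(cid, 0.0) for cid in cids])
    else:
        cluster = -1
        probs = np.array([config.condition_prevalences[cid] for cid in cids])
    draws = rng.random(len(cids)) < probs
    return {cid: int(v) for cid, v in zip(cids, draws)}, cluster


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Flags-only fast path: ground truth without text rendering.

    Returns one row per record with record_id, cluster_id, structured
    fields, condition flags, derived flags, the gdm outcome and the other
    complication flags. ``generate_cohort`` builds on this table.
    """
    config.validate()
    ext = ExtractionConfig()
    rows = []
    for i in range(config.n_records):
        rng = _record_rng(config.seed, i)
        flags, cluster = _draw_flags(config, rng)

        band = _weighted_choice(rng, [w for _, _, w in config.age_bands])
        lo, hi, _ = config.age_bands[band]
        age = int(rng.integers(lo, hi + 1))
        band = _weighted_choice(rng, [w for _, _, w in config.bmi_bands])
        lo_b, hi_b, _ = config.bmi_bands[band]
        bmi = round(float(rng.uniform(lo_b, hi_b)), 1)
        ethnicity = ETHNICITY_CATEGORIES[
            _weighted_choice(rng, [w for _, w in ETHNICITY_CATEGORIES])
        ][0]
        parity = PARITY_WEIGHTS[_weighted_choice(rng, [w for _, w in PARITY_WEIGHTS])][0]
        if parity == 2 and rng.random() < 0.3:
            parity = 3

        overweight, obesity = derive_bmi_flags(bmi, ext)
        all_flags = dict(flags)
        all_flags["overweight"] = overweight
        all_flags["obesity"] = obesity
        all_flags["advanced_age"] = derive_advanced_age(age, ext)

        gdm = int(rng.random() < config.outcome_model.probability(all_flags))
        comps = {
            cid: int(rng.random() < p)
            for cid, p in config.complication_prevalences.items()
        }
        rows.append(
            {
                "record_id": f"R{i:06d}",
                "cluster_id": cluster,
                "maternal_age": age,
                "bmi": bmi,
                "parity": parity,
                "ethnicity": ethnicity,
                **all_flags,
                "gdm": gdm,
                **comps,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    config: SimulationConfig,
    morbidity_lexicon: MorbidityLexicon | None = None,
    complication_lexicon: MorbidityLexicon | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, truth) tables for a synthetic pregnancy cohort.

    ``records`` has the raw input schema (structured columns plus rendered
    free-text fields); ``truth`` carries the generating flags, latent
    cluster ids and outcome labels. The same config (including seed)
    reproduces both tables exactly.
    """
    morbidity_lexicon = morbidity_lexicon or default_morbidity_lexicon()
    complication_lexicon = complication_lexicon or default_complication_lexicon()
    truth = generate_truth(config)

    cond_ids = list(config.condition_prevalences)
    comp_ids = ["gdm"] + [c for c in config.complication_prevalences if c != "gdm"]
    cond_texts, comp_texts = [], []
    for i in range(config.n_records):
        # Independent sub-stream so rendering never perturbs the truth draws.
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), i, 1]))
        row = truth.iloc[i]
        cond_flags = {cid: int(row[cid]) for cid in cond_ids}
        cond_texts.append(
            render_condition_text(cond_flags, morbidity_lexicon, config.noise, rng)
        )
        comp_flags = {cid: int(row[cid]) for cid in comp_ids if cid in row}
        comp_texts.append(
            render_condition_text(comp_flags, complication_lexicon, config.noise, rng)
        )

    records = truth[
        ["record_id", "maternal_age", "bmi", "parity", "ethnicity"]
    ].copy()
    records["medical_conditions_text"] = cond_texts
    records["complications_text"] = comp_texts
    return records, truth
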