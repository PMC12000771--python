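"""Multimorbidity burden distributions and stratified summary tables.

Burden classes follow the standard definitions: *none* (no condition),
*single* (exactly one), *multimorbidity* (two or more). Percentages are
printed to one decimal, rounded half away from zero, matching common
epidemiological reporting style; band edges for age and BMI strata default
to the cohort-report bands (age ≤24, 25–29, 30–34, 35–39, ≥40; BMI ≤19.9,
20–24.9, 25–26.9, 27–29.9, 30–34.9, 35+), implemented as half-open
intervals so 24.95 kg/m² falls in 20–24.9 without any rounding step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .extraction import BURDEN_MULTI, BURDEN_NONE, BURDEN_SINGLE

__all__ = [
    "BurdenDistribution",
    "round_half_away",
    "burden_distribution",
    "stratified_table",
    "DEFAULT_AGE_EDGES",
    "DEFAULT_BMI_EDGES",
]

# (label, lower_inclusive, upper_exclusive); None = unbounded.
DEFAULT_AGE_EDGES: tuple[tuple[str, float | None, float | None], ...] = (
    ("<=24", None, 25.0),
    ("25-29", 25.0, 30.0),
    ("30-34", 30.0, 35.0),
    ("35-39", 35.0, 40.0),
    (">=40", 40.0, None),
)
DEFAULT_BMI_EDGES: tuple[tuple[str, float | None, float | None], ...] = (
    ("<=19.9", None, 20.0),
    ("20-24.9", 20.0, 25.0),
    ("25-26.9", 25.0, 27.0),
    ("27-29.9", 27.0, 30.0),
    ("30-34.9", 30.0, 35.0),
    ("35+", 35.0, None),
)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (7.25 -> 7.3, -7.25 -> -7.3)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class BurdenDistribution:
    """Counts and cohort percentages per number of conditions, plus class totals."""

    by_count: dict[int, tuple[int, float]]
    n_total: int
    n_none: int
    n_single: int
    n_multimorbidity: int

    @property
    def percent_multimorbidity(self) -> float:
        return round_half_away(100.0 * self.n_multimorbidity / self.n_total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, n, pct) for k, (n, pct) in sorted(self.by_count.items())],
            columns=["n_conditions", "n", "percent"],
        )


def burden_distribution(profiles: pd.DataFrame) -> BurdenDistribution:
    """Distribution of morbidity counts over the cohort.

    ``profiles`` must carry a ``morbidity_count`` column; raises on an
    empty table (percentages would be undefined).
    """
    if profiles.empty:
        raise ValueError("cannot summarise an empty profile table")
    counts = profiles["morbidity_count"].astype(int)
    total = len(counts)
    by_count = {
        int(k): (int(v), round_half_away(100.0 * v / total))
        for k, v in counts.value_counts().sort_index().items()
    }
    return BurdenDistribution(
        by_count=by_count,
        n_total=total,
        n_none=int((counts == 0).sum()),
        n_single=int((counts == 1).sum()),
        n_multimorbidity=int((counts >= 2).sum()),
    )


def _band_of(
    value: float, bands: Sequence[tuple[str, float | None, float | None]]
) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    for label, lo, hi in bands:
        if (lo is None or value >= lo) and (hi is None or value < hi):
            return label
    return None


def _validate_bands(bands: Sequence[tuple[str, float | None, float | None]]) -> None:
    finite = sorted(
        ((-math.inf if lo is None else lo, math.inf if hi is None else hi, label)
         for label, lo, hi in bands)
    )
    for (lo1, hi1, l1), (lo2, hi2, l2) in zip(finite, finite[1:]):
        if lo2 < hi1:
            raise ValueError(f"strata bands {l1!r} and {l2!r} overlap")


def stratified_table(
    profiles: pd.DataFrame,
    records: pd.DataFrame,
    strata_var: str,
    strata_bounds: Sequence[tuple[str, float | None, float | None]] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate burden class by a stratifying variable.

    Numeric variables (age, BMI) are banded with half-open intervals;
    categorical variables (ethnicity, parity, a complication flag) stratify
    by their values. Returns one row per stratum with total n, per-class n
    and per-class column percentages (percent of that burden class falling
    in the stratum).
    """
    if strata_var not in records.columns:
        raise KeyError(f"stratifying variable {strata_var!r} not in records")
    merged = records[["record_id", strata_var]].merge(
        profiles[["record_id", "burden_class"]], on="record_id", validate="one_to_one"
    )
    if strata_bounds is None and strata_var == "maternal_age":
        strata_bounds = DEFAULT_AGE_EDGES
    if strata_bounds is None and strata_var == "bmi":
        strata_bounds = DEFAULT_BMI_EDGES
    if strata_bounds is not None:
        _validate_bands(strata_bounds)
        merged["stratum"] = [
            _band_of(v, strata_bounds) for v in merged[strata_var].astype(float)
        ]
        order = [label for label, _, _ in strata_bounds]
    else:
        merged["stratum"] = merged[strata_var].astype(str)
        order = sorted(merged["stratum"].unique())

    class_totals = merged["burden_class"].value_counts().to_dict()
    rows = []
    for label in order:
        sub = merged[merged["stratum"] == label]
        row: dict[str, object] = {"stratum": label, "n_total": len(sub)}
        for cls in (BURDEN_NONE, BURDEN_SINGLE, BURDEN_MULTI):
            n_cls = int((sub["burden_class"] == cls).sum())
            denom = class_totals.get(cls, 0)
            row[f"n_{cls}"] = n_cls
            row[f"pct_{cls}"] = (
                round_half_away(100.0 * n_cls / denom) if denom else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
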