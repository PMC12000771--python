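"""2×2 association screening: chi-square (with Yates correction), p, phi.

Every morbidity×complication pair is screened with the Pearson chi-square
on its 2×2 contingency table. The reported statistic applies the Yates
continuity correction — ``N(|ad − bc| − N/2)²_+ / (r1 r2 c1 c2)`` — which is
what reproduces the published statistics from their printed cells; the
uncorrected form and the phi coefficient (satisfying φ²·N = uncorrected χ²)
are carried alongside. Tables with a zero margin are flagged degenerate and
carry no statistic rather than being patched with pseudo-counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "DegenerateTableError",
    "contingency_2x2",
    "chi_square_uncorrected",
    "chi_square_corrected",
    "chi2_pvalue_1df",
    "phi_coefficient",
    "odds_ratio",
    "associate_all",
    "rank_associations",
    "top_complications_per_morbidity",
    "adjust_pvalues",
    "results_to_frame",
]


class DegenerateTableError(ValueError):
    """Chi-square is undefined when a row or column margin is zero."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out rows = exposure (no, yes), columns = outcome (no, yes):
    a = (no, no), b = (no, yes), c = (yes, no), d = (yes, yes)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @property
    def degenerate(self) -> bool:
        return any(m == 0 for m in self.margins)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


def contingency_2x2(
    exposure: Sequence[int] | np.ndarray, outcome: Sequence[int] | np.ndarray
) -> ContingencyTable2x2:
    """Exact cross-tabulation of two equal-length binary vectors."""
    e = np.asarray(exposure)
    o = np.asarray(outcome)
    if e.shape != o.shape or e.ndim != 1:
        raise ValueError("exposure and outcome must be 1-D vectors of equal length")
    if not (np.isin(e, (0, 1)).all() and np.isin(o, (0, 1)).all()):
        raise ValueError("vectors must be binary (0/1)")
    d = int(np.sum((e == 1) & (o == 1)))
    c = int(np.sum((e == 1) & (o == 0)))
    b = int(np.sum((e == 0) & (o == 1)))
    a = int(np.sum((e == 0) & (o == 0)))
    return ContingencyTable2x2(a, b, c, d)


def _check_margins(t: ContingencyTable2x2) -> tuple[int, int, int, int]:
    if t.degenerate:
        raise DegenerateTableError(f"zero margin in table {t}")
    return t.margins


def chi_square_uncorrected(t: ContingencyTable2x2) -> float:
    """Pearson chi-square: ``N(ad − bc)² / (r1 r2 c1 c2)``."""
    r1, r2, c1, c2 = _check_margins(t)
    det = t.a * t.d - t.b * t.c
    return t.n * det * det / (r1 * r2 * c1 * c2)


def chi_square_corrected(t: ContingencyTable2x2) -> float:
    """Continuity-corrected chi-square: ``N·max(|ad − bc| − N/2, 0)² / (r1 r2 c1 c2)``."""
    r1, r2, c1, c2 = _check_margins(t)
    adj = max(abs(t.a * t.d - t.b * t.c) - t.n / 2.0, 0.0)
    return t.n * adj * adj / (r1 * r2 * c1 * c2)


def chi2_pvalue_1df(stat: float) -> float:
    """Upper-tail p for chi-square with one degree of freedom."""
    if stat < 0:
        raise ValueError(f"statistic must be non-negative, got {stat}")
    return float(stats.chi2.sf(stat, df=1))


def phi_coefficient(t: ContingencyTable2x2) -> float:
    """Signed phi: ``(ad − bc) / sqrt(r1 r2 c1 c2)``, in [−1, 1]."""
    r1, r2, c1, c2 = _check_margins(t)
    return (t.a * t.d - t.b * t.c) / math.sqrt(r1 * r2 * c1 * c2)


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Cross-product odds ratio ad/(bc); inf when bc = 0."""
    if t.b * t.c == 0:
        return math.inf
    return (t.a * t.d) / (t.b * t.c)


@dataclass(frozen=True)
class AssociationResult:
    exposure: str
    outcome: str
    table: ContingencyTable2x2
    chi2_corrected: float | None
    chi2_uncorrected: float | None
    p_value: float | None
    phi: float | None
    degenerate: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.exposure, self.outcome)


def _associate_one(exposure: str, outcome: str, t: ContingencyTable2x2) -> AssociationResult:
    if t.degenerate:
        return AssociationResult(exposure, outcome, t, None, None, None, None, True)
    corrected = chi_square_corrected(t)
    return AssociationResult(
        exposure,
        outcome,
        t,
        corrected,
        chi_square_uncorrected(t),
        chi2_pvalue_1df(corrected),
        phi_coefficient(t),
        False,
    )


def associate_all(
    profiles: pd.DataFrame,
    outcome_flags: pd.DataFrame,
    exposures: Sequence[str],
    outcomes: Sequence[str],
) -> list[AssociationResult]:
    """One AssociationResult per (exposure, outcome) pair.

    ``profiles`` holds the exposure columns, ``outcome_flags`` the outcome
    columns (the two frames may be the same object); rows must align.
    Degenerate pairs are returned flagged, with no statistic.
    """
    missing = [c for c in exposures if c not in profiles.columns]
    missing += [c for c in outcomes if c not in outcome_flags.columns]
    if missing:
        raise KeyError(f"unknown columns: {sorted(set(missing))}")
    if len(profiles) != len(outcome_flags):
        raise ValueError("profiles and outcome_flags must have equal row counts")
    results = []
    for exp in exposures:
        e = profiles[exp].to_numpy()
        for out in outcomes:
            t = contingency_2x2(e, outcome_flags[out].to_numpy())
            results.append(_associate_one(exp, out, t))
    return results


def _rank_key(r: AssociationResult) -> tuple:
    return (r.p_value, -r.chi2_corrected, r.exposure, r.outcome)


def rank_associations(results: Sequence[AssociationResult], k: int) -> list[AssociationResult]:
    """First *k* non-degenerate results by ascending p, ties by descending
    corrected chi-square then pair name."""
    valid = [r for r in results if not r.degenerate]
    return sorted(valid, key=_rank_key)[:k]


def top_complications_per_morbidity(
    results: Sequence[AssociationResult], k: int = 3
) -> dict[str, list[AssociationResult]]:
    """Per exposure, its *k* smallest-p outcomes (degenerate pairs excluded)."""
    by_exposure: dict[str, list[AssociationResult]] = {}
    for r in results:
        if not r.degenerate:
            by_exposure.setdefault(r.exposure, []).append(r)
    return {
        exp: sorted(rs, key=_rank_key)[:k] for exp, rs in sorted(by_exposure.items())
    }


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Optional multiple-testing adjustment ('bonferroni' or 'bh')."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method: {method!r}")


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten results for delimited-text export."""
    return pd.DataFrame(
        {
            "exposure": [r.exposure for r in results],
            "outcome": [r.outcome for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "chi2_corrected": [r.chi2_corrected for r in results],
            "chi2_uncorrected": [r.chi2_uncorrected for r in results],
            "p_value": [r.p_value for r in results],
            "phi": [r.phi for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
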