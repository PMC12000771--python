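import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from pregmorb.association import (
    AssociationResult,
    ContingencyTable2x2,
    DegenerateTableError,
    adjust_pvalues,
    associate_all,
    chi2_pvalue_1df,
    chi_square_corrected,
    chi_square_uncorrected,
    contingency_2x2,
    phi_coefficient,
    rank_associations,
    results_to_frame,
    top_complications_per_morbidity,
)
from pregmorb.reference import load_reference_tables, reference_table

cells_st = st.tuples(*[st.integers(min_value=1, max_value=500)] * 4)


def _cellwise_chi2(t: ContingencyTable2x2) -> float:
    """Independent oracle: sum over cells of (O-E)^2/E."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows * cols / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


class TestContingency:
    def test_balanced_example(self):
        t = contingency_2x2([0, 0, 1, 1], [0, 1, 0, 1])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_matches_brute_force_paired_count(self):
        rng = np.random.default_rng(0)
        e = (rng.random(10_000) < 0.4).astype(int)
        o = (rng.random(10_000) < 0.2).astype(int)
        t = contingency_2x2(e, o)
        expected = {(i, j): sum(1 for x, y in zip(e, o) if (x, y) == (i, j))
                    for i in (0, 1) for j in (0, 1)}
        assert (t.a, t.b, t.c, t.d) == (
            expected[(0, 0)], expected[(0, 1)], expected[(1, 0)], expected[(1, 1)]
        )

    def test_reference_overweight_cells(self):
        t = reference_table("overweight")
        assert (t.a, t.b, t.c, t.d) == (27_542, 7_042, 10_617, 3_301)
        assert t.n == 48_502

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            contingency_2x2([0, 1], [0])
        with pytest.raises(ValueError):
            contingency_2x2([0, 2], [0, 1])
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestChiSquare:
    def test_independence_gives_zero(self):
        t = ContingencyTable2x2(10, 10, 10, 10)
        assert chi_square_uncorrected(t) == 0.0
        assert chi_square_corrected(t) == 0.0

    def test_perfect_association_equals_n(self):
        t = ContingencyTable2x2(10, 0, 0, 10)
        assert chi_square_uncorrected(t) == t.n == 20
        assert phi_coefficient(t) == 1.0

    def test_perfect_negative_association(self):
        t = ContingencyTable2x2(0, 10, 10, 0)
        assert phi_coefficient(t) == -1.0

    def test_zero_margin_raises(self):
        t = ContingencyTable2x2(5, 5, 0, 0)
        for fn in (chi_square_uncorrected, chi_square_corrected, phi_coefficient):
            with pytest.raises(DegenerateTableError):
                fn(t)

    @pytest.mark.parametrize(
        "condition,printed",
        [("overweight", 66.4), ("obesity", 822.8)],
    )
    def test_published_statistics_reproduced(self, condition, printed):
        """Continuity-corrected chi-square reproduces the printed cohort
        statistics from their printed 2×2 cells to one decimal."""
        t = reference_table(condition)
        assert round(chi_square_corrected(t), 1) == printed

    @settings(max_examples=200, derandomize=True)
    @given(cells_st)
    def test_uncorrected_matches_cellwise_oracle(self, cells):
        t = ContingencyTable2x2(*cells)
        assert chi_square_uncorrected(t) == pytest.approx(_cellwise_chi2(t), rel=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(cells_st)
    def test_correction_never_exceeds_uncorrected(self, cells):
        t = ContingencyTable2x2(*cells)
        assert chi_square_corrected(t) <= chi_square_uncorrected(t) + 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(cells_st)
    def test_phi_identity_and_transpose_invariance(self, cells):
        t = ContingencyTable2x2(*cells)
        phi = phi_coefficient(t)
        assert phi**2 * t.n == pytest.approx(chi_square_uncorrected(t), rel=1e-9, abs=1e-12)
        tt = t.transpose()
        assert chi_square_uncorrected(tt) == pytest.approx(chi_square_uncorrected(t), rel=1e-12)
        assert chi_square_corrected(tt) == pytest.approx(chi_square_corrected(t), rel=1e-12)
        assert abs(phi_coefficient(tt)) == pytest.approx(abs(phi), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(cells_st, st.integers(min_value=2, max_value=9))
    def test_uncorrected_scales_exactly_with_cell_multiplier(self, cells, m):
        t = ContingencyTable2x2(*cells)
        tm = ContingencyTable2x2(*(m * c for c in cells))
        assert chi_square_uncorrected(tm) == pytest.approx(
            m * chi_square_uncorrected(t), rel=1e-12
        )


class TestPValue:
    def test_zero_statistic_gives_one(self):
        assert chi2_pvalue_1df(0.0) == 1.0

    def test_critical_value(self):
        assert chi2_pvalue_1df(3.841) == pytest.approx(0.0500, abs=5e-4)

    def test_large_statistic_below_reporting_threshold(self):
        assert chi2_pvalue_1df(66.4) < 0.001

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi2_pvalue_1df(-0.1)

    def test_strictly_decreasing(self):
        stats = np.linspace(0, 30, 50)
        ps = [chi2_pvalue_1df(s) for s in stats]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_matches_numerical_integration_of_density(self):
        """Closed-form upper tail agrees with quadrature of the df=1 density."""
        def density(x):
            return math.exp(-x / 2) / math.sqrt(2 * math.pi * x)

        for stat in (0.5, 1.0, 3.841, 10.0, 25.0):
            num, _ = integrate.quad(density, stat, np.inf)
            assert chi2_pvalue_1df(stat) == pytest.approx(num, abs=1e-6)


def _toy_profiles(n=200, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "expo_a": (rng.random(n) < 0.3).astype(int),
            "expo_b": (rng.random(n) < 0.5).astype(int),
            "out_x": (rng.random(n) < 0.2).astype(int),
            "out_y": (rng.random(n) < 0.4).astype(int),
            "out_zero": np.zeros(n, dtype=int),
        }
    )
    return df


class TestAssociateAll:
    def test_pair_counts(self):
        df = _toy_profiles()
        assert len(associate_all(df, df, ["expo_a"], ["out_x"])) == 1
        results = associate_all(df, df, ["expo_a", "expo_b"], ["out_x", "out_y", "out_zero"])
        assert len(results) == 6

    def test_degenerate_pairs_flagged_without_statistics(self):
        df = _toy_profiles()
        results = associate_all(df, df, ["expo_a"], ["out_zero"])
        assert results[0].degenerate and results[0].p_value is None

    def test_unknown_columns_raise(self):
        df = _toy_profiles()
        with pytest.raises(KeyError):
            associate_all(df, df, ["nope"], ["out_x"])

    def test_results_frame_roundtrip(self):
        df = _toy_profiles()
        results = associate_all(df, df, ["expo_a", "expo_b"], ["out_x", "out_zero"])
        frame = results_to_frame(results)
        assert len(frame) == 4
        assert frame["degenerate"].sum() == 2


class TestRanking:
    def _results(self, spec):
        out = []
        for name, p, chi2 in spec:
            out.append(
                AssociationResult(
                    exposure=name, outcome="gdm",
                    table=ContingencyTable2x2(10, 10, 10, 10),
                    chi2_corrected=chi2, chi2_uncorrected=chi2,
                    p_value=p, phi=0.0, degenerate=False,
                )
            )
        return out

    def test_k_zero_empty(self):
        assert rank_associations(self._results([("a", 0.01, 5.0)]), 0) == []

    def test_smaller_p_first_with_tiebreaks(self):
        res = self._results([("a", 0.03, 1.0), ("b", 0.01, 5.0), ("c", 0.03, 2.0)])
        ranked = rank_associations(res, 3)
        assert [r.exposure for r in ranked] == ["b", "c", "a"]

    def test_order_agrees_with_brute_force_sort(self):
        rng = np.random.default_rng(5)
        res = self._results(
            [(f"e{i}", float(rng.random()), float(rng.random() * 10)) for i in range(40)]
        )
        ranked = rank_associations(res, 40)
        brute = sorted(res, key=lambda r: (r.p_value, -r.chi2_corrected, r.exposure))
        assert [r.exposure for r in ranked] == [r.exposure for r in brute]

    def test_top_complications_per_morbidity(self):
        rng = np.random.default_rng(1)
        res = []
        for exp in ("asthma", "pcos"):
            for out in ("gdm", "preterm", "cesarean", "pih"):
                res.append(
                    AssociationResult(
                        exposure=exp, outcome=out,
                        table=ContingencyTable2x2(10, 10, 10, 10),
                        chi2_corrected=1.0, chi2_uncorrected=1.0,
                        p_value=float(rng.random()), phi=0.0, degenerate=False,
                    )
                )
        top = top_complications_per_morbidity(res, k=3)
        assert set(top) == {"asthma", "pcos"}
        for exp, items in top.items():
            assert len(items) == 3
            ps = [r.p_value for r in items]
            assert ps == sorted(ps)

    def test_top_k_larger_than_available_returns_all(self):
        res = self._results([("a", 0.01, 1.0)])
        top = top_complications_per_morbidity(res, k=3)
        assert len(top["a"]) == 1


class TestAdjustment:
    def test_bonferroni_and_bh_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.001, 0.01, 0.02, 0.03, 0.5, 0.9]
        np.testing.assert_allclose(
            adjust_pvalues(p, "bonferroni"),
            multipletests(p, method="bonferroni")[1],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            adjust_pvalues(p, "bh"), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )


class TestReferenceTables:
    def test_all_tables_share_the_cohort_total(self):
        df = load_reference_tables()
        totals = df[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == 48_502).all()

    def test_gdm_margin_consistent_across_tables(self):
        df = load_reference_tables()
        assert ((df["b"] + df["d"]) == 10_343).all()
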