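"""Association statistics: printed-table checks, oracles and invariants."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from haph.association import (
    ConfigError,
    ContingencyTable2x2,
    GenotypeCounts3,
    armitage_trend,
    chi2_2x2,
    classify_status,
    odds_ratio,
    pool_tables,
    predictive_values,
    rank_sum,
    relative_risk,
)

HERD1 = ContingencyTable2x2(15, 5, 4, 17)
HERD2 = ContingencyTable2x2(11, 4, 4, 12)

tables = st.builds(
    ContingencyTable2x2,
    a=st.integers(1, 40),
    b=st.integers(1, 40),
    c=st.integers(1, 40),
    d=st.integers(1, 40),
)


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "pap,expected",
        [(94.0, "affected"), (50.5, "affected"), (30.0, "unaffected"),
         (45.0, "indeterminate"), (50.0, "indeterminate"), (39.0, "indeterminate")],
    )
    def test_herd1_thresholds_strict(self, pap, expected):
        assert classify_status(pap) == expected

    def test_herd2_inclusive_thresholds(self):
        # younger replication herd: affected at PAP >= 45, unaffected <= 39
        kw = dict(affected_min=45, unaffected_max=39,
                  affected_inclusive=True, unaffected_inclusive=True)
        assert classify_status(45.0, **kw) == "affected"
        assert classify_status(39.0, **kw) == "unaffected"
        assert classify_status(42.0, **kw) == "indeterminate"

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            classify_status(40.0, affected_min=39, unaffected_max=50)


class TestChi2:
    def test_herd1_printed_value(self):
        res = chi2_2x2(HERD1)
        assert res.statistic == pytest.approx(12.897, abs=0.001)
        assert res.pvalue == pytest.approx(3.3e-4, rel=0.01)

    def test_proportional_rows_null(self):
        res = chi2_2x2(ContingencyTable2x2(10, 10, 5, 5))
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_zero_margin_undefined(self):
        res = chi2_2x2(ContingencyTable2x2(0, 0, 4, 17))
        assert not res.defined and "zero margin" in res.note

    @settings(derandomize=True, max_examples=100)
    @given(tables)
    def test_row_column_swap_symmetry(self, t):
        base = chi2_2x2(t).pvalue
        swapped_rows = ContingencyTable2x2(t.c, t.d, t.a, t.b)
        swapped_cols = ContingencyTable2x2(t.b, t.a, t.d, t.c)
        assert chi2_2x2(swapped_rows).pvalue == pytest.approx(base)
        assert chi2_2x2(swapped_cols).pvalue == pytest.approx(base)

    @settings(derandomize=True, max_examples=100)
    @given(tables)
    def test_matches_scipy_and_z_squared(self, t):
        """Cross-check vs scipy and the squared two-proportion z statistic."""
        ours = chi2_2x2(t)
        ref, p, _, _ = stats.chi2_contingency(t.as_array(), correction=False)
        assert ours.statistic == pytest.approx(ref)
        assert ours.pvalue == pytest.approx(p)
        p1, n1 = t.a / (t.a + t.b), t.a + t.b
        p2, n2 = t.c / (t.c + t.d), t.c + t.d
        pbar = (t.a + t.c) / t.n
        if 0 < pbar < 1:
            z = (p1 - p2) / math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
            assert ours.statistic == pytest.approx(z * z)

    def test_yates_reduces_statistic(self):
        assert chi2_2x2(HERD1, yates=True).statistic < chi2_2x2(HERD1).statistic


class TestArmitage:
    def test_identical_distributions_null(self):
        res = armitage_trend(GenotypeCounts3((5, 3, 2), (5, 3, 2)))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_single_genotype(self):
        res = armitage_trend(GenotypeCounts3((10, 0, 0), (12, 0, 0)))
        assert not res.defined

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_textbook_matrix_formula(self, seed):
        """Independent oracle: direct evaluation of the trend z-score."""
        rng = np.random.default_rng(seed)
        r = tuple(int(x) for x in rng.integers(0, 15, 3))
        s = tuple(int(x) for x in rng.integers(0, 15, 3))
        if sum(r) == 0 or sum(s) == 0 or sum(1 for ri, si in zip(r, s) if ri + si) < 2:
            pytest.skip("degenerate draw")
        w = np.array([0.0, 1.0, 2.0])
        rr, ss = np.array(r, float), np.array(s, float)
        n_i, N, R = rr + ss, rr.sum() + ss.sum(), rr.sum()
        p_bar = R / N
        t_num = float(w @ (rr - p_bar * n_i))
        t_var = p_bar * (1 - p_bar) * (
            float((w**2) @ n_i) - float(w @ n_i) ** 2 / N
        )
        expect = t_num**2 / t_var
        got = armitage_trend(GenotypeCounts3(r, s))
        assert got.statistic == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_carrier_weights_reduce_to_chi2(self, seed):
        """Weights (0,1,1) collapse het+hom-alt: equals uncorrected chi2."""
        rng = np.random.default_rng(100 + seed)
        r = tuple(int(x) for x in rng.integers(1, 15, 3))
        s = tuple(int(x) for x in rng.integers(1, 15, 3))
        trend = armitage_trend(GenotypeCounts3(r, s), weights=(0, 1, 1))
        t2 = ContingencyTable2x2(r[1] + r[2], r[0], s[1] + s[2], s[0])
        assert trend.statistic == pytest.approx(chi2_2x2(t2).statistic, rel=1e-9)


class TestRankSum:
    def test_identical_lists_p_one(self):
        assert rank_sum([3.0, 4.0, 5.0], [3.0, 4.0, 5.0], mode="exact").pvalue == 1.0

    def test_complete_separation_3v3(self):
        res = rank_sum([1, 2, 3], [10, 11, 12], mode="exact")
        assert res.pvalue == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_matches_enumeration_oracle(self, seed):
        """Full C(n, n_a) enumeration over mid-ranks, n_a+n_b <= 12."""
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(2, 6)), int(rng.integers(2, 7))
        pool = rng.integers(0, 6, n_a + n_b).astype(float)  # ties likely
        a, b = pool[:n_a], pool[n_a:]
        ranks = stats.rankdata(pool)
        w_obs = ranks[:n_a].sum()
        mu = n_a * (len(pool) + 1) / 2
        n_extreme = sum(
            1
            for idx in combinations(range(len(pool)), n_a)
            if abs(ranks[list(idx)].sum() - mu) >= abs(w_obs - mu) - 1e-9
        )
        expect = n_extreme / math.comb(len(pool), n_a)
        got = rank_sum(a, b, mode="exact")
        assert got.pvalue == pytest.approx(expect, rel=1e-9)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(size=7)
        ours = rank_sum(a, b, mode="exact")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_normal_approx_close_to_exact_n15(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        exact = rank_sum(a, b, mode="exact").pvalue
        approx = rank_sum(a, b, mode="normal_approx").pvalue
        assert approx == pytest.approx(exact, rel=0.10)


class TestRiskEstimates:
    def test_printed_relative_risk_with_ci(self):
        rr = relative_risk(HERD1)
        assert rr.point == pytest.approx(3.47, abs=0.005)
        assert rr.lower == pytest.approx(1.55, abs=0.005)
        assert rr.upper == pytest.approx(7.77, abs=0.005)

    def test_printed_odds_ratio(self):
        assert odds_ratio(HERD1).point == pytest.approx(12.75)

    def test_equal_risks_give_unity(self):
        t = ContingencyTable2x2(10, 10, 10, 10)
        assert relative_risk(t).point == pytest.approx(1.0)
        assert odds_ratio(t).point == pytest.approx(1.0)

    def test_symmetric_log_ci_at_unity(self):
        est = odds_ratio(ContingencyTable2x2(1, 1, 1, 1))
        assert est.point == 1.0
        assert math.log(est.upper) == pytest.approx(-math.log(est.lower))

    @settings(derandomize=True, max_examples=60)
    @given(tables)
    def test_or_reciprocity_under_row_swap(self, t):
        swapped = ContingencyTable2x2(t.c, t.d, t.a, t.b)
        assert odds_ratio(t).point * odds_ratio(swapped).point == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(tables)
    def test_wald_cis_match_statsmodels(self, t):
        """statsmodels Table2x2 as the independent Wald-CI oracle."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        # statsmodels rows are exposure: [[a, c], [b, d]] puts carriers first
        ref = sm.Table2x2(np.array([[t.a, t.c], [t.b, t.d]]))
        rr, orr = relative_risk(t), odds_ratio(t)
        assert rr.point == pytest.approx(ref.riskratio)
        assert rr.lower == pytest.approx(ref.riskratio_confint()[0], rel=1e-6)
        assert rr.upper == pytest.approx(ref.riskratio_confint()[1], rel=1e-6)
        assert orr.point == pytest.approx(ref.oddsratio)
        assert orr.lower == pytest.approx(ref.oddsratio_confint()[0], rel=1e-6)
        assert orr.upper == pytest.approx(ref.oddsratio_confint()[1], rel=1e-6)

    def test_zero_cell_handling(self):
        t = ContingencyTable2x2(0, 5, 4, 17)
        assert relative_risk(t).point == 0.0
        assert math.isnan(relative_risk(t).lower)
        corrected = relative_risk(t, continuity=True)
        assert corrected.point > 0 and corrected.lower <= corrected.point
        orr = odds_ratio(ContingencyTable2x2(5, 0, 4, 17))
        assert math.isinf(orr.point)
        hald = odds_ratio(ContingencyTable2x2(5, 0, 4, 17), haldane=True)
        assert math.isfinite(hald.point) and "Haldane" in hald.note


class TestPredictiveValues:
    def test_printed_values_at_half_prevalence(self):
        ppv, npv = predictive_values(15 / 20, 17 / 21, 0.5)
        assert 100 * ppv == pytest.approx(79.7, abs=0.05)
        assert 100 * npv == pytest.approx(76.4, abs=0.05)

    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_monotone_in_prevalence(self):
        prevs = np.linspace(0.01, 0.99, 25)
        ppvs, npvs = zip(*(predictive_values(0.75, 17 / 21, p) for p in prevs))
        assert all(x <= y + 1e-12 for x, y in zip(ppvs, ppvs[1:]))
        assert all(x >= y - 1e-12 for x, y in zip(npvs, npvs[1:]))

    def test_arguments_validated(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.5)


class TestPooling:
    def test_joint_analysis_printed_p(self):
        pooled = pool_tables([HERD1, HERD2])
        assert (pooled.a, pooled.b, pooled.c, pooled.d) == (26, 9, 8, 29)
        assert chi2_2x2(pooled).pvalue == pytest.approx(7.7e-6, rel=0.01)

    def test_single_table_identity_and_commutativity(self):
        assert pool_tables([HERD1]) == HERD1
        assert pool_tables([HERD1, HERD2]) == pool_tables([HERD2, HERD1])
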