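import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from del22q.stats import (
    fisher_exact,
    percent,
    ppv_scenarios,
    size_concordance,
    summarize_cohort,
    wilcoxon_rank_sum,
    wilson_ci,
)
from oracles import fisher_exact_oracle, wilcoxon_exact_oracle


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(1, 16, 6.3), (177, 307, 57.7), (176, 177, 99.4), (1, 3, 33.3), (1, 8, 12.5)],
    )
    def test_half_up_rounding(self, num, den, expected):
        assert percent(num, den) == expected

    def test_empty_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestWilsonCI:
    @pytest.mark.parametrize(
        "s,n,lo,hi",
        [(176, 177, 0.969, 0.999), (5, 10, 0.237, 0.763), (0, 10, 0.0, 0.278)],
    )
    def test_frozen_values(self, s, n, lo, hi):
        got = wilson_ci(s, n)
        assert got[0] == pytest.approx(lo, abs=5e-4)
        assert got[1] == pytest.approx(hi, abs=5e-4)

    @pytest.mark.parametrize("s,n", [(0, 5), (3, 7), (50, 60), (176, 177), (10, 10)])
    @pytest.mark.parametrize("method,sm_method", [("wilson", "wilson"), ("clopper_pearson", "beta")])
    def test_against_statsmodels(self, s, n, method, sm_method):
        lo, hi = wilson_ci(s, n, method=method)
        sm_lo, sm_hi = proportion_confint(s, n, alpha=0.05, method=sm_method)
        assert lo == pytest.approx(sm_lo, abs=1e-9)
        assert hi == pytest.approx(sm_hi, abs=1e-9)

    def test_interval_brackets_point_and_narrows_with_n(self):
        lo1, hi1 = wilson_ci(50, 100)
        lo2, hi2 = wilson_ci(500, 1000)
        assert lo1 < 0.5 < hi1
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_continuity_corrected_is_wider(self):
        plain = wilson_ci(50, 100, method="wilson")
        cc = wilson_ci(50, 100, method="wilson_cc")
        assert cc[0] < plain[0] and cc[1] > plain[1]

    @pytest.mark.parametrize("s,n", [(5, 0), (-1, 10), (11, 10)])
    def test_invalid_inputs(self, s, n):
        with pytest.raises(ValueError):
            wilson_ci(s, n)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).pvalue == 1.0

    def test_fully_separated_small_samples(self):
        # 2 of C(6,3)=20 labelings are as extreme: p = 0.10
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.pvalue == pytest.approx(0.10)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(0.5, size=10)
            exact = wilcoxon_rank_sum(x, y).pvalue  # N=20 -> exact path
            approx = wilcoxon_rank_sum(x, y, exact_limit=0).pvalue
            assert approx == pytest.approx(exact, abs=0.01)

    def test_matches_scipy_on_tie_free_data(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = wilcoxon_rank_sum(x, y).pvalue
            scipys = mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(scipys, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFisher:
    def test_symmetric_table(self):
        res = fisher_exact(1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_perfect_association(self):
        res = fisher_exact(5, 0, 0, 5)
        assert res.pvalue == pytest.approx(2 / 252)

    def test_sample_odds_ratio(self):
        assert fisher_exact(20, 10, 5, 15).odds_ratio == pytest.approx(6.0)

    def test_zero_cell_haldane_or_finite(self):
        res = fisher_exact(5, 0, 2, 5)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1

    @pytest.mark.parametrize("table", [(0, 0, 1, 1), (1, 0, 1, 0), (1.5, 1, 1, 1), (-1, 1, 1, 1)])
    def test_degenerate_or_invalid_rejected(self, table):
        with pytest.raises(ValueError):
            fisher_exact(*table)

    def test_against_enumeration_oracle_spot(self):
        for table in [(3, 1, 1, 4), (2, 2, 2, 2), (6, 0, 1, 5), (1, 4, 3, 2)]:
            assert fisher_exact(*table).pvalue == pytest.approx(
                fisher_exact_oracle(*table), abs=1e-9
            )


class TestSizeConcordance:
    def test_identity_line(self):
        pairs = [(0.5, 0.5), (1.0, 1.0), (2.55, 2.55), (1.4, 1.4)]
        res = size_concordance(pairs)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            size_concordance([(1, 1), (2, 2)])

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            size_concordance([(1, 1), (1, 2), (1, 3)])


def toy_cohort(groups):
    """Build a cohort table from (origin, testing, completeness, confirmed, count)."""
    rows = []
    for origin, testing, completeness, confirmed, count in groups:
        for _ in range(count):
            rows.append(
                {
                    "suspected_origin": origin,
                    "testing": testing,
                    "completeness": completeness,
                    "confirmed": confirmed,
                    "fetal_inherited": "unknown",
                    "ultrasound": False,
                    "cardiac": False,
                    "deferred_postnatal": False,
                }
            )
    return pd.DataFrame(rows)


class TestPPVScenarios:
    def test_all_true_positive_toy_cohort(self):
        cohort = toy_cohort([("fetal", "fetal_only", "complete", "true_positive", 10)])
        ppv = ppv_scenarios(cohort)
        for name in ("complete", "fetal_only", "conservative", "upper_bound", "lower_bound"):
            assert getattr(ppv, name).point == pytest.approx(1.0)

    def test_empty_scenario_flagged(self):
        cohort = toy_cohort([("maternal", "maternal_only", "complete", "true_positive", 5)])
        ppv = ppv_scenarios(cohort)
        assert ppv.fetal_only is None
        assert any("fetal_only" in note for note in ppv.notes)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.integers(0, 40),
        st.integers(0, 5),
        st.integers(0, 20),
        st.integers(0, 30),
    )
    def test_scenario_ordering_invariant(self, tp, fp, inc, none):
        if tp + fp == 0:
            return
        cohort = toy_cohort(
            [
                ("fetal", "fetal_only", "complete", "true_positive", tp),
                ("fetal", "fetal_only", "complete", "false_positive", fp),
                ("fetal", "maternal_only", "incomplete", "unknown", inc),
                ("fetal", "none", "none", "unknown", none),
            ]
        )
        ppv = ppv_scenarios(cohort)
        assert (
            ppv.lower_bound.point
            <= ppv.conservative.point + 1e-12
            <= ppv.complete.point + 1e-12
            <= ppv.upper_bound.point + 1e-12
        )


class TestSummarize:
    def test_empty_category_noted(self):
        cohort = toy_cohort([("fetal", "none", "none", "unknown", 4)])
        out = summarize_cohort(cohort)
        assert "pct_deferred_postnatal" not in out
        assert any("pct_deferred_postnatal" in n for n in out["notes"])
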