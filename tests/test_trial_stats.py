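import math

import numpy as np
import pytest
from scipy import stats

from pedinfuse.trial_stats import (
    SummaryStats,
    clopper_pearson,
    format_p,
    mcnemar_exact,
    one_sample_t_ci,
    paired_t,
    render_report,
    trial_report,
    welch_t,
)

from conftest import TABLE2


class TestOneSampleTCI:
    @pytest.mark.parametrize("key", sorted(TABLE2))
    def test_reproduces_published_mean_ci_cells(self, key):
        mean, sd, lo, hi = TABLE2[key]
        ci = one_sample_t_ci(SummaryStats(10, mean, sd))
        # printed bounds come from unrounded raw data; rounded summaries
        # regenerate them to within one unit in the last printed digit
        assert ci.lower == pytest.approx(lo, abs=0.1)
        assert ci.upper == pytest.approx(hi, abs=0.1)

    def test_zero_sd_collapses_to_point(self):
        ci = one_sample_t_ci(SummaryStats(5, 3.0, 0.0))
        assert (ci.lower, ci.upper) == (3.0, 3.0)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            one_sample_t_ci(SummaryStats(1, 3.0, 0.0))


WELCH_CASES = [
    # (conventional, app, printed diff and CI)
    ((308.1, 128.3), (128.1, 36.5), 180.0, 86.5, 273.5),  # TDP period 1
    ((198.4, 60.2), (143.7, 21.9), 54.7, 10.3, 99.1),  # TDP period 2
    ((390.8, 129.3), (213.5, 59.9), 177.3, 79.7, 274.9),  # TDD period 1
    ((276.7, 70.6), (221.8, 33.0), 54.9, 1.6, 108.2),  # TDD period 2
]


class TestWelchT:
    @pytest.mark.parametrize("conv,app,diff,lo,hi", WELCH_CASES)
    def test_reproduces_published_between_arm_cis(self, conv, app, diff, lo, hi):
        ci, test = welch_t(SummaryStats(10, *conv), SummaryStats(10, *app))
        assert ci.estimate == pytest.approx(diff, abs=1e-9)
        assert ci.lower == pytest.approx(lo, abs=0.1)
        assert ci.upper == pytest.approx(hi, abs=0.1)
        assert test.p < 0.05

    @pytest.mark.parametrize("conv,app,diff,lo,hi", WELCH_CASES)
    def test_matches_scipy_statistic_and_p(self, conv, app, diff, lo, hi):
        s1, s2 = SummaryStats(10, *conv), SummaryStats(10, *app)
        _, test = welch_t(s1, s2)
        ref = stats.ttest_ind_from_stats(
            s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=False
        )
        assert test.statistic == pytest.approx(ref.statistic)
        assert test.p == pytest.approx(ref.pvalue)

    def test_identical_groups_give_p_one(self):
        s = SummaryStats(10, 5.0, 2.0)
        ci, test = welch_t(s, s)
        assert ci.estimate == 0.0
        assert test.p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        ci, test = welch_t(SummaryStats(5, 3.0, 0.0), SummaryStats(5, 3.0, 0.0))
        assert test.degenerate and test.p == 1.0
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_pooled_variant_uses_classical_df(self):
        ci, test = welch_t(
            SummaryStats(10, 308.1, 128.3), SummaryStats(10, 128.1, 36.5), pooled=True
        )
        assert test.df == 18
        assert ci.estimate == pytest.approx(180.0)

    def test_ci_width_shrinks_with_n(self):
        widths = [
            (lambda ci: ci.upper - ci.lower)(
                welch_t(SummaryStats(n, 10.0, 4.0), SummaryStats(n, 8.0, 3.0))[0]
            )
            for n in (5, 10, 20, 40)
        ]
        assert widths == sorted(widths, reverse=True)


def cp_oracle(k: int, n: int, level: float = 0.95, tol: float = 1e-9):
    """Invert the binomial tail directly: the lower bound is the smallest p
    with P[X >= k | p] >= alpha/2, the upper the largest with
    P[X <= k | p] >= alpha/2.  Bisection on the monotone tail functions."""
    alpha = 1 - level

    def upper_tail(p):  # P[X >= k]
        return float(stats.binom.pmf(np.arange(k, n + 1), n, p).sum())

    def lower_tail(p):  # P[X <= k]
        return float(stats.binom.pmf(np.arange(0, k + 1), n, p).sum())

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if (f(mid) >= target) == increasing:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(upper_tail, alpha / 2, increasing=True)
    upper = 1.0 if k == n else bisect(lower_tail, alpha / 2, increasing=False)
    return lower, upper


class TestClopperPearson:
    def test_published_pooled_error_ci(self):
        ci = clopper_pearson(14, 20)
        assert round(100 * ci.lower, 1) == 45.7
        assert round(100 * ci.upper, 1) == 88.1

    def test_zero_numerator(self):
        ci = clopper_pearson(0, 10)
        assert ci.lower == 0.0
        assert round(100 * ci.upper) == 31

    def test_six_of_ten_rounds_to_printed_integers(self):
        ci = clopper_pearson(6, 10)
        assert round(100 * ci.lower) == 26
        assert round(100 * ci.upper) == 88

    def test_full_numerator_upper_is_one(self):
        assert clopper_pearson(7, 7).upper == 1.0

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    def test_agrees_with_tail_inversion_oracle_small_n(self):
        for n in range(1, 31):
            for k in range(n + 1):
                ci = clopper_pearson(k, n)
                lo, hi = cp_oracle(k, n)
                assert ci.lower == pytest.approx(lo, abs=1e-6), (k, n)
                assert ci.upper == pytest.approx(hi, abs=1e-6), (k, n)

    def test_simulated_coverage_at_least_nominal(self):
        rng = np.random.default_rng(20170201)
        n = 10
        bounds = [clopper_pearson(k, n) for k in range(n + 1)]
        lo = np.array([b.lower for b in bounds])
        hi = np.array([b.upper for b in bounds])
        for p in (0.1, 0.5, 0.7):
            ks = rng.binomial(n, p, size=10_000)
            covered = (lo[ks] <= p) & (p <= hi[ks])
            assert covered.mean() >= 0.95


class TestMcNemarExact:
    def test_fourteen_discordant_pairs_one_sided_dominance(self):
        # all 14 discordant pairs favour one method: p = 2 x 0.5^14
        res = mcnemar_exact(14, 0)
        assert res.p == pytest.approx(2 * 0.5**14)
        assert res.p < 0.001

    def test_balanced_pairs_capped_at_one(self):
        assert mcnemar_exact(6, 6).p == 1.0
        assert mcnemar_exact(1, 0).p == 1.0  # 2 x 0.5, capped

    @pytest.mark.parametrize("b,c", [(3, 7), (0, 5), (10, 2)])
    def test_symmetry(self, b, c):
        assert mcnemar_exact(b, c).p == mcnemar_exact(c, b).p

    def test_agrees_with_statsmodels_exact(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(14, 0), (8, 3), (1, 1), (5, 9)]:
            table = [[0, b], [c, 0]]
            ref = sm.mcnemar(table, exact=True)
            assert mcnemar_exact(b, c).p == pytest.approx(ref.pvalue)

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ValueError, match="discordant"):
            mcnemar_exact(0, 0)


class TestPairedT:
    def test_all_zero_differences_flagged_degenerate(self):
        ci, test = paired_t([0.0] * 5)
        assert ci.estimate == 0.0
        assert test.degenerate
        assert math.isnan(test.p)

    def test_ci_centred_on_mean(self):
        ci, _ = paired_t([1.0, 2.0, 3.0, 4.0])
        assert ci.estimate == pytest.approx(2.5)
        assert ci.upper - ci.estimate == pytest.approx(ci.estimate - ci.lower)

    def test_power_against_strong_shift(self):
        # N(5, 1) differences with n=100: essentially always significant
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            _, test = paired_t(rng.normal(5.0, 1.0, size=100))
            rejections += test.p < 0.05
        assert rejections / n_sim > 0.99


class TestTrialReport:
    def test_time_cells_match_published_table(self, table2_records):
        report = trial_report(table2_records)
        for (outcome, period, method), (mean, sd, lo, hi) in TABLE2.items():
            cell = report.times[(f"{outcome}_s", period, method)]
            assert cell.stats.mean == pytest.approx(mean, abs=1e-9)
            assert cell.stats.sd == pytest.approx(sd, abs=1e-9)
            assert cell.ci.lower == pytest.approx(lo, abs=0.1)
            assert cell.ci.upper == pytest.approx(hi, abs=0.1)

    def test_between_arm_differences_and_percent_reduction(self, table2_records):
        report = trial_report(table2_records)
        comp = report.comparisons[("tdp_s", 1)]
        assert comp.diff_ci.estimate == pytest.approx(180.0, abs=1e-9)
        assert comp.pct_reduction == 58
        assert report.comparisons[("tdd_s", 1)].pct_reduction == 45
        assert report.comparisons[("tdp_s", 2)].diff_ci.estimate == pytest.approx(54.7)
        assert report.comparisons[("tdd_s", 2)].diff_ci.estimate == pytest.approx(54.9)

    def test_error_rates_and_paired_comparison(self, table2_records):
        report = trial_report(table2_records)
        assert (report.error_rates[("conventional", 1)].k, report.error_rates[("conventional", 1)].n) == (8, 10)
        assert (report.error_rates[("conventional", 2)].k, report.error_rates[("conventional", 2)].n) == (6, 10)
        assert report.error_rates[("app", 1)].k == 0
        pooled = report.pooled_error_rates["conventional"]
        assert (pooled.k, pooled.n) == (14, 20)
        assert round(100 * pooled.ci.lower, 1) == 45.7
        assert round(100 * pooled.ci.upper, 1) == 88.1
        assert (report.paired_errors.k, report.paired_errors.n) == (14, 20)
        assert report.mcnemar.p < 0.001

    def test_empty_input_reports_missing_strata(self):
        report = trial_report([])
        assert report.times == {}
        assert report.missing  # all strata flagged absent
        assert report.mcnemar is None

    def test_render_produces_journal_style_lines(self, table2_records):
        text = render_report(trial_report(table2_records))
        assert "180.0 s" in text
        assert "58% of conventional time" in text
        assert "P<.001" in text


class TestFormatP:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0001, "<.001"), (0.002, "=.002"), (0.0446, "=.04"), (0.71, "=.71"), (1.0, "=1.00")],
    )
    def test_journal_style(self, p, expected):
        assert format_p(p) == expected
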