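"""Diagnostic-accuracy statistics against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from nodulestrat import (
    ThresholdCounts,
    crude_risk,
    diagnostic_summary,
    false_positive_reduction,
    mcnemar,
    pearson_chi2,
    perifissural_risk,
    univariable_logistic_or,
)
from nodulestrat.accuracy import clopper_pearson_coverage, proportion_ci
from nodulestrat.cohort import NoduleRecord, ParticipantRecord
from nodulestrat.errors import ConvergenceError


class TestDiagnosticSummary:
    def test_rule_out_80_reproduces_published_performance(self):
        d = diagnostic_summary(ThresholdCounts(tp=198, fn=30, fp=1975, tn=3726))
        assert round(d.sensitivity[0], 1) == 86.8
        assert round(d.specificity[0], 1) == 65.4
        assert round(d.npv[0], 1) == 99.2

    def test_rule_in_300_ppv(self):
        d = diagnostic_summary(ThresholdCounts(tp=152, fp=359, fn=76, tn=5342))
        assert round(d.ppv[0], 1) == 29.7

    def test_undefined_metric_is_absent_not_zero(self):
        d = diagnostic_summary(ThresholdCounts(tp=0, fn=0, fp=3, tn=7))
        assert d.sensitivity is None
        assert d.specificity is not None

    def test_exchange_symmetry_swaps_metrics(self):
        a = diagnostic_summary(ThresholdCounts(tp=30, fp=12, fn=5, tn=70))
        b = diagnostic_summary(ThresholdCounts(tp=70, fp=5, fn=12, tn=30))
        assert a.sensitivity == b.specificity
        assert a.ppv == b.npv

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ThresholdCounts(tp=-1, fp=0, fn=0, tn=0)

    def test_wilson_interval_available(self):
        d = diagnostic_summary(
            ThresholdCounts(tp=198, fn=30, fp=1975, tn=3726), method="wilson"
        )
        cp = diagnostic_summary(ThresholdCounts(tp=198, fn=30, fp=1975, tn=3726))
        assert d.sensitivity[1] != cp.sensitivity[1]  # different interval family
        assert abs(d.sensitivity[1] - cp.sensitivity[1]) < 1.0


class TestCrudeRisk:
    def test_published_risks_reproduce(self):
        assert round(crude_risk(228, 5929).risk_pct, 2) == 3.85
        r = crude_risk(37, 4809)
        assert round(r.risk_pct, 2) == 0.77
        assert (round(r.ci[0], 2), round(r.ci[1], 2)) == (0.54, 1.06)

    def test_zero_events_lower_bound_zero(self):
        r = crude_risk(0, 100)
        assert r.risk_pct == 0.0 and r.ci[0] == 0.0

    def test_events_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            crude_risk(5, 4)


class TestPearsonChi2:
    def test_identical_proportions_give_zero_statistic(self):
        stat, p = pearson_chi2([[10, 90], [30, 270]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[15, 1406], [37, 4772]],
            [[30, 3726], [37, 4772]],
            [[5, 5], [50, 40]],
            [[1, 99], [10, 890]],
        ],
    )
    def test_closed_form_cross_product_identity(self, table):
        (a, b), (c, d) = table
        n = a + b + c + d
        expected = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        expected_p = stats.chi2.sf(expected, df=1)
        stat, p = pearson_chi2(table)
        assert stat == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(expected_p, abs=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 10]])


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        assert mcnemar(7, 7) == pytest.approx(1.0)

    def test_one_sided_discordance_closed_form(self):
        assert mcnemar(0, 15) == pytest.approx(2 * 0.5**15, rel=1e-12)

    @pytest.mark.parametrize("b,c", [(0, 1), (2, 9), (5, 5), (3, 17), (10, 10)])
    def test_exact_variant_agrees_with_binomial_enumeration(self, b, c):
        n = b + c
        k = min(b, c)
        # brute-force: two-sided tail of Binomial(n, 1/2)
        enumerated = min(
            1.0, 2 * sum(math.comb(n, j) * 0.5**n for j in range(k + 1))
        )
        assert mcnemar(b, c, "exact") == pytest.approx(enumerated, rel=1e-12)

    def test_chi2_variants_match_closed_forms(self):
        b, c = 14, 30
        assert mcnemar(b, c, "chi2") == pytest.approx(
            stats.chi2.sf((b - c) ** 2 / (b + c), 1), rel=1e-12
        )
        assert mcnemar(b, c, "chi2-corrected") == pytest.approx(
            stats.chi2.sf((abs(b - c) - 1) ** 2 / (b + c), 1), rel=1e-12
        )

    def test_no_discordant_pairs_undefined(self):
        with pytest.raises(ValueError):
            mcnemar(0, 0)


class TestLogisticOddsRatio:
    def test_binary_predictor_equals_cross_product_ratio(self):
        # 2x2: exposed a/b cases/controls, unexposed c/d
        a, b, c, d = 30, 70, 10, 90
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        res = univariable_logistic_or(x, y)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_association_or_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        y = rng.random(4000) < 0.2
        res = univariable_logistic_or(x, y)
        assert res.ci[0] < 1.0 < res.ci[1]

    def test_known_slope_recovered_within_3se(self):
        rng = np.random.default_rng(5)
        n, beta0, beta1 = 10000, -3.0, 0.8
        x = rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        res = univariable_logistic_or(x, y)
        assert abs(res.slope - beta1) <= 3 * res.slope_se

    def test_unit_scale_rescales_odds_ratio(self):
        rng = np.random.default_rng(7)
        x = rng.normal(scale=100, size=2000)
        y = rng.random(2000) < 1 / (1 + np.exp(-(-2 + 0.01 * x)))
        res10 = univariable_logistic_or(x, y, unit_scale=10.0)
        res1 = univariable_logistic_or(x, y, unit_scale=1.0)
        assert res10.odds_ratio == pytest.approx(res1.odds_ratio**10, rel=1e-9)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = (x > 0).astype(float)
        with pytest.raises(ConvergenceError):
            univariable_logistic_or(x, y)

    def test_single_outcome_class_rejected(self):
        with pytest.raises(ValueError):
            univariable_logistic_or([1.0, 2.0], [1.0, 1.0])


def _peri_participant(pid, peri, cancer):
    nodule = NoduleRecord(
        nodule_id=f"{pid}-n1",
        diameter_mm=4.0,
        volume_mm3=30.0,
        segmentation_reliable=True,
        perifissural_typical=peri,
        malignant=cancer,
    )
    return ParticipantRecord(
        participant_id=pid,
        age_years=65.0,
        sex="male",
        family_history_lung_cancer=False,
        emphysema=False,
        nodules=(nodule,),
        cancer_outcome=cancer,
        malignant_nodule_id=nodule.nodule_id if cancer else None,
    )


class TestPerifissuralRisk:
    def test_published_risk_with_registry_events(self):
        cohort = [
            _peri_participant(f"p{i}", True, i < 4) for i in range(3823)
        ] + [_peri_participant(f"q{i}", False, False) for i in range(100)]
        r = perifissural_risk(cohort, extra_events=4)
        assert r.n == 3823 and r.events == 8
        assert round(r.risk_pct, 2) == 0.21
        assert (round(r.ci[0], 2), round(r.ci[1], 2)) == (0.09, 0.41)

    def test_delegates_to_crude_risk(self):
        cohort = [_peri_participant(f"p{i}", True, i < 2) for i in range(50)]
        r = perifissural_risk(cohort)
        assert r.ci == crude_risk(2, 50).ci


class TestIntervalCoverageAndReduction:
    @pytest.mark.parametrize("p", [0.01, 0.1, 0.5])
    @pytest.mark.parametrize("n", [50, 500])
    def test_clopper_pearson_coverage_at_least_nominal(self, p, n):
        assert clopper_pearson_coverage(p, n, 0.95) >= 0.95

    def test_proportion_ci_brackets_point(self):
        lo, hi = proportion_ci(37, 4809)
        assert lo < 37 / 4809 < hi

    def test_false_positive_referral_reduction(self):
        assert false_positive_reduction(359, 198) == pytest.approx(44.846, abs=1e-2)
        with pytest.raises(ValueError):
            false_positive_reduction(0, 0)
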