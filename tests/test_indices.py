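import math

import numpy as np
import pytest

from binodex import (
    BinormalMixture,
    NormalComponent,
    auc,
    compute_report,
    interval_lr,
    likelihood_ratios,
    optimal_cutoff,
    point_lr,
    posterior_probability,
    predictive_values,
    reference_range,
    roc_curve,
    sensitivity,
    specificity,
)

T_OPT = math.log(1.61)


class TestSeSp:
    @pytest.mark.parametrize(
        "t,expected",
        [(T_OPT, 0.766), (math.log(4), 0.322), (math.log(6), 0.161)],
    )
    def test_sensitivity_reported_values(self, pos, t, expected):
        assert sensitivity(t, pos) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "t,expected",
        [(T_OPT, 0.825), (math.log(4), 0.991), (math.log(6), 0.999)],
    )
    def test_specificity_reported_values(self, neg, t, expected):
        assert specificity(t, neg) == pytest.approx(expected, abs=5e-4)

    def test_median_cutoff(self, neg, pos):
        assert sensitivity(pos.mu, pos) == pytest.approx(0.5)
        assert specificity(neg.mu, neg) == pytest.approx(0.5)

    def test_monotone_in_cutoff(self, printed_mix):
        t = np.linspace(-4, 5, 400)
        assert np.all(np.diff(sensitivity(t, printed_mix.pos)) < 0)
        assert np.all(np.diff(specificity(t, printed_mix.neg)) > 0)


class TestRoc:
    def test_uninformative_classifier_is_diagonal(self, neg):
        roc = roc_curve(BinormalMixture(neg, neg, pr=0.5))
        np.testing.assert_allclose(roc.tpr, roc.fpr, atol=1e-12)

    def test_monotone_and_spans_unit_square(self, printed_mix):
        roc = roc_curve(printed_mix)
        assert np.all(np.diff(roc.fpr) <= 0) and np.all(np.diff(roc.tpr) <= 0)
        assert roc.fpr[0] > 0.999 and roc.tpr[0] > 0.999
        assert roc.fpr[-1] < 1e-3 and roc.tpr[-1] < 1e-3

    def test_operating_point_on_curve(self, printed_mix):
        # the reported cut-off maps to (1-0.825, 0.766) on the curve
        roc = roc_curve(printed_mix)
        d = np.hypot(roc.fpr - (1 - 0.825), roc.tpr - 0.766)
        assert d.min() < 5e-3

    def test_perfect_separation_hits_top_left(self):
        mix = BinormalMixture(NormalComponent(-10, 0.3), NormalComponent(10, 0.3), 0.5)
        roc = roc_curve(mix, grid_size=2001)
        assert np.hypot(roc.fpr, roc.tpr - 1).min() < 1e-6

    def test_small_grid_rejected(self, printed_mix):
        with pytest.raises(ValueError):
            roc_curve(printed_mix, grid_size=2)


class TestAuc:
    def test_uninformative_is_half(self, neg):
        assert auc(BinormalMixture(neg, neg, pr=0.5)) == pytest.approx(0.5)

    def test_reported_value(self, printed_mix):
        # the printed parameters give 0.876 in closed form; the discrete
        # series reported alongside them rounds to 0.874
        assert auc(printed_mix, "closed_form") == pytest.approx(0.874, abs=3e-3)

    def test_trapezoid_matches_closed_form(self, printed_mix):
        assert abs(auc(printed_mix, "trapezoid") - auc(printed_mix, "closed_form")) < 1e-3

    def test_monte_carlo_oracle(self, printed_mix):
        rng = np.random.default_rng(12)
        n = 1_000_000
        x_neg = rng.normal(printed_mix.neg.mu, printed_mix.neg.sigma, n)
        x_pos = rng.normal(printed_mix.pos.mu, printed_mix.pos.sigma, n)
        p_hat = np.mean(x_pos > x_neg)
        se = math.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(auc(printed_mix, "closed_form") - p_hat) < 3 * se

    def test_wide_separation_approaches_one(self):
        mix = BinormalMixture(NormalComponent(-10, 0.5), NormalComponent(10, 0.5), 0.5)
        assert auc(mix) == pytest.approx(1.0, abs=1e-12)


class TestOptimalCutoff:
    def test_reported_cutoff(self, printed_mix):
        t = optimal_cutoff(printed_mix, "youden")
        assert round(math.exp(t), 2) == 1.61

    def test_equal_sigmas_give_midpoint(self):
        mix = BinormalMixture(NormalComponent(-1.0, 0.7), NormalComponent(2.0, 0.7), 0.3)
        assert optimal_cutoff(mix, "youden") == pytest.approx(0.5, abs=1e-10)

    def test_cost_mode_reduces_to_youden_at_neutral_cost(self, printed_mix):
        c_neutral = (1 - printed_mix.pr) / printed_mix.pr
        t_cost = optimal_cutoff(printed_mix, "cost", cost_ratio=c_neutral)
        assert t_cost == pytest.approx(optimal_cutoff(printed_mix, "youden"), abs=1e-9)

    def test_youden_cutoff_is_density_crossing(self, printed_mix):
        t = optimal_cutoff(printed_mix, "youden")
        assert point_lr(t, printed_mix) == pytest.approx(1.0, abs=1e-8)

    def test_youden_maximizes_grid(self, printed_mix):
        t = optimal_cutoff(printed_mix, "youden")
        grid = np.linspace(-3, 4, 20_001)
        j = sensitivity(grid, printed_mix.pos) + specificity(grid, printed_mix.neg) - 1
        j_star = sensitivity(t, printed_mix.pos) + specificity(t, printed_mix.neg) - 1
        assert j_star >= j.max() - 1e-9

    def test_cost_mode_requires_interior_prevalence(self, neg, pos):
        with pytest.raises(ValueError):
            optimal_cutoff(BinormalMixture(neg, pos, pr=0.0), "cost", cost_ratio=4.0)


class TestReferenceRange:
    def test_reported_limits(self, neg):
        low, high, p95 = reference_range(neg)
        assert low == pytest.approx(0.2505, abs=5e-4)
        assert high == pytest.approx(3.115, abs=5e-3)
        assert p95 == pytest.approx(2.544, abs=5e-3)
        assert low < p95 < high

    def test_coverage_by_simulation(self, neg):
        rng = np.random.default_rng(23)
        n = 100_000
        draws = np.exp(rng.normal(neg.mu, neg.sigma, n))
        low, high, _ = reference_range(neg)
        cover = np.mean((draws >= low) & (draws <= high))
        se = math.sqrt(0.95 * 0.05 / n)
        assert abs(cover - 0.95) < 3 * se


class TestPredictiveValues:
    def test_reported_values(self, printed_mix):
        se = float(sensitivity(T_OPT, printed_mix.pos))
        sp = float(specificity(T_OPT, printed_mix.neg))
        ppv, npv = predictive_values(se, sp, printed_mix.pr)
        assert ppv == pytest.approx(0.519, abs=5e-4)
        assert npv == pytest.approx(0.935, abs=5e-4)

    def test_certain_prevalence(self):
        ppv, _ = predictive_values(0.8, 0.9, 1.0)
        assert ppv == 1.0

    def test_uninformative_test_returns_prevalence(self):
        ppv, npv = predictive_values(0.5, 0.5, 0.3)
        assert ppv == pytest.approx(0.3) and npv == pytest.approx(0.7)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            predictive_values(0.0, 1.0, 0.0)

    def test_consistent_with_bayes_posterior(self, printed_mix):
        # PPV is the Bayes posterior for the evidence "value above cut-off"
        se = float(sensitivity(T_OPT, printed_mix.pos))
        sp = float(specificity(T_OPT, printed_mix.neg))
        pr = printed_mix.pr
        p_evidence = pr * se + (1 - pr) * (1 - sp)
        ppv, _ = predictive_values(se, sp, pr)
        assert posterior_probability(se, p_evidence, pr) == pytest.approx(ppv, rel=1e-12)


class TestLikelihoodRatios:
    def test_reported_values(self, printed_mix):
        # the published 4.38 / 0.28 follow from Se, Sp rounded to 3 decimals
        lr_pos, lr_neg = likelihood_ratios(0.766, 0.825)
        assert round(lr_pos, 2) == 4.38
        assert round(lr_neg, 2) == 0.28
        # unrounded, the same algebra gives 4.372 / 0.283
        se = float(sensitivity(T_OPT, printed_mix.pos))
        sp = float(specificity(T_OPT, printed_mix.neg))
        exact_pos, exact_neg = likelihood_ratios(se, sp)
        assert exact_pos == pytest.approx(4.372, abs=1e-3)
        assert exact_neg == pytest.approx(0.2833, abs=1e-3)

    def test_chance_level(self):
        lr_pos, _ = likelihood_ratios(0.3, 0.7)
        assert lr_pos == pytest.approx(1.0)

    def test_near_perfect_test(self):
        lr_pos, lr_neg = likelihood_ratios(0.999, 0.999)
        assert lr_pos == pytest.approx(999.0)
        assert lr_neg == pytest.approx(0.001 / 0.999, rel=1e-12)

    def test_degenerate_specificity_signalled(self):
        with pytest.raises(ValueError):
            likelihood_ratios(0.5, 1.0)
        with pytest.raises(ValueError):
            likelihood_ratios(0.5, 0.0)


class TestIntervalAndPointLr:
    def test_reported_interval(self, printed_mix):
        # a value between 4 and 6 ng/mL is ~20 times likelier under disease
        assert interval_lr(math.log(4), math.log(6), printed_mix) == pytest.approx(20.24, abs=0.01)

    def test_equals_mass_ratio(self, printed_mix):
        from scipy import stats

        t1, t2 = 0.3, 1.2
        num = stats.norm.cdf(t2, 1.033, 0.766) - stats.norm.cdf(t1, 1.033, 0.766)
        den = stats.norm.cdf(t2, -0.124, 0.643) - stats.norm.cdf(t1, -0.124, 0.643)
        assert interval_lr(t1, t2, printed_mix) == pytest.approx(num / den, rel=1e-10)

    def test_identical_components_give_unity(self, neg):
        mix = BinormalMixture(neg, neg, pr=0.5)
        assert interval_lr(-0.5, 0.9, mix) == pytest.approx(1.0, rel=1e-9)

    def test_unordered_interval_errors(self, printed_mix):
        with pytest.raises(ValueError):
            interval_lr(1.0, 1.0, printed_mix)

    def test_converges_to_point_lr(self, printed_mix):
        x = 0.9
        target = point_lr(x, printed_mix)
        widths = [1e-3, 1e-4, 1e-5, 1e-6]
        errs = [abs(interval_lr(x - w / 2, x + w / 2, printed_mix) - target) for w in widths]
        # quadratic shrinkage until float cancellation in the CDF differences
        # dominates (~1e-9); every width is already deep inside that regime
        assert errs[1] < errs[0] / 10
        assert max(errs) < 1e-4
        assert errs[-1] < 1e-6

    @pytest.mark.parametrize("x,expected,digits", [(1.79, 43, 0), (0.0, 0.34, 2)])
    def test_reported_point_values(self, printed_mix, x, expected, digits):
        assert round(point_lr(x, printed_mix), digits) == pytest.approx(expected)

    def test_point_lr_unity_for_identical_components(self, neg):
        mix = BinormalMixture(neg, neg, pr=0.5)
        x = np.linspace(-3, 3, 50)
        np.testing.assert_allclose(point_lr(x, mix), 1.0, rtol=1e-12)


class TestPosterior:
    def test_published_worked_example(self):
        assert posterior_probability(0.678, 0.820, 0.494) == pytest.approx(0.408, abs=5e-4)

    def test_independent_evidence_returns_prior(self):
        assert posterior_probability(0.6, 0.6, 0.37) == pytest.approx(0.37)

    def test_zero_prior(self):
        assert posterior_probability(0.5, 0.5, 0.0) == 0.0

    def test_incoherent_inputs_error(self):
        with pytest.raises(ValueError, match="incoherent"):
            posterior_probability(0.9, 0.1, 0.8)


class TestComputeReport:
    def test_full_report_at_auto_cutoff(self, printed_mix):
        rep = compute_report(printed_mix)
        assert rep.cutoff_raw == pytest.approx(1.61, abs=5e-3)
        assert rep.se == pytest.approx(0.766, abs=1e-2)
        assert rep.youden == pytest.approx(rep.se + rep.sp - 1)
        assert rep.prevalence == printed_mix.pr
        assert rep.ref_low < rep.p95 < rep.ref_high
        assert rep.cost_ratio is None

    def test_cost_weighted_report(self, printed_mix):
        rep = compute_report(printed_mix, mode="cost", cost_ratio=4.0)
        # at pr = 0.198 and C = 4 the cost rule sits beside the Youden root
        assert rep.cutoff_raw == pytest.approx(1.61, abs=2e-2)
        assert rep.cost_ratio == 4.0
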