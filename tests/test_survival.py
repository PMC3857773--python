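import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
import pandas as pd

from conftest import make_survival
from netmra.core import ExpressionMatrix, SurvivalTable, ValidationError
from netmra.simulate import simulate_survival
from netmra.survival import (
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    optimal_cutoff_scan,
    pairwise_group_tests,
    relative_expression,
)


class TestRelativeExpression:
    def test_values_divided_by_mean(self):
        m = ExpressionMatrix(["G"], ["a", "b", "c"], np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(relative_expression(m, "G"), [0.5, 1.0, 1.5])

    def test_constant_gene_all_ones(self):
        m = ExpressionMatrix(["G"], ["a", "b"], np.array([[3.0, 3.0]]))
        np.testing.assert_allclose(relative_expression(m, "G"), [1.0, 1.0])

    def test_zero_mean_rejected(self):
        m = ExpressionMatrix(["G"], ["a", "b"], np.array([[-1.0, 1.0]]))
        with pytest.raises(ValidationError):
            relative_expression(m, "G")


class TestPairwiseGroupTests:
    def test_three_groups_bonferroni(self, rng):
        values = rng.standard_normal(30)
        groups = np.repeat(["a", "b", "c"], 10)
        table = pairwise_group_tests(values, groups)
        assert len(table) == 3 and (table["correction"] == "bonferroni").all()
        np.testing.assert_allclose(table["p_corrected"],
                                   np.minimum(1.0, table["p"] * 3))

    def test_five_groups_bh(self, rng):
        values = rng.standard_normal(50)
        groups = np.repeat(list("abcde"), 10)
        table = pairwise_group_tests(values, groups)
        assert len(table) == 10 and (table["correction"] == "fdr_bh").all()

    def test_identical_groups_high_corrected_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(30):
            values = rng.standard_normal(30)
            groups = np.repeat(["a", "b", "c"], 10)
            ps.extend(pairwise_group_tests(values, groups)["p_corrected"])
        assert np.mean(np.array(ps) > 0.5) > 0.6  # corrected p concentrates high

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_group_tests([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestKaplanMeier:
    def test_three_events_no_censoring(self, toy_survival):
        km = km_estimate(toy_survival)
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_computed_with_censoring(self):
        # times 1,2,3,4 events 1,0,1,0: S(1)=3/4, S(3)=3/8
        t = make_survival([1, 2, 3, 4], [1, 0, 1, 0])
        km = km_estimate(t)
        np.testing.assert_allclose(km.survival, [0.75, 0.375])

    def test_all_censored_flat(self):
        km = km_estimate(make_survival([1, 2, 3], [0, 0, 0]))
        assert km.survival.size == 0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(1, 50) + 0.01
        t = make_survival(times, [1] * 50)
        km = km_estimate(t)
        for u, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(np.mean(times > u))

    def test_matches_lifelines(self, rng):
        times = np.round(rng.exponential(5, 80), 1) + 0.1  # ties included
        events = rng.integers(0, 2, 80)
        events[0] = 1
        t = make_survival(times, events)
        km = km_estimate(t)
        kmf = KaplanMeierFitter().fit(times, events)
        ours = dict(zip(km.event_times, km.survival))
        for u, s in ours.items():
            assert s == pytest.approx(kmf.predict(u), abs=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self, rng):
        times = rng.exponential(1, 30) + 0.01
        t = make_survival(times, [1] * 30)
        chi2, p = logrank_test(t, t)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        ta = make_survival(rng.exponential(1, 40) + 0.01, rng.integers(0, 2, 40))
        tb = make_survival(rng.exponential(3, 35) + 0.01, rng.integers(0, 2, 35))
        if ta.event.sum() + tb.event.sum() == 0:
            pytest.skip("degenerate draw")
        chi2, p = logrank_test(ta, tb)
        ref = ll_logrank(ta.time, tb.time, ta.event, tb.event)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_on_rate_ratio_three(self):
        significant = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ta = make_survival(rng.exponential(1.0, 200) + 1e-9, [1] * 200)
            tb = make_survival(rng.exponential(3.0, 200) + 1e-9, [1] * 200)
            if logrank_test(ta, tb)[1] < 0.001:
                significant += 1
        assert significant >= 19

    def test_equals_cox_score_test_binary_covariate(self, rng):
        """Log-rank chi-square equals the Cox score test at beta=0 for a
        binary covariate with untied event times."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = (r.random(60) > 0.5).astype(float)
            times = r.exponential(1 / np.exp(0.7 * x))
            events = (r.random(60) > 0.2).astype(int)
            if events.sum() < 2 or len({t for t in times}) < 60:
                continue
            table = make_survival(times, events, x)
            lr_chi2, _ = logrank_test(table.subset(x == 0), table.subset(x == 1))
            sc_chi2, _ = cox_score_test(table)
            assert lr_chi2 == pytest.approx(sc_chi2, abs=1e-6)

    def test_empty_group_rejected(self, toy_survival):
        with pytest.raises(ValidationError):
            logrank_test(toy_survival, toy_survival.subset(np.zeros(3, dtype=bool)))


class TestCox:
    def test_untied_closed_form_grid_oracle(self):
        """With a handful of untied events the partial likelihood has a
        simple closed form; the Newton fit matches a 1-D grid search."""
        x = np.array([1.0, 0.0, 0.5, -0.8])
        table = make_survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], x)
        fit = cox_fit(table)

        def neg_ll(beta):
            ll = 0.0
            for i in range(4):
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[i:])))
            return -ll

        coarse = np.linspace(-20, 20, 4001)
        best = coarse[np.argmin([neg_ll(b) for b in coarse])]
        fine = np.linspace(best - 0.02, best + 0.02, 40001)
        best = fine[np.argmin([neg_ll(b) for b in fine])]
        assert fit.beta == pytest.approx(best, abs=1e-6)
        assert neg_ll(fit.beta) == pytest.approx(-fit.log_partial_likelihood, abs=1e-9)

    def test_null_beta_recovery(self):
        betas = []
        for seed in range(20):
            table, _ = simulate_survival(500, 0.0, 0.1, 0.02, seed)
            betas.append(cox_fit(table).beta)
        assert abs(np.median(betas)) <= 0.15

    def test_log_two_recovery(self):
        betas = []
        for seed in range(20):
            table, _ = simulate_survival(1000, np.log(2), 0.1, 0.02, seed)
            betas.append(cox_fit(table).beta)
        assert abs(np.median(betas) - np.log(2)) <= 0.1

    def test_matches_lifelines_with_ties(self, rng):
        times = np.ceil(rng.exponential(5, 120))  # heavy ties
        x = rng.standard_normal(120)
        events = rng.integers(0, 2, 120)
        events[:2] = 1
        table = make_survival(times, events, x)
        fit = cox_fit(table)
        df = pd.DataFrame({"T": times, "E": events, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_likelihood_never_below_null(self, rng):
        table, _ = simulate_survival(200, 0.8, 0.1, 0.05, 3)
        fit = cox_fit(table)
        from netmra.survival import _cox_blocks, _cox_ll_grad_hess

        _, _, x, starts, blocks = _cox_blocks(table)
        ll0, _, _ = _cox_ll_grad_hess(0.0, x, starts, blocks)
        assert fit.log_partial_likelihood >= ll0

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit(make_survival([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0]))

    def test_perfect_separation_flagged_diverged(self):
        # covariate perfectly orders event times: monotone likelihood
        n = 30
        x = np.linspace(-2, 2, n)
        times = np.exp(-5 * x) + np.linspace(0, 1e-6, n)
        fit = cox_fit(make_survival(times, [1] * n, x))
        assert fit.diverged

    def test_breslow_option(self, rng):
        table, _ = simulate_survival(100, 0.5, 0.1, 0.05, 9)
        efron = cox_fit(table, tie_method="efron")
        breslow = cox_fit(table, tie_method="breslow")
        # no ties in continuous simulation: both must agree
        assert efron.beta == pytest.approx(breslow.beta, abs=1e-8)


class TestCutoffScan:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            t = make_survival(np.arange(1, 31), [1] * 30, [1.0] * 30)
            optimal_cutoff_scan(t, n_permutations=100, seed=1)

    def test_scan_covers_interquartile_percentiles(self):
        table, _ = simulate_survival(100, 0.5, 0.1, 0.02, 2)
        res = optimal_cutoff_scan(table, n_permutations=100, seed=3)
        assert res.scan["percentile"].min() == 25
        assert res.scan["percentile"].max() == 75
        assert res.selected_p == res.scan["p"].min()
        assert res.adjusted_p >= res.selected_p

    def test_selection_beats_median_split_nominally(self):
        table, _ = simulate_survival(120, 0.4, 0.1, 0.02, 4)
        res = optimal_cutoff_scan(table, n_permutations=100, seed=5)
        median_p = float(res.scan.loc[res.scan["percentile"] == 50, "p"].iloc[0])
        assert res.selected_p <= median_p

    def test_planted_median_effect_localized(self):
        """A hazard step exactly at the covariate median should select a
        cutoff near the 50th percentile."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.standard_normal(n)
            high = x > np.median(x)
            rate = np.where(high, 0.3, 0.1)
            times = rng.exponential(1 / rate)
            table = make_survival(times, [1] * n, x)
            res = optimal_cutoff_scan(table, n_permutations=50, seed=seed + 1)
            if 40 <= res.selected_percentile <= 60:
                hits += 1
        assert hits >= 18

    def test_determinism(self):
        table, _ = simulate_survival(80, 0.3, 0.1, 0.02, 6)
        r1 = optimal_cutoff_scan(table, n_permutations=200, seed=7)
        r2 = optimal_cutoff_scan(table, n_permutations=200, seed=7)
        assert r1.adjusted_p == r2.adjusted_p and r1.selected_percentile == r2.selected_percentile
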