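"""Cox fitting, screening, risk scores, KM/log-rank and time-dependent ROC."""

import numpy as np
import pandas as pd
import pytest

from wavprog.cox_prognosis import (
    CoxFit,
    PrognosticModel,
    SurvivalData,
    km_logrank,
    median_split,
    multivariate_cox,
    prognostic_risk_score,
    screen_univariate,
    stepwise_select,
    time_dependent_roc,
    univariate_cox,
)

from oracles import efron_fit, logrank_statistic, pairwise_auc


def _surv(time, event):
    return SurvivalData(tuple(f"s{i}" for i in range(len(time))),
                        np.asarray(time, float), np.asarray(event, int))


def _series(x):
    return pd.Series(np.asarray(x, float), index=[f"s{i}" for i in range(len(x))],
                     name="g")


class TestUnivariateCox:
    def test_parameter_recovery_hr_two(self, survival_factory):
        x, t, e = survival_factory(np.log(2.0), n=2000, seed=1)
        fit = univariate_cox(_series(x[0]), _surv(t, e))
        assert 1.8 <= fit.hr[0] <= 2.2

    def test_hr_is_exp_beta_and_ci_formula(self, survival_factory):
        x, t, e = survival_factory(0.5, n=300, seed=2)
        fit = univariate_cox(_series(x[0]), _surv(t, e))
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]), abs=1e-12)
        lo, hi = fit.ci95[0]
        assert lo == pytest.approx(np.exp(fit.beta[0] - 1.959963984540054 * fit.se[0]))
        assert hi == pytest.approx(np.exp(fit.beta[0] + 1.959963984540054 * fit.se[0]))
        assert lo < hi

    def test_negating_covariate_negates_beta(self, survival_factory):
        x, t, e = survival_factory(0.7, n=200, seed=3)
        s = _surv(t, e)
        f1 = univariate_cox(_series(x[0]), s)
        f2 = univariate_cox(_series(-x[0]), s)
        assert f1.beta[0] == pytest.approx(-f2.beta[0], abs=1e-8)

    def test_null_wald_rejection_rate_calibrated(self, survival_factory):
        """Permutation null: rejection at 0.05 stays within 0.05 +/- 0.02."""
        rng = np.random.default_rng(7)
        x, t, e = survival_factory(0.0, n=80, seed=7)
        s = _surv(t, e)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            fit = univariate_cox(_series(rng.permutation(x[0])), s)
            rejections += fit.p[0] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_agrees_with_independent_efron_maximizer(self, survival_factory):
        """Cross-implementation: lifelines vs the test-local Newton oracle."""
        for seed in range(20):
            x, t, e = survival_factory(
                np.random.default_rng(seed).uniform(-1, 1), n=40, seed=seed
            )
            fit = univariate_cox(_series(x[0]), _surv(t, e))
            beta_ref = efron_fit(x[0], t, e)
            assert abs(fit.beta[0] - beta_ref) < 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(_series(np.ones(30)), _surv(np.arange(1, 31), [1] * 30))
        with pytest.raises(ValueError, match="events"):
            univariate_cox(_series(np.arange(30.0)), _surv(np.arange(1, 31), [0] * 30))


class TestScreening:
    def test_null_survivor_count_near_alpha(self, survival_factory):
        rng = np.random.default_rng(11)
        _, t, e = survival_factory(0.0, n=150, seed=11)
        expr = pd.DataFrame(
            rng.normal(size=(100, 150)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(150)],
        )
        hits = screen_univariate(expr, _surv(t, e))
        assert len(hits) <= 12  # ~5 expected under the null

    def test_planted_gene_retained_and_order(self, survival_factory):
        x, t, e = survival_factory(0.8, n=300, seed=13)
        rng = np.random.default_rng(13)
        expr = pd.DataFrame(
            np.vstack([x, rng.normal(size=(9, 300))]),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(300)],
        )
        hits = screen_univariate(expr, _surv(t, e))
        assert hits[0][0] == "g0"  # smallest p first

    def test_alpha_zero_empty(self, survival_factory):
        x, t, e = survival_factory(0.8, n=100, seed=17)
        expr = pd.DataFrame(x, index=["g0"], columns=[f"s{i}" for i in range(100)])
        assert screen_univariate(expr, _surv(t, e), alpha=0.0) == []


class TestStepwise:
    def test_single_candidate_returned(self, survival_factory):
        x, t, e = survival_factory(0.6, n=100, seed=19)
        expr = pd.DataFrame(x, index=["g0"], columns=[f"s{i}" for i in range(100)])
        assert stepwise_select(["g0"], expr, _surv(t, e)) == ["g0"]

    def test_collinear_pair_pruned_to_one(self, survival_factory):
        x, t, e = survival_factory(0.8, n=400, seed=23)
        rng = np.random.default_rng(23)
        twin = x[0] + rng.normal(0, 0.05, 400)  # r > 0.95
        expr = pd.DataFrame(
            np.vstack([x[0], twin]), index=["g0", "g1"],
            columns=[f"s{i}" for i in range(400)],
        )
        selected = stepwise_select(["g0", "g1"], expr, _surv(t, e))
        assert len(selected) == 1

    def test_independent_informative_genes_both_kept(self, survival_factory):
        kept_both = 0
        for rep in range(5):
            x, t, e = survival_factory([0.6, 0.6], n=500, seed=29 + rep)
            expr = pd.DataFrame(
                x, index=["g0", "g1"], columns=[f"s{i}" for i in range(500)]
            )
            sel = stepwise_select(["g0", "g1"], expr, _surv(t, e))
            kept_both += sel == ["g0", "g1"]
        assert kept_both >= 4


class TestMultivariate:
    def test_single_covariate_equals_univariate(self, survival_factory):
        x, t, e = survival_factory(0.5, n=200, seed=31)
        expr = pd.DataFrame(x, index=["g0"], columns=[f"s{i}" for i in range(200)])
        s = _surv(t, e)
        fit_m, model = multivariate_cox(expr, s)
        fit_u = univariate_cox(expr.loc["g0"], s)
        assert fit_m.beta[0] == pytest.approx(fit_u.beta[0], abs=1e-10)
        assert model.gene_ids == ("g0",)

    def test_three_beta_recovery(self, survival_factory):
        x, t, e = survival_factory([0.5, -0.5, 0.3], n=2000, seed=37)
        expr = pd.DataFrame(
            x, index=["g0", "g1", "g2"], columns=[f"s{i}" for i in range(2000)]
        )
        fit, _ = multivariate_cox(expr, _surv(t, e))
        assert np.abs(fit.beta - [0.5, -0.5, 0.3]).max() <= 0.15

    def test_noise_covariate_leaves_estimates_within_one_se(self, survival_factory):
        x, t, e = survival_factory([0.5, -0.5], n=1000, seed=41)
        rng = np.random.default_rng(940)  # distinct stream from the covariates
        s = _surv(t, e)
        expr2 = pd.DataFrame(
            x, index=["g0", "g1"], columns=[f"s{i}" for i in range(1000)]
        )
        expr3 = pd.concat(
            [expr2, pd.DataFrame(rng.normal(size=(1, 1000)), index=["noise"],
                                 columns=expr2.columns)]
        )
        fit2, _ = multivariate_cox(expr2, s)
        fit3, _ = multivariate_cox(expr3, s)
        assert np.abs(fit3.beta[:2] - fit2.beta).max() <= fit2.se.max()

    def test_singular_design_names_collinear_pair(self, survival_factory):
        x, t, e = survival_factory(0.5, n=100, seed=43)
        expr = pd.DataFrame(
            np.vstack([x[0], x[0]]), index=["gA", "gB"],
            columns=[f"s{i}" for i in range(100)],
        )
        with pytest.raises(ValueError, match="gA.*gB"):
            multivariate_cox(expr, _surv(t, e))


class TestRiskScore:
    PUBLISHED = {
        "FAM184B": -0.342, "KRT19": 0.300, "GBP4": 0.318,
        "GALNT5": -0.070, "MCF2L": -0.412,
    }

    def _model(self):
        return PrognosticModel(
            tuple(self.PUBLISHED), np.array(list(self.PUBLISHED.values())), 0.0
        )

    def test_unit_expression_sums_printed_coefficients(self):
        """With Exp = 1 for every gene, PRS is the plain coefficient sum."""
        expr = pd.DataFrame(1.0, index=list(self.PUBLISHED), columns=["patient"])
        prs = prognostic_risk_score(self._model(), expr)
        assert prs["patient"] == pytest.approx(-0.342 + 0.300 + 0.318 - 0.070 - 0.412)

    def test_zero_expression_zero_score_and_linearity(self):
        rng = np.random.default_rng(47)
        expr = pd.DataFrame(
            rng.normal(size=(5, 4)), index=list(self.PUBLISHED),
            columns=[f"p{i}" for i in range(4)],
        )
        model = self._model()
        assert prognostic_risk_score(model, expr * 0).abs().max() == 0.0
        assert np.allclose(
            prognostic_risk_score(model, expr * 2),
            2 * prognostic_risk_score(model, expr),
        )

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame(1.0, index=["KRT19"], columns=["p"])
        with pytest.raises(ValueError, match="FAM184B"):
            prognostic_risk_score(self._model(), expr)


class TestMedianSplit:
    def test_even_count(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_tie_goes_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert list(labels) == ["low", "low", "high"]

    def test_order_invariance(self):
        prs = pd.Series([3.0, 1.0, 4.0, 2.0], index=list("abcd"))
        perm = prs.sample(frac=1, random_state=0)
        assert median_split(prs).sort_index().equals(median_split(perm).sort_index())

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([3.0, 5, 7, 9, 11, 13] * 2)
        e = np.array([1, 0, 1, 1, 0, 1] * 2)
        s = _surv(t, e)
        g = pd.Series(["a"] * 6 + ["b"] * 6, index=s.sample_ids)
        _, stat, p = km_logrank(g, s)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        """Matches the explicit O-E / V chi-square on a fixed fixture."""
        t = np.array([2.0, 4.0, 5.0, 6.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        grp = np.array([1, 0, 1, 1, 0, 0])
        s = _surv(t, e)
        g = pd.Series(np.where(grp == 1, "high", "low"), index=s.sample_ids)
        _, stat, _ = km_logrank(g, s)
        assert stat == pytest.approx(logrank_statistic(t, e, grp), abs=1e-10)

    def test_km_starts_at_one(self):
        t = np.array([5.0, 6, 7, 8])
        e = np.array([1, 1, 0, 1])
        s = _surv(t, e)
        g = pd.Series(["a", "a", "b", "b"], index=s.sample_ids)
        curves, _, _ = km_logrank(g, s)
        for curve in curves.values():
            assert curve.loc[curve["time"] == 0.0, "survival"].iloc[0] == 1.0

    def test_eventless_pair_rejected(self):
        s = _surv([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        g = pd.Series(["a", "a", "b", "b"], index=s.sample_ids)
        with pytest.raises(ValueError, match="events"):
            km_logrank(g, s)


class TestTimeDependentROC:
    def test_perfect_ordering_auc_one(self):
        t = np.array([10.0, 20, 30, 100, 110, 120])
        e = np.array([1, 1, 1, 0, 0, 0])
        s = _surv(t, e)
        prs = pd.Series([6.0, 5, 4, 3, 2, 1], index=s.sample_ids)
        _, auc = time_dependent_roc(prs, s, horizon=60.0)
        assert auc == 1.0

    def test_constant_score_auc_half(self):
        t = np.array([10.0, 20, 100, 120])
        e = np.array([1, 1, 0, 0])
        s = _surv(t, e)
        prs = pd.Series(np.ones(4), index=s.sample_ids)
        _, auc = time_dependent_roc(prs, s, horizon=60.0)
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_matches_pairwise_concordance_oracle(self):
        """Trapezoid AUC equals Mann-Whitney on 20 random 10-sample draws."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.uniform(1, 100, 10)
            e = rng.integers(0, 2, 10)
            scores = np.round(rng.normal(size=10), 1)  # provoke ties
            s = _surv(t, e)
            case = (e == 1) & (t <= 50)
            ctrl = t > 50
            if case.sum() == 0 or ctrl.sum() == 0:
                continue
            prs = pd.Series(scores, index=s.sample_ids)
            _, auc = time_dependent_roc(prs, s, horizon=50.0)
            keep = case | ctrl
            ref = pairwise_auc(scores[keep], case[keep])
            assert abs(auc - ref) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(53)
        t = rng.uniform(1, 100, 40)
        e = rng.integers(0, 2, 40)
        s = _surv(t, e)
        prs = pd.Series(rng.normal(size=40), index=s.sample_ids)
        _, a1 = time_dependent_roc(prs, s, 50.0)
        _, a2 = time_dependent_roc(np.exp(prs * 3), s, 50.0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_censored_before_horizon_excluded(self):
        t = np.array([10.0, 30.0, 100.0, 90.0])
        e = np.array([1, 0, 0, 1])   # s1 censored at 30 < horizon: excluded
        s = _surv(t, e)
        prs = pd.Series([4.0, 3.0, 2.0, 1.0], index=s.sample_ids)
        _, auc = time_dependent_roc(prs, s, horizon=60.0)
        # cases {s0}, controls {s2, s3}; s0 outranks both
        assert auc == 1.0

    def test_no_cases_rejected(self):
        s = _surv([100.0, 120.0], [0, 0])
        prs = pd.Series([1.0, 2.0], index=s.sample_ids)
        with pytest.raises(ValueError, match="case"):
            time_dependent_roc(prs, s, horizon=60.0)
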