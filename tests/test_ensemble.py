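import numpy as np
import pytest
import statsmodels.api as sm

from vterisk.cohort import Cohort, CohortError, VariableMeta
from vterisk.ensemble import (
    FitResult,
    ReplicateResult,
    aggregate_ensemble,
    fit_logistic,
    fit_logistic_cohort,
    replicate_data,
    run_ensemble,
    stepwise_select,
)
from vterisk.resample import replicate_seed


def _binary_cohort(case_exposed, case_unexposed, ctrl_exposed, ctrl_unexposed):
    vals = np.array(
        [1.0] * case_exposed + [0.0] * case_unexposed + [1.0] * ctrl_exposed + [0.0] * ctrl_unexposed
    )[:, None]
    status = np.array([1] * (case_exposed + case_unexposed) + [0] * (ctrl_exposed + ctrl_unexposed))
    ids = [f"s{i}" for i in range(len(vals))]
    return Cohort(ids, status, [VariableMeta("x", "binary")], vals)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = np.ones((4, 1))
        y = np.array([1.0, 1.0, 0.0, 0.0])
        f = fit_logistic(X, y)
        assert f.converged
        assert f.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert f.loglik == pytest.approx(4 * np.log(0.5), abs=1e-8)
        assert f.aic == pytest.approx(2 - 2 * 4 * np.log(0.5), abs=1e-6)

    def test_two_by_two_closed_form(self):
        """Saturated binary predictor: beta = log cross-product ratio,
        SE = sqrt of summed reciprocal cell counts."""
        c = _binary_cohort(30, 10, 10, 30)
        f = fit_logistic_cohort(c, ["x"])
        assert f.converged
        assert f.coef[1] == pytest.approx(np.log(9), abs=1e-6)
        assert f.se[1] == pytest.approx(np.sqrt(1 / 30 + 1 / 10 + 1 / 10 + 1 / 30), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_mle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 3, n)])
        eta = -0.3 + 0.8 * X[:, 1] + 0.4 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        f = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert f.converged
        np.testing.assert_allclose(f.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(f.se, ref.bse, atol=1e-5)
        assert f.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_perfect_separation_flagged_not_silent(self):
        c = _binary_cohort(20, 0, 0, 20)
        f = fit_logistic_cohort(c, ["x"])
        assert not f.converged
        assert f.se is None

    def test_aic_identity_holds(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = (rng.random(50) < 0.4).astype(float)
        f = fit_logistic(X, y)
        assert f.aic == pytest.approx(2 * X.shape[1] - 2 * f.loglik, rel=1e-12)


class TestStepwiseSelect:
    def test_no_candidates_gives_intercept_only(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        rr = stepwise_select(cohort, [])
        assert rr.selected == []
        assert len(rr.fit.coef) == 1

    def test_strong_predictor_selected_and_beats_null_aic(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        rr = stepwise_select(cohort, ["rs_strong"])
        null_aic = fit_logistic_cohort(cohort, []).aic
        single_aic = fit_logistic_cohort(cohort, ["rs_strong"]).aic
        assert rr.selected == ["rs_strong"]
        assert single_aic < null_aic
        assert rr.fit.aic == pytest.approx(single_aic, abs=1e-6)

    def test_aic_path_strictly_decreasing_under_noise(self):
        rng = np.random.default_rng(0)
        n, p = 120, 8
        for seed in range(30):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(n, p))
            status = (r.random(n) < 0.5).astype(int)
            if status.sum() in (0, n):
                continue
            schema = [VariableMeta(f"n{j:02d}", "continuous") for j in range(p)]
            c = Cohort([f"s{i}" for i in range(n)], status, schema, vals)
            rr = stepwise_select(c, c.var_names)
            assert all(b < a for a, b in zip(rr.aic_path, rr.aic_path[1:]))

    def test_forced_variables_stay_in_model(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        rr = stepwise_select(cohort, cohort.var_names, forced=["rs_null1"])
        assert "rs_null1" in rr.selected

    def test_forward_is_subset_of_candidates(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        rr = stepwise_select(cohort, cohort.var_names, direction="forward")
        assert set(rr.selected) <= set(cohort.var_names)


class TestRunEnsemble:
    def test_single_replicate_composes_impute_split_select(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        (rr,) = run_ensemble(cohort, cohort.var_names, 1, master_seed=17, compute_test_auc=False)
        rng = np.random.default_rng(replicate_seed(17, 0))
        complete, plan = replicate_data(cohort, rng, 0)
        direct = stepwise_select(complete.subset(plan.train_ids), cohort.var_names)
        assert rr.selected == direct.selected
        np.testing.assert_allclose(rr.fit.coef, direct.fit.coef)

    def test_same_master_seed_reproduces_replicates(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        a = run_ensemble(cohort, cohort.var_names, 3, 5)
        b = run_ensemble(cohort, cohort.var_names, 3, 5)
        assert [r.selected for r in a] == [r.selected for r in b]
        assert [r.test_auc for r in a] == [r.test_auc for r in b]

    def test_reducing_replicate_count_yields_prefix_of_schedule(self, small_signal_cohort):
        """Replicates are seeded independently, so a shorter run is an
        exact prefix of a longer one."""
        cohort, _ = small_signal_cohort
        long = run_ensemble(cohort, cohort.var_names, 5, 6, compute_test_auc=False)
        short = run_ensemble(cohort, cohort.var_names, 3, 6, compute_test_auc=False)
        assert [r.selected for r in long[:3]] == [r.selected for r in short]
        assert [r.seed for r in long[:3]] == [r.seed for r in short]

    def test_signal_variables_outselect_decoys(self, small_signal_cohort):
        cohort, _ = small_signal_cohort
        reps = run_ensemble(cohort, cohort.var_names, 30, 2, compute_test_auc=False)
        model = aggregate_ensemble(reps, cohort.var_names)
        s = {v.name: v.selection_frequency for v in model.variables}
        assert s["rs_strong"] > s["rs_null1"]
        assert s["rs_strong"] > s["rs_null2"]


def _fake_rep(i, variables, coefs, ses, intercept=-1.0):
    coef = np.array([intercept] + list(coefs))
    se = np.array([0.1] + list(ses))
    fit = FitResult(list(variables), coef, se, -10.0, 20.0 + 2 * len(coef), True, 5)
    return ReplicateResult(i, i, list(variables), fit, [25.0, 20.0])


class TestAggregateEnsemble:
    def test_never_selected_variable_has_unit_odds_ratio(self):
        reps = [_fake_rep(i, ["a"], [0.5], [0.1]) for i in range(4)]
        model = aggregate_ensemble(reps, ["a", "b"])
        b = model.summary("b")
        assert b.odds_ratio == 1.0
        assert b.median_se is None and b.p is None and b.ci95 is None
        assert b.selection_frequency == 0.0

    def test_median_with_unselected_counted_as_zero(self):
        reps = [
            _fake_rep(0, ["a"], [0.5], [0.2]),
            _fake_rep(1, ["a"], [1.0], [0.4]),
            _fake_rep(2, [], [], []),
        ]
        model = aggregate_ensemble(reps, ["a"])
        a = model.summary("a")
        assert a.median_coefficient == pytest.approx(0.5)  # median of {0, 0.5, 1.0}
        assert a.median_se == pytest.approx(0.3)  # over the 2 selected runs only
        assert a.selection_frequency == pytest.approx(2 / 3)

    def test_wald_ci_reproduces_printed_interval(self):
        """log(6.46) with SE 0.2387 gives the printed 95% CI lower bound ~4.04."""
        beta, se = np.log(6.46), 0.2387
        reps = [_fake_rep(i, ["v"], [beta], [se]) for i in range(3)]
        model = aggregate_ensemble(reps, ["v"])
        v = model.summary("v")
        assert v.odds_ratio == pytest.approx(6.46, abs=1e-9)
        assert v.ci95[0] == pytest.approx(4.05, abs=0.01)
        assert round(v.ci95[1], 1) == pytest.approx(10.3, abs=0.05)

    def test_ci_brackets_or_and_q_at_least_p(self):
        rng = np.random.default_rng(3)
        reps = []
        names = [f"v{j}" for j in range(6)]
        for i in range(9):
            sel = [n for n in names if rng.random() < 0.7]
            reps.append(_fake_rep(i, sel, rng.normal(size=len(sel)), 0.1 + rng.random(len(sel))))
        model = aggregate_ensemble(reps, names)
        for v in model.variables:
            if v.ci95 is not None:
                assert v.ci95[0] <= v.odds_ratio <= v.ci95[1]
            if v.p is not None:
                assert v.q >= v.p - 1e-12

    def test_intercept_is_median_over_all_replicates(self):
        reps = [_fake_rep(i, ["a"], [0.5], [0.1], intercept=float(i)) for i in range(5)]
        model = aggregate_ensemble(reps, ["a"])
        assert model.intercept == 2.0

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(CohortError):
            aggregate_ensemble([], ["a"])
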