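import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from vterisk.cohort import CohortError, ModelSpec
from vterisk.evaluate import (
    MODEL_REGISTRY,
    ROCCurve,
    auc_rank,
    compare_models,
    comparison_table,
    crossval_evaluate,
    registry_model,
    score_individuals,
)
from vterisk.simulate import VariantSpec, generate_cohort


def auc_pair_oracle(cases, controls):
    wins = sum(1.0 for a in cases for b in controls if a > b)
    ties = sum(1.0 for a in cases for b in controls if a == b)
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestAucRank:
    def test_perfect_separation(self):
        assert auc_rank([2, 3], [0, 1]) == 1.0

    def test_complete_ties(self):
        assert auc_rank([1, 1], [1, 1, 1]) == 0.5

    def test_enumerated_example(self):
        # pairs: 3>2, 3>0, 1<2, 1>0 -> 3/4
        assert auc_rank([3, 1], [2, 0]) == 0.75

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_enumeration_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        cases = rng.integers(0, 8, size=rng.integers(2, 20)).astype(float)
        ctrls = rng.integers(0, 8, size=rng.integers(2, 20)).astype(float)
        mine = auc_rank(cases, ctrls)
        assert mine == pytest.approx(auc_pair_oracle(cases, ctrls), rel=1e-12)
        y = np.r_[np.ones(len(cases)), np.zeros(len(ctrls))]
        assert mine == pytest.approx(roc_auc_score(y, np.r_[cases, ctrls]), rel=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=9)
        assert auc_rank(a, b) + auc_rank(b, a) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert auc_rank(a, b) == pytest.approx(auc_rank(np.exp(a), np.exp(b)))

    def test_empty_group_rejected(self):
        with pytest.raises(CohortError):
            auc_rank([], [1.0])


class TestROCCurve:
    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_area_equals_rank_auc_on_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(5, 40), rng.integers(5, 40)
        scores = rng.permutation(np.arange(n1 + n0, dtype=float))  # tie-free
        status = np.r_[np.ones(n1, dtype=int), np.zeros(n0, dtype=int)]
        curve = ROCCurve.from_scores(scores, status)
        assert curve.area == pytest.approx(auc_rank(scores[status == 1], scores[status == 0]), rel=1e-9)

    def test_non_monotone_coordinates_rejected(self):
        with pytest.raises(CohortError):
            ROCCurve(np.array([0.0, 0.5, 0.4, 1.0]), np.array([0.0, 0.5, 0.6, 1.0]))


@pytest.fixture(scope="module")
def snp_cohort():
    variants = [VariantSpec("rs_big", 0.3, np.log(3.5)), VariantSpec("rs_null", 0.4, 0.0)]
    cohort, _ = generate_cohort(variants, [], 400, 400, baseline_logit=-2.0, seed=21)
    return cohort


class TestCrossvalEvaluate:
    def test_null_model_has_chance_auc(self, snp_cohort):
        model = ModelSpec("null", ["rs_null"], refit=True)
        res = crossval_evaluate(snp_cohort, model, 40, 3)
        assert abs(res.median_auc - 0.5) < 0.05
        lo, hi = res.ci95
        assert 0 <= lo <= res.median_auc <= hi <= 1

    def test_strong_snp_auc_matches_genotype_table_oracle(self, snp_cohort):
        # With a single SNP the score is monotone in genotype, so the AUC
        # is computable exhaustively from the case/control genotype
        # distributions of the whole cohort.
        g = snp_cohort.column("rs_big")
        case_g, ctrl_g = g[snp_cohort.case_mask], g[~snp_cohort.case_mask]
        pc = np.array([(case_g == k).mean() for k in range(3)])
        pk = np.array([(ctrl_g == k).mean() for k in range(3)])
        oracle = sum(
            pc[i] * pk[j] * (1.0 if i > j else 0.5 if i == j else 0.0)
            for i in range(3)
            for j in range(3)
        )
        model = ModelSpec("single", ["rs_big"], refit=True)
        res = crossval_evaluate(snp_cohort, model, 40, 3)
        assert res.median_auc > 0.5
        assert abs(res.median_auc - oracle) < 0.04  # Monte-Carlo slack

    def test_same_seed_reproduces_result(self, snp_cohort):
        model = ModelSpec("m", ["rs_big"], refit=True)
        a = crossval_evaluate(snp_cohort, model, 10, 9)
        b = crossval_evaluate(snp_cohort, model, 10, 9)
        np.testing.assert_array_equal(a.aucs, b.aucs)

    def test_fixed_coefficient_model_requires_no_refit(self, snp_cohort):
        fixed = ModelSpec(
            "fixed", ["rs_big"], coefficients={"rs_big": np.log(3.5)}, intercept=-2.0, refit=False
        )
        res = crossval_evaluate(snp_cohort, fixed, 10, 4)
        assert res.median_auc > 0.6


class TestCompareModels:
    def test_identical_specs_give_identical_results(self, snp_cohort):
        m1 = ModelSpec("a", ["rs_big"], refit=True)
        m2 = ModelSpec("b", ["rs_big"], refit=True)
        results, pooled, averaged = compare_models(snp_cohort, [m1, m2], 8, 5)
        np.testing.assert_array_equal(results[0].aucs, results[1].aucs)
        np.testing.assert_array_equal(pooled["a"].tpr, pooled["b"].tpr)

    def test_missing_variable_named_in_error(self, snp_cohort):
        with pytest.raises(CohortError, match="rs6025"):
            compare_models(snp_cohort, [registry_model("dehaan5")], 4, 1)

    def test_comparison_table_shape(self, snp_cohort):
        results, _, _ = compare_models(
            snp_cohort, [ModelSpec("a", ["rs_big"], refit=True)], 6, 2, collect_roc=False
        )
        df = comparison_table(results)
        assert list(df.columns[:4]) == ["model", "median_auc", "ci_lo", "ci_hi"]


class TestRegistry:
    def test_dehaan5_lists_exactly_the_five_snps(self):
        assert registry_model("dehaan5").variables == [
            "rs6025", "rs1799963", "rs8176719", "rs2066865", "rs2036914",
        ]

    def test_bruzelius6_composition(self):
        assert set(MODEL_REGISTRY["bruzelius6"]) == {
            "rs6025", "rs1799963", "rs8176719", "rs2289252", "rs710446", "rs2066865",
        }

    def test_combined_is_clinical_plus_genetic(self):
        assert set(MODEL_REGISTRY["combined13"]) == set(
            MODEL_REGISTRY["clinical4"] + MODEL_REGISTRY["genetic9"]
        )
        assert len(MODEL_REGISTRY["combined13"]) == 13

    def test_unknown_registry_name_rejected(self):
        with pytest.raises(CohortError, match="unknown registry"):
            registry_model("nope")


class TestScoreIndividuals:
    @pytest.fixture
    def fixed_model(self):
        return ModelSpec(
            "m", ["g"], coefficients={"g": np.log(2.0)}, intercept=-1.0, refit=False
        )

    def test_all_zero_covariates_score_is_intercept(self, fixed_model):
        import pandas as pd

        out = score_individuals(fixed_model, pd.DataFrame({"g": [0.0]}))
        assert out["score"].iloc[0] == pytest.approx(-1.0)
        assert out["probability"].iloc[0] == pytest.approx(1 / (1 + np.exp(1.0)))

    def test_homozygote_adds_twice_the_log_or(self, fixed_model):
        import pandas as pd

        out = score_individuals(fixed_model, pd.DataFrame({"g": [0.0, 2.0]}))
        assert out["score"].iloc[1] - out["score"].iloc[0] == pytest.approx(2 * np.log(2.0))

    def test_model_without_intercept_omits_probability(self):
        import pandas as pd

        m = ModelSpec("m", ["g"], coefficients={"g": 1.0}, refit=False)
        out = score_individuals(m, pd.DataFrame({"g": [1.0]}))
        assert "probability" not in out.columns

    def test_missing_covariate_policy(self, fixed_model):
        import pandas as pd

        rows = pd.DataFrame({"g": [np.nan]})
        with pytest.raises(CohortError, match="missing"):
            score_individuals(fixed_model, rows)
        out = score_individuals(fixed_model, rows, missing="zero")
        assert out["score"].iloc[0] == pytest.approx(-1.0)
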