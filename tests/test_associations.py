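import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmpscore import (
    clinicopath_association,
    generate_drug_panel,
    mutation_burden_compare,
    per_gene_mutation_assoc,
    rank_test,
    ridge_drug_response,
    MutationMatrix,
)
from mmpscore.associations import significance_stars
from mmpscore.data_io import DataError, ExpressionMatrix


class TestRankTest:
    def test_exact_two_sample_enumeration(self):
        """{1,2,3} vs {4,5,6}: 2/20 assignments are as extreme => p = 0.1."""
        res = rank_test(np.arange(1.0, 7.0), ["a"] * 3 + ["b"] * 3)
        assert res.p == pytest.approx(0.1)
        assert res.test == "wilcoxon-exact"

    def test_identical_multisets_give_h_zero(self):
        res = rank_test([1.0, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3, mode="k-sample")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=40)
        g = rng.integers(0, 3, 40)
        r1 = rank_test(v, g, mode="k-sample")
        r2 = rank_test(np.exp(v), g, mode="k-sample")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_three_group_null_calibration(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_sim = 500
        for _ in range(n_sim):
            v = rng.normal(size=45)
            g = np.repeat([0, 1, 2], 15)
            rej += rank_test(v, g, mode="k-sample").p < 0.05
        assert abs(rej / n_sim - 0.05) <= 0.02

    def test_empty_group_is_error(self):
        with pytest.raises(DataError):
            rank_test([1.0, 2.0], ["a", "a"])

    def test_star_mapping(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(2e-4) == "***"
        assert significance_stars(1e-5) == "****"
        assert significance_stars(0.5) == "ns"


class TestMutationBurden:
    def test_identical_distributions_not_significant(self):
        idx = [f"S{i}" for i in range(20)]
        b = pd.Series([3] * 10 + [3] * 10, index=idx)
        g = pd.Series(["high"] * 10 + ["low"] * 10, index=idx)
        assert mutation_burden_compare(b, g).p == pytest.approx(1.0, abs=0.05)

    def test_planted_burden_difference_detected(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}" for i in range(200)]
        b = pd.Series(np.concatenate([rng.poisson(8, 100), rng.poisson(4, 100)]),
                      index=idx)
        g = pd.Series(["low"] * 100 + ["high"] * 100, index=idx)
        assert mutation_burden_compare(b, g).p < 0.01

    def test_single_sample_group_is_error(self):
        idx = ["S0", "S1"]
        b = pd.Series([1, 2], index=idx)
        g = pd.Series(["high", "high"], index=idx)
        with pytest.raises(DataError):
            mutation_burden_compare(b, g)


def _mutation_fixture(n_low_mut, n_low, n_high_mut, n_high):
    n = n_low + n_high
    idx = [f"S{i}" for i in range(n)]
    vals = np.zeros((1, n), dtype=int)
    vals[0, :n_low_mut] = 1
    vals[0, n_low:n_low + n_high_mut] = 1
    mut = MutationMatrix(pd.DataFrame(vals, index=["G1"], columns=idx))
    groups = pd.Series(["low"] * n_low + ["high"] * n_high, index=idx)
    return mut, groups


class TestPerGeneMutation:
    def test_closed_form_odds_ratio(self):
        mut, groups = _mutation_fixture(30, 100, 10, 100)
        res = per_gene_mutation_assoc(mut, groups, min_mutated=10)[0]
        assert res.odds_ratio == pytest.approx(27 / 7, rel=1e-6)
        assert res.odds_ratio == pytest.approx(np.exp(res.beta), rel=1e-9)

    def test_equal_rates_give_unit_odds_ratio(self):
        mut, groups = _mutation_fixture(20, 100, 20, 100)
        res = per_gene_mutation_assoc(mut, groups, min_mutated=10)[0]
        assert res.odds_ratio == pytest.approx(1.0, rel=1e-6)
        assert res.p > 0.9

    def test_group_swap_inverts_odds_ratio(self):
        mut, groups = _mutation_fixture(30, 100, 10, 100)
        swapped = groups.map({"low": "high", "high": "low"})
        r1 = per_gene_mutation_assoc(mut, groups, min_mutated=10)[0]
        r2 = per_gene_mutation_assoc(mut, swapped, min_mutated=10)[0]
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio, rel=1e-6)

    def test_rare_gene_skipped(self):
        mut, groups = _mutation_fixture(3, 100, 2, 100)
        assert per_gene_mutation_assoc(mut, groups, min_mutated=10) == []

    def test_zero_cell_gets_haldane_correction(self):
        mut, groups = _mutation_fixture(15, 100, 0, 100)
        res = per_gene_mutation_assoc(mut, groups, min_mutated=10)[0]
        assert res.corrected
        assert np.isfinite(res.beta) and np.isfinite(res.se)

    def test_wald_agrees_with_fisher_oracle(self):
        """On random 2x2 tables with all cells >=5 the Wald test agrees with
        Fisher's exact test — same accept/reject at alpha = 0.05 and a
        p-value within an order of magnitude — in >=95% of 200 tables."""
        rng = np.random.default_rng(7)
        agree = 0
        n_tab = 200
        for _ in range(n_tab):
            while True:
                a, b = rng.integers(5, 45), rng.integers(5, 45)
                c, d = rng.integers(5, 45), rng.integers(5, 45)
                if min(a, b, c, d) >= 5:
                    break
            n_low, n_high = a + b, c + d
            mut, groups = _mutation_fixture(a, n_low, c, n_high)
            res = per_gene_mutation_assoc(mut, groups, min_mutated=5)[0]
            p_fisher = stats.fisher_exact([[a, b], [c, d]])[1]
            same_call = (res.p < 0.05) == (p_fisher < 0.05)
            within_decade = 0.1 < res.p / p_fisher < 10
            agree += same_call and within_decade
        assert agree / n_tab >= 0.95


class TestRidgeDrugResponse:
    def test_infinite_shrinkage_predicts_training_mean(self):
        expr, y, _ = generate_drug_panel(40, 15, 4, 0.3, seed=0)
        pred = ridge_drug_response(expr, y, expr, lam=1e12)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-3)

    def test_exact_interpolation_in_noiseless_overdetermined_regime(self):
        expr, y, _ = generate_drug_panel(120, 30, 6, 0.0, seed=1)
        train = ExpressionMatrix(expr.values.iloc[:, :80])
        test = ExpressionMatrix(expr.values.iloc[:, 80:])
        pred_train = ridge_drug_response(train, y[:80], train, lam=0.0)
        assert np.abs(pred_train - y[:80]).max() < 1e-6
        pred_test = ridge_drug_response(train, y[:80], test, lam=0.0)
        ss_res = float(((pred_test - y[80:]) ** 2).sum())
        ss_tot = float(((y[80:] - y[80:].mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot > 0.99

    def test_cv_at_least_as_good_as_unregularized(self):
        expr, y, _ = generate_drug_panel(80, 60, 8, 0.5, seed=0)
        train = ExpressionMatrix(expr.values.iloc[:, :50])
        test = ExpressionMatrix(expr.values.iloc[:, 50:])

        def r2(pred):
            res = float(((pred - y[50:]) ** 2).sum())
            tot = float(((y[50:] - y[50:].mean()) ** 2).sum())
            return 1 - res / tot

        r2_cv = r2(ridge_drug_response(train, y[:50], test, lam="cv"))
        r2_zero = r2(ridge_drug_response(train, y[:50], test, lam=1e-8))
        assert r2_cv >= r2_zero

    def test_low_gene_overlap_is_error(self):
        expr, y, _ = generate_drug_panel(20, 10, 2, 0.1, seed=0)
        cohort = ExpressionMatrix(expr.values.iloc[:3])
        with pytest.raises(DataError, match="overlap"):
            ridge_drug_response(expr, y, cohort)


class TestClinicopath:
    def test_score_tracking_stage_detected(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}" for i in range(200)]
        stage = pd.DataFrame({"T": rng.integers(1, 5, 200)}, index=idx)
        scores = pd.Series(stage["T"] + 0.3 * rng.normal(size=200), index=idx)
        out = clinicopath_association(scores, stage)
        assert out[0].p < 0.001

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        rej, n_sim = 0, 500
        for _ in range(n_sim):
            idx = [f"S{i}" for i in range(60)]
            stage = pd.DataFrame({"T": np.repeat([1, 2, 3], 20)}, index=idx)
            scores = pd.Series(rng.normal(size=60), index=idx)
            rej += clinicopath_association(scores, stage)[0].p < 0.05
        assert abs(rej / n_sim - 0.05) <= 0.02

    def test_single_level_covariate_skipped(self):
        idx = [f"S{i}" for i in range(10)]
        stage = pd.DataFrame({"M": [1] * 10}, index=idx)
        scores = pd.Series(np.arange(10.0), index=idx)
        assert clinicopath_association(scores, stage) == []
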