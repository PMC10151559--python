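import numpy as np
import pandas as pd
import pytest

from mmpscore import (
    CohortSpec,
    ExpressionMatrix,
    SignaturePair,
    assign_signatures,
    boruta_select,
    fit_scores,
    generate_cohort,
    median_split,
    project_scores,
)
from mmpscore.data_io import DataError
from mmpscore.synthetic import make_planted_classification


@pytest.fixture(scope="module")
def scored_cohort():
    """Cohort with scores fitted from the planted signature split."""
    c = generate_cohort(CohortSpec(n_samples=300, seed=0))
    pair = SignaturePair(c.truth["up_genes"], c.truth["down_genes"],
                        cluster_order=[0, 1, 2])
    return c, fit_scores(c.expression, pair)


class TestAssignSignatures:
    def _setup(self, gene_rows):
        """Three clusters of 6 samples with hand-set gene trajectories."""
        n = 18
        labels = pd.Series([1] * 6 + [2] * 6 + [3] * 6,
                           index=[f"S{i}" for i in range(n)])
        rows = {g: vals for g, vals in gene_rows.items()}
        rows["FILLER"] = np.linspace(0, 1, n)
        expr = ExpressionMatrix(pd.DataFrame(rows, index=labels.index).T)
        # cluster 1 best prognosis, cluster 3 worst
        time = np.array([100.0] * 6 + [50.0] * 6 + [10.0] * 6)
        clin = pd.DataFrame({"OS_time": time, "OS_event": 1}, index=labels.index)
        from mmpscore import ClinicalTable
        return expr, labels, ClinicalTable(clin)

    def test_monotone_genes_split_by_direction(self):
        inc = np.repeat([0.0, 1.0, 2.0], 6)  # rises toward worse prognosis
        dec = inc[::-1].copy()
        expr, labels, clin = self._setup({"UP": inc, "DOWN": dec})
        pair = assign_signatures(expr, {"UP", "DOWN"}, labels, clin, "OS")
        assert pair.signature_A == ["UP"]
        assert pair.signature_B == ["DOWN"]
        assert list(pair.cluster_order) == [1, 2, 3]  # best -> worst

    def test_constant_gene_excluded(self):
        inc = np.repeat([0.0, 1.0, 2.0], 6)
        expr, labels, clin = self._setup({"UP": inc, "FLAT": np.zeros(18)})
        pair = assign_signatures(expr, {"UP", "FLAT"}, labels, clin, "OS")
        assert "FLAT" not in pair.signature_A + pair.signature_B

    def test_single_cluster_is_error(self):
        inc = np.repeat([0.0, 1.0, 2.0], 6)
        expr, labels, clin = self._setup({"UP": inc})
        with pytest.raises(DataError):
            assign_signatures(expr, {"UP"}, pd.Series(1, index=labels.index),
                              clin, "OS")


class TestBoruta:
    def test_single_iteration_leaves_everything_tentative(self):
        X, y = make_planted_classification(100, 10, 2, seed=0)
        res = boruta_select(X, y, max_iter=1, seed=0, n_estimators=50)
        assert len(res.tentative) == 10
        assert res.confirmed == [] and res.rejected == []

    def test_shuffled_target_confirms_almost_nothing(self):
        """Null behavior at Bonferroni-corrected alpha: <=2 of 50 features
        confirmed across five independent label shuffles."""
        X, y = make_planted_classification(300, 50, 5, seed=0)
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            y_null = rng.permutation(y)
            res = boruta_select(X, y_null, max_iter=12, seed=seed, n_estimators=100)
            total += len(res.confirmed)
        assert total <= 2

    def test_result_partitions_features(self):
        X, y = make_planted_classification(150, 12, 3, seed=1)
        res = boruta_select(X, y, max_iter=10, seed=1, n_estimators=80)
        all_feats = set(res.confirmed) | set(res.rejected) | set(res.tentative)
        assert len(all_feats) == 12

    def test_non_finite_input_rejected(self):
        X = np.ones((20, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            boruta_select(X, np.zeros(20), max_iter=2)


class TestFitScores:
    def test_identical_signature_content_cancels(self, rng):
        # invariant-respecting version of "A == B": B genes are exact copies
        # of A genes under different names, so PC1A == PC1B and score == 0
        X = rng.normal(size=(4, 30))
        values = np.vstack([X, X])
        expr = ExpressionMatrix(pd.DataFrame(
            values, index=[f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)],
            columns=[f"S{j}" for j in range(30)]))
        st = fit_scores(expr, SignaturePair([f"A{i}" for i in range(4)],
                                            [f"B{i}" for i in range(4)], [1, 2]))
        np.testing.assert_allclose(st.scores.to_numpy(), 0.0, atol=1e-10)

    def test_score_recovers_latent_factor(self, scored_cohort):
        c, st = scored_cohort
        r = np.corrcoef(st.scores, c.truth["latent_factor"])[0, 1]
        assert abs(r) >= 0.9

    def test_sign_convention_positive_against_signature_mean(self, scored_cohort):
        c, st = scored_cohort
        for genes, pc1 in ((c.truth["up_genes"], st.table["pc1_A"]),
                           (c.truth["down_genes"], st.table["pc1_B"])):
            sub = c.expression.values.loc[genes]
            z = (sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1), axis=0)
            assert np.corrcoef(pc1, z.mean(axis=0))[0, 1] > 0

    def test_gene_and_sample_order_invariance(self, scored_cohort, rng):
        c, st = scored_cohort
        pair = SignaturePair(list(rng.permutation(c.truth["up_genes"])),
                             list(rng.permutation(c.truth["down_genes"])), [0, 1, 2])
        perm = rng.permutation(c.expression.n_samples)
        expr_p = ExpressionMatrix(c.expression.values.iloc[:, perm])
        st2 = fit_scores(expr_p, pair)
        np.testing.assert_allclose(st2.scores.reindex(st.scores.index),
                                   st.scores, atol=1e-9)

    def test_global_constant_shift_leaves_scores_unchanged(self, scored_cohort):
        c, st = scored_cohort
        shifted = ExpressionMatrix(c.expression.values + 7.5)
        pair = SignaturePair(c.truth["up_genes"], c.truth["down_genes"], [0, 1, 2])
        st2 = fit_scores(shifted, pair)
        np.testing.assert_allclose(st2.scores, st.scores, atol=1e-9)

    def test_all_constant_signature_is_error(self):
        values = np.vstack([np.ones((2, 10)), np.random.default_rng(0).normal(size=(2, 10))])
        expr = ExpressionMatrix(pd.DataFrame(
            values, index=["C1", "C2", "V1", "V2"],
            columns=[f"S{j}" for j in range(10)]))
        with pytest.raises(DataError, match="constant"):
            fit_scores(expr, SignaturePair(["C1", "C2"], ["V1", "V2"], [1, 2]))

    def test_overlapping_signatures_rejected(self):
        with pytest.raises(DataError, match="overlap"):
            SignaturePair(["G1", "G2"], ["G2"], [1, 2])


class TestMedianSplit:
    def test_even_split(self):
        g = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(g) == ["low", "low", "high", "high"]

    def test_tie_rule_at_median(self):
        g = median_split(pd.Series([1.0, 2.0, 2.0, 3.0]))
        assert list(g) == ["low", "low", "low", "high"]

    def test_all_equal_degenerates_to_all_low(self, caplog):
        g = median_split(pd.Series([5.0, 5.0, 5.0]))
        assert (g == "low").all()

    def test_balanced_on_continuous_scores(self, scored_cohort):
        _, st = scored_cohort
        counts = st.groups.value_counts()
        assert abs(counts["high"] - counts["low"]) <= 1


class TestProjection:
    def test_self_projection_reproduces_training_scores(self, scored_cohort):
        c, st = scored_cohort
        proj = project_scores(c.expression, st.model)
        np.testing.assert_allclose(proj.scores, st.scores, atol=1e-12)

    def test_missing_gene_contributes_zero(self, scored_cohort):
        c, st = scored_cohort
        drop = c.truth["up_genes"][0]
        reduced = ExpressionMatrix(c.expression.values.drop(index=drop))
        proj = project_scores(reduced, st.model)
        # oracle: recompute training PC1A with that gene's contribution zeroed
        la = st.model.loadings_A
        i = la.genes.index(drop)
        z = (c.expression.values.loc[drop].to_numpy() - la.means[i]) / la.scales[i]
        expected = st.table["pc1_A"].to_numpy() - la.weights[i] * z
        np.testing.assert_allclose(proj.table["pc1_A"], expected, atol=1e-10)

    def test_low_overlap_is_error(self, scored_cohort):
        c, st = scored_cohort
        keep = c.truth["up_genes"][:3] + c.truth["down_genes"]
        reduced = ExpressionMatrix(c.expression.values.loc[keep])
        with pytest.raises(DataError, match="signature genes present"):
            project_scores(reduced, st.model)

    def test_transfers_to_new_cohort_from_same_process(self, scored_cohort):
        """Projected high/low groups separate the planted latent factor."""
        from scipy import stats
        c, st = scored_cohort
        c2 = generate_cohort(CohortSpec(n_samples=300, seed=99))
        proj = project_scores(c2.expression, st.model)
        f = c2.truth["latent_factor"]
        hi = f[proj.groups == "high"]
        lo = f[proj.groups == "low"]
        p = stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue
        assert p < 0.01
        assert hi.mean() > lo.mean()

    def test_model_json_round_trip(self, scored_cohort, tmp_path):
        c, st = scored_cohort
        path = tmp_path / "model.json"
        st.model.to_json(path)
        from mmpscore import ScoreModel
        model = ScoreModel.from_json(path)
        proj = project_scores(c.expression, model)
        np.testing.assert_allclose(proj.scores, st.scores, atol=1e-12)


def test_direction_stability_across_seeds():
    """Sign convention makes high-score groups carry higher latent factor."""
    for seed in range(10):
        c = generate_cohort(CohortSpec(n_samples=150, seed=seed))
        pair = SignaturePair(c.truth["up_genes"], c.truth["down_genes"], [0, 1, 2])
        st = fit_scores(c.expression, pair)
        f = c.truth["latent_factor"]
        assert f[st.groups == "high"].mean() > f[st.groups == "low"].mean()
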