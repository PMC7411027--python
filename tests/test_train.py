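"""Predictor construction: association scan, path fitting, selection, scoring."""
import numpy as np
import pandas as pd
import pytest

from sibprs import SimConfig, simulate_cohort
from sibprs.datatypes import GenotypeMatrix, PhenotypeTable
from sibprs.train import (
    TrainConfig,
    compute_scores,
    fit_lasso_path,
    kkt_residuals,
    lasso_objective,
    rank_select,
    select_lambda,
    single_marker_regression,
    train_ensemble,
)
from tests.conftest import make_phen


def _gm(dosages, sample_ids=None):
    dosages = np.asarray(dosages)
    ids = sample_ids or [f"s{i}" for i in range(dosages.shape[0])]
    vids = [f"v{j:03d}" for j in range(dosages.shape[1])]
    return GenotypeMatrix(ids, vids, dosages)


class TestAssociation:
    def test_identity_fit_toy(self):
        gm = _gm(np.array([[0], [1], [2], [1]], dtype=np.uint8))
        phen = make_phen(gm.sample_ids, [0, 1, 2, 1])
        res = single_marker_regression(gm, phen, gm.sample_ids)
        assert res["slope"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] < 1e-6

    def test_perfect_association_ranks_first(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(200, 30)).astype(np.uint8)
        gm = _gm(d)
        x = d[:, 7].astype(float)
        phen = make_phen(gm.sample_ids, (x - x.mean()) / x.std())
        res = single_marker_regression(gm, phen, gm.sample_ids)
        assert rank_select(res, 1)[0] == gm.variant_ids[7]

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(500, 2000)).astype(np.uint8)
        gm = _gm(d)
        phen = make_phen(gm.sample_ids, rng.standard_normal(500))
        res = single_marker_regression(gm, phen, gm.sample_ids)
        frac = (res["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 2000))

    def test_monomorphic_flagged_and_ranked_last(self):
        d = np.array([[0, 1], [0, 2], [0, 0], [0, 1]], dtype=np.uint8)
        gm = _gm(d)
        phen = make_phen(gm.sample_ids, [0.1, 0.9, -0.3, 0.2])
        res = single_marker_regression(gm, phen, gm.sample_ids)
        assert np.isnan(res["p_value"].iloc[0])
        assert list(rank_select(res, 2)) == [gm.variant_ids[1], gm.variant_ids[0]]


class TestRankSelect:
    def test_k_exceeding_p_returns_all(self):
        assoc = pd.DataFrame({"p_value": [0.5, 0.1]}, index=["b", "a"])
        assert len(rank_select(assoc, 10)) == 2

    def test_order_statistics(self):
        assoc = pd.DataFrame({"p_value": [0.5, 0.001, 0.2]}, index=["v1", "v2", "v3"])
        assert list(rank_select(assoc, 2)) == ["v2", "v3"]

    def test_tie_break_lexicographic(self):
        assoc = pd.DataFrame({"p_value": [0.3, 0.3, 0.3]}, index=["vC", "vA", "vB"])
        assert list(rank_select(assoc, 2)) == ["vA", "vB"]


class TestLassoPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 10))
        y = X[:, 0] + rng.normal(size=100)
        path = fit_lasso_path(X, y)
        assert np.all(path.coefficients[0] == 0.0)
        assert np.all(np.diff(path.lambda_grid) < 0)

    def test_univariate_soft_threshold_closed_form(self):
        # single standardized predictor: beta(lambda) = sign(c) max(0, |c| - lambda)
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400) * 0.5
        path = fit_lasso_path(x[:, None], y, n_lambdas=50)
        xs = (x - x.mean()) / x.std()
        yc = y - y.mean()
        c = float(xs @ yc) / len(y)
        expected = np.sign(c) * np.maximum(0.0, np.abs(c) - path.lambda_grid)
        assert np.allclose(path.coefficients[:, 0], expected, atol=1e-6)

    def test_kkt_conditions_along_path(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 40))
        beta = np.zeros(40)
        beta[:5] = [1.0, -0.8, 0.5, 0.3, -0.2]
        y = X @ beta + rng.normal(size=150)
        path = fit_lasso_path(X, y, n_lambdas=30)
        assert kkt_residuals(path, X, y).max() < 1e-4

    def test_objective_minimality_probe(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 12))
        y = X[:, 0] - X[:, 3] + 0.3 * rng.normal(size=80)
        path = fit_lasso_path(X, y, n_lambdas=20)
        Xs = (X - path.x_mean) / path.x_sd
        yc = y - path.y_mean
        for i in (5, 10, 19):
            lam = path.lambda_grid[i]
            b = path.coefficients[i].copy()
            base = lasso_objective(Xs, yc, b, lam)
            for j in np.flatnonzero(b):
                for eps in (1e-3, -1e-3):
                    bp = b.copy()
                    bp[j] += eps
                    assert lasso_objective(Xs, yc, bp, lam) >= base - 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso_path(np.ones((1, 2)), np.ones(1))
        with pytest.raises(ValueError):
            fit_lasso_path(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]))


class TestSelectLambda:
    def _path_and_val(self, seed=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 20))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=300)
        path = fit_lasso_path(X[:200], y[:200], n_lambdas=30)
        return path, X[200:], y[200:]

    def test_chooses_argmax_metric(self):
        path, Xv, yv = self._path_and_val()
        pred = select_lambda(path, Xv, yv, "correlation")
        Xs = (Xv - path.x_mean) / path.x_sd
        S = Xs @ path.coefficients.T
        best = max(
            0.0 if np.std(S[:, i]) == 0 else np.corrcoef(S[:, i], yv)[0, 1]
            for i in range(S.shape[1])
        )
        assert pred.metric_value == pytest.approx(best)

    def test_binary_validation_needs_both_classes(self):
        path, Xv, _ = self._path_and_val()
        with pytest.raises(ValueError):
            select_lambda(path, Xv, np.ones(len(Xv)), "auc")

    def test_all_zero_point_gives_auc_half(self):
        path, Xv, yv = self._path_and_val()
        labels = (yv > np.median(yv)).astype(float)
        from sibprs.metrics import auc
        Xs = (Xv - path.x_mean) / path.x_sd
        s0 = Xs @ path.coefficients[0]
        assert auc(s0, labels) == 0.5  # lambda_max point scores are constant 0


class TestEnsemble:
    def test_holdouts_disjoint_and_deterministic(self, small_binary_cohort):
        c = small_binary_cohort
        cfg = TrainConfig(k=150, holdout_cases=60, holdout_controls=60, seed=7,
                          n_lambdas=40)
        ens1 = train_ensemble(c.genotypes, c.phenotypes, c.pedigree, "binary", cfg)
        assert ens1.check_holdouts_disjoint()
        ens2 = train_ensemble(c.genotypes, c.phenotypes, c.pedigree, "binary", cfg)
        for p1, p2 in zip(ens1.predictors, ens2.predictors):
            assert np.array_equal(p1.weights, p2.weights)
            assert p1.chosen_lambda == p2.chosen_lambda

    def test_holdouts_exclude_siblings(self, small_binary_cohort):
        c = small_binary_cohort
        cfg = TrainConfig(k=150, holdout_cases=60, holdout_controls=60, seed=7,
                          n_lambdas=40)
        ens = train_ensemble(c.genotypes, c.phenotypes, c.pedigree, "binary", cfg)
        sibs = set(c.pedigree.sib_ids())
        for p in ens.predictors:
            assert not (set(p.holdout_ids) & sibs)

    def test_metric_stability_across_members(self, small_binary_cohort):
        c = small_binary_cohort
        cfg = TrainConfig(k=150, holdout_cases=60, holdout_controls=60, seed=8,
                          n_lambdas=40)
        ens = train_ensemble(c.genotypes, c.phenotypes, c.pedigree, "binary", cfg)
        m = ens.metric_values
        assert np.all(np.abs(m - m.mean()) <= 3 * max(m.std(ddof=1), 1e-3))

    def test_zero_heritability_gives_null_auc(self):
        cfg_sim = SimConfig(n_families=50, n_unrelated=2500, n_variants=300, n_causal=0,
                            h2=0.0, prevalence=0.3, seed=21, trait_kind="binary")
        c = simulate_cohort(cfg_sim)
        cfg = TrainConfig(k=100, holdout_cases=80, holdout_controls=80, seed=9,
                          n_lambdas=30)
        ens = train_ensemble(c.genotypes, c.phenotypes, c.pedigree, "binary", cfg)
        assert ens.metric_mean == pytest.approx(0.5, abs=0.06)

    def test_insufficient_cases_error_names_shortfall(self, small_binary_cohort):
        c = small_binary_cohort
        cfg = TrainConfig(k=100, holdout_cases=10_000, holdout_controls=10)
        with pytest.raises(ValueError, match="cases"):
            train_ensemble(c.genotypes, c.phenotypes, c.pedigree, "binary", cfg)


class TestScoring:
    def _tiny_ensemble(self, vids, weights):
        from sibprs.train import Predictor, PredictorEnsemble
        p = Predictor(np.asarray(vids, dtype=object), np.asarray(weights, float),
                      0.1, "auc", 0.6, "t")
        return PredictorEnsemble([p], "t", "binary")

    def test_zero_weights_zero_scores(self):
        gm = _gm(np.array([[0, 1], [2, 1]], dtype=np.uint8))
        ens = self._tiny_ensemble(gm.variant_ids, [0.0, 0.0])
        st = compute_scores(gm, ens, gm.sample_ids)
        assert np.allclose(st.ref_mean, 0.0)
        assert np.allclose(st.scores, 0.0)

    def test_zscore_population_convention(self):
        # one variant, weight 2, dosages 0/1/2 -> raw (0,2,4), z (-1.225, 0, 1.225)
        gm = _gm(np.array([[0], [1], [2]], dtype=np.uint8))
        ens = self._tiny_ensemble(gm.variant_ids, [2.0])
        st = compute_scores(gm, ens, gm.sample_ids)
        assert st.scores[:, 0] == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_raw_score_linearity(self):
        gm = _gm(np.array([[0, 2], [1, 1], [2, 0], [2, 2]], dtype=np.uint8))
        w = np.array([0.5, -1.0])
        ens = self._tiny_ensemble(gm.variant_ids, w)
        st = compute_scores(gm, ens, gm.sample_ids)
        raw = st.scores[:, 0] * st.ref_sd[0] + st.ref_mean[0]
        expected = gm.dosages.astype(float) @ w
        assert np.allclose(raw, expected)

    def test_missing_variant_raises(self):
        gm = _gm(np.array([[0], [1]], dtype=np.uint8))
        ens = self._tiny_ensemble(["nope"], [1.0])
        with pytest.raises(KeyError):
            compute_scores(gm, ens, gm.sample_ids)

    def test_empty_reference_rejected(self):
        gm = _gm(np.array([[0], [1]], dtype=np.uint8))
        ens = self._tiny_ensemble(gm.variant_ids, [1.0])
        with pytest.raises(ValueError):
            compute_scores(gm, ens, [])
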