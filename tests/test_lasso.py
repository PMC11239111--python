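"""Penalised logistic regression: solver correctness, CV, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest

from pgxprs import lasso
from pgxprs.lasso import PenalizedLogit, roc_auc, soft_threshold
from conftest import make_cohort


def _logistic_data(rng, n=80, p=5, beta=None, icept=0.3):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
    prob = 1 / (1 + np.exp(-(icept + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return X, y


class TestEncoding:
    def test_additive_and_carrier(self):
        cohort = make_cohort({"v": [0, 1, 2]}, covariates={"stent": [1, 0, 1]})
        fm = lasso.encode_features(cohort)
        assert fm.data["v"].tolist() == [0, 1, 2]
        fm2 = lasso.encode_features(cohort, carrier_overrides={"v"})
        assert fm2.data["v"].tolist() == [0, 1, 1]
        assert fm2.column_meta.loc["v", "encoding"] == "carrier"
        assert fm2.column_meta.loc["stent", "kind"] == "covariate"

    def test_missing_dosage_requires_imputation_flag(self):
        cohort = make_cohort({"v": [0.0, np.nan, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            lasso.encode_features(cohort)
        fm = lasso.encode_features(cohort, impute_missing=True)
        assert fm.data["v"].tolist() == [0.0, 1.0, 2.0]
        assert bool(fm.column_meta.loc["v", "imputed"])

    def test_destandardised_coefficients_reproduce_predictions(self, rng):
        X, y = _logistic_data(rng, n=60, p=4,
                              beta=np.array([1.0, -1.0, 0.5, 0.0]))
        Xdf = pd.DataFrame(X, columns=list("abcd")) * [1.0, 10.0, 0.1, 5.0] + 3
        m = PenalizedLogit(y, Xdf, standardize=True)
        res = m.fit(lambdas=[0.01])
        # original-scale params applied to raw X equal standardized-space preds
        eta_orig = res.intercepts[0] + Xdf.to_numpy() @ res.coefs[:, 0]
        eta_std = res.intercepts_std[0] + m.Xs @ res.coefs_std[:, 0]
        np.testing.assert_allclose(eta_orig, eta_std, rtol=1e-10)


class TestSolver:
    def test_lambda_max_gives_null_model(self, rng):
        X, y = _logistic_data(rng, beta=np.array([1.0, 0, 0, 0, -0.5]))
        m = PenalizedLogit(y, X)
        res = m.fit(lambdas=[m.lambda_max, 2 * m.lambda_max])
        assert np.all(res.coefs == 0)
        ybar = y.mean()
        np.testing.assert_allclose(res.intercepts,
                                   np.log(ybar / (1 - ybar)), atol=1e-6)

    def test_lambda_zero_matches_newton_raphson(self, rng):
        """Unpenalised limit against an IRLS/Newton oracle (statsmodels)."""
        import statsmodels.api as sm

        X, y = _logistic_data(rng, n=200, p=4,
                              beta=np.array([1.0, -0.8, 0.0, 0.5]))
        res = PenalizedLogit(y, X).fit(lambdas=[0.0])
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton",
                                                     tol=1e-12)
        np.testing.assert_allclose(res.coefs[:, 0], oracle.params[1:], atol=1e-6)
        np.testing.assert_allclose(res.intercepts[0], oracle.params[0], atol=1e-6)

    def test_orthonormal_gaussian_soft_threshold_closed_form(self, rng):
        """On an orthonormal design with squared-error loss the lasso solution
        is the soft-thresholded OLS estimate, coordinatewise."""
        n, p = 64, 6
        # QR against the intercept column: orthonormal columns with mean 0
        q, _ = np.linalg.qr(np.c_[np.ones(n), rng.normal(size=(n, p))])
        X = q[:, 1:] * np.sqrt(n)  # (1/n) X'X = I, column means 0
        beta_true = np.array([2.0, -1.5, 0.8, 0.0, 0.0, 0.3])
        y = X @ beta_true + rng.normal(0, 0.1, n)
        y = y - y.mean()
        z = X.T @ y / n  # OLS coordinates
        for lam in (0.05, 0.5, 1.0):
            m = PenalizedLogit(y, X, family="gaussian", standardize=False)
            res = m.fit(lambdas=[lam])
            np.testing.assert_allclose(res.coefs[:, 0],
                                       soft_threshold(z, lam), atol=1e-6)

    def test_kkt_conditions_along_path(self, rng):
        X, y = _logistic_data(rng, n=100, p=12,
                              beta=np.r_[np.array([1.5, -1.0, 0.7]), np.zeros(9)])
        res = PenalizedLogit(y, X).fit(n_lambdas=40)
        for lam in res.lambda_path[::5]:
            assert res.check_kkt(lam=lam) < 1e-6

    def test_training_deviance_monotone_in_lambda(self, rng):
        X, y = _logistic_data(rng, n=90, p=8, beta=np.r_[[1.0, -1.0], np.zeros(6)])
        res = PenalizedLogit(y, X).fit(n_lambdas=50)
        dev = res.deviance_path()
        assert np.all(np.diff(dev) <= 1e-7)  # lambda decreasing along path

    def test_constant_column_dropped_with_warning(self, rng):
        X, y = _logistic_data(rng, n=50, p=3)
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            m = PenalizedLogit(y, X)
        assert len(m.feature_names) == 2

    def test_non_binary_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="binomial"):
            PenalizedLogit(np.array([0.0, 0.5, 1.0]), rng.normal(size=(3, 2)))


class TestCrossValidation:
    def test_pure_noise_selects_sparse_or_empty_model(self):
        """On pure noise the 1-SE rule returns the empty model in >= 80% of
        seeds; lambda_min occasionally keeps a few spurious features (its
        known optimism) but the median selected size is 0."""
        empty_1se = 0
        nnz_min = []
        n_seeds = 15
        for s in range(n_seeds):
            rng = np.random.default_rng(300 + s)
            X = rng.normal(size=(69, 20))
            y = rng.binomial(1, 0.5, 69).astype(float)
            res = PenalizedLogit(y, X).fit_cv(k=3, seed=s)
            empty_1se += len(res.nonzero_features(res.lambda_1se)) == 0
            nnz_min.append(len(res.nonzero_features(res.lambda_min)))
        assert empty_1se >= 0.8 * n_seeds - 1  # binomial slack at 15 seeds
        assert np.median(nnz_min) <= 2

    def test_planted_signal_recovered_at_lambda_min(self):
        rng = np.random.default_rng(9)
        n, p = 500, 20
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        ct = 107 - 25 * X[:, :3].sum(axis=1) + rng.normal(0, 20, n)
        y = (ct < 106).astype(float)
        res = PenalizedLogit(y, X).fit_cv(k=3, seed=0)
        assert {"x0", "x1", "x2"} <= set(res.nonzero_features())

    def test_leave_one_out_boundary(self, rng):
        X, y = _logistic_data(rng, n=6, p=2)
        while len(np.unique(y)) < 2:
            X, y = _logistic_data(rng, n=6, p=2)
        res = PenalizedLogit(y, X).fit_cv(k=6, seed=0)
        assert np.all(np.isfinite(res.cv_mean))
        assert res.selected_lambda is not None

    def test_lambda_1se_not_smaller_than_lambda_min(self, rng):
        X, y = _logistic_data(rng, n=80, p=10, beta=np.r_[[1.2], np.zeros(9)])
        res = PenalizedLogit(y, X).fit_cv(k=3, seed=1)
        assert res.lambda_1se >= res.lambda_min
        assert res.summary()  # renders without error

    def test_mse_loss_option(self, rng):
        X, y = _logistic_data(rng, n=60, p=5, beta=np.r_[[1.0], np.zeros(4)])
        res = PenalizedLogit(y, X).fit_cv(k=3, loss="mse", seed=0)
        assert res.cv_loss == "mse"
        assert np.all(res.cv_mean <= 1.0)


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.auc == 1.0
        assert np.all(np.diff(curve.tpr) >= 0) and np.all(np.diff(curve.fpr) >= 0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(23)
        s = rng.normal(size=2000)
        y = rng.binomial(1, 0.5, 2000)
        assert roc_auc(s, y).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_concordant_pair_fraction_brute_force(self, rng):
        """AUC == (concordant + 0.5 * tied) / (n1 * n0), O(n^2) count."""
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.binomial(1, 0.5, n)
            if labels.sum() in (0, n):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            conc = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
            expect = conc / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(expect, abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.normal(size=300)
        y = rng.binomial(1, 0.4, 300)
        assert roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_training_auc_with_informative_features_small_cohort(self, seed):
        """Study-scale qualitative check: 7 strong variants (-25 s/allele)
        among 30, n=69, ~80% case fraction -> training AUC above 0.9."""
        from pgxprs import simulate as sim

        specs = tuple(sim.VariantSpec(f"v{i}", 0.35, -25.0 if i < 7 else 0.0)
                      for i in range(30))
        cfg = sim.calibrate_baseline(
            sim.SimulationConfig(n_subjects=69, variant_specs=specs,
                                 ct_noise_sd=20.0, seed=seed), 0.8)
        cohort = sim.simulate_cohort(cfg)
        fm = lasso.encode_features(cohort)
        res = PenalizedLogit(cohort.htpr.to_numpy(), fm.data).fit_cv(k=3, seed=seed)
        assert res.roc().auc > 0.9
        # out-of-fold AUC is computable and within bounds
        assert 0.0 <= res.cv_roc().auc <= 1.0
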