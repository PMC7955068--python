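"""Phenotype prediction: GMM binarization, site hold-out, sparse group
lasso, nested CV, evaluation metrics, and permutation inference."""

import logging

import numpy as np
import pandas as pd
import pytest

from hifquant.predict import (
    auprc,
    auroc,
    evaluate,
    fit_sgl_logistic,
    gmm_binarize,
    lambda_grid,
    lambda_max,
    nested_cv_ensemble,
    permutation_beta_inference,
    site_holdout_split,
)


class TestGmmBinarize:
    def test_symmetric_mixture_threshold_at_midpoint(self, rng):
        x = np.r_[rng.normal(0, 1, 1000), rng.normal(6, 1, 1000)]
        model, labels = gmm_binarize(x, seed=0)
        assert model.threshold == pytest.approx(3.0, abs=0.15)
        assert labels.sum() == (x >= model.threshold).sum()

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            gmm_binarize(np.full(30, 2.0))

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError):
            gmm_binarize(rng.normal(size=10))

    def test_unequal_variance_threshold_matches_analytic_root(self, rng):
        x = np.r_[rng.normal(0, 1, 4000), rng.normal(6, 2, 4000)]
        model, _ = gmm_binarize(x, seed=1)
        # solve 0.5·N(t|0,1) = 0.5·N(t|6,4): quadratic in t via log-density
        s1, s2, mu2 = 1.0, 4.0, 6.0
        a = 0.5 * (1 / s1 - 1 / s2)
        b = mu2 / s2
        c = -mu2 ** 2 / (2 * s2) - 0.5 * np.log(s2 / s1)
        roots = np.roots([a, b, c])
        root = [t for t in roots if 0 < t < mu2][0]
        assert model.threshold == pytest.approx(root, abs=0.2)


class TestSiteHoldout:
    @staticmethod
    def _meta(n_sites, per_site):
        rows = []
        for s in range(n_sites):
            for i in range(per_site):
                rows.append({"patient_id": f"P{s}_{i}", "site_id": f"site{s}"})
        return pd.DataFrame(rows)

    def test_fraction_in_range_and_site_disjoint(self):
        meta = self._meta(10, 10)
        for seed in range(5):
            train, hold = site_holdout_split(meta, seed=seed)
            assert 0.2 <= len(hold) / 100 <= 0.3
            tr_sites = set(meta.set_index("patient_id").loc[train, "site_id"])
            ho_sites = set(meta.set_index("patient_id").loc[hold, "site_id"])
            assert not tr_sites & ho_sites
            assert sorted(train + hold) == sorted(meta["patient_id"])

    def test_two_sites_warning_path(self, caplog):
        meta = self._meta(2, 10)
        with caplog.at_level(logging.WARNING, logger="hifquant.predict"):
            train, hold = site_holdout_split(meta, seed=0)
        assert "hold-out range" in caplog.text
        assert len(hold) > 0 and len(train) > 0

    def test_deterministic_per_seed(self):
        meta = self._meta(8, 7)
        assert site_holdout_split(meta, seed=4) == site_holdout_split(meta, seed=4)


def _toy_logistic(rng, n=300, p=6):
    X = rng.normal(size=(n, p))
    beta = np.array([1.5, -1.0, 0.8, 0.0, 0.0, 0.0])[:p]
    logits = X @ beta - 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
    return X, y


class TestSgl:
    def test_lambda_zero_matches_unpenalized_logistic(self, rng):
        from sklearn.linear_model import LogisticRegression
        X, y = _toy_logistic(rng)
        groups = np.array([0, 0, 1, 1, 2, 2])
        m = fit_sgl_logistic(X, y, groups, lam=0.0, tol=1e-8, max_iter=50000)
        ref = LogisticRegression(C=np.inf, tol=1e-10, max_iter=10000).fit(X, y)
        np.testing.assert_allclose(m.beta, ref.coef_.ravel(), atol=1e-4)
        assert m.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_lambda_max_zeroes_all_coefficients(self, rng):
        X, y = _toy_logistic(rng)
        groups = np.array([0, 0, 1, 1, 2, 2])
        lmax = lambda_max(X, y, groups)
        m = fit_sgl_logistic(X, y, groups, lam=lmax * 1.0001)
        assert np.all(m.beta == 0.0)
        m2 = fit_sgl_logistic(X, y, groups, lam=lmax * 0.5)
        assert np.any(m2.beta != 0.0)

    def test_support_recovery_single_active_group(self, rng):
        n, p = 400, 30
        groups = np.repeat(np.arange(6), 5)
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[groups == 2] = np.array([1.0, -0.8, 0.9, 0.7, -1.1])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        lmax = lambda_max(X, y, groups)
        grid = lambda_grid(lmax)
        supports = []
        beta_ws, b0_ws = None, None
        for lam in grid:
            m = fit_sgl_logistic(X, y, groups, lam=lam,
                                 beta0=beta_ws, intercept0=b0_ws)
            beta_ws, b0_ws = m.beta, m.intercept
            supports.append(set(groups[m.beta != 0]))
        # the true group enters the path first...
        first_active = next(s for s in supports if s)
        assert first_active == {2}
        # ...and is the sole active group over a stretch of the mid-path
        exact = sum(s == {2} for s in supports[1:-1])
        assert exact >= 3

    def test_non_binary_labels_rejected(self, rng):
        X, y = _toy_logistic(rng, n=50)
        with pytest.raises(ValueError):
            fit_sgl_logistic(X, y + 0.5, np.zeros(6, int), lam=0.1)
        with pytest.raises(ValueError):
            fit_sgl_logistic(X, y, np.zeros(6, int), lam=-1.0)


class TestNestedCv:
    def test_ensemble_beta_is_mean_of_folds(self, rng):
        X, y = _toy_logistic(rng, n=150)
        groups = np.array([0, 0, 1, 1, 2, 2])
        ens = nested_cv_ensemble(X, y, groups, seed=1, n_lambda=8)
        np.testing.assert_allclose(
            ens.beta, np.mean([m.beta for m in ens.models], axis=0))
        probs = ens.predict_proba(X)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_strong_signal_recovers_high_auroc(self, rng):
        X, y = _toy_logistic(rng, n=400)
        groups = np.array([0, 0, 1, 1, 2, 2])
        Xh, yh = _toy_logistic(rng, n=400)
        ens = nested_cv_ensemble(X, y, groups, seed=2, n_lambda=10)
        assert auroc(ens.predict_proba(Xh), yh) > 0.8

    @pytest.mark.parametrize("seed", range(5))
    def test_permuted_labels_give_chance_auroc(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 250, 20
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, n).astype(float)
        groups = np.repeat(np.arange(5), 4)
        ens = nested_cv_ensemble(X, y, groups, seed=seed, n_lambda=8)
        Xh = rng.normal(size=(400, p))
        yh = rng.integers(0, 2, 400).astype(float)
        assert 0.35 <= auroc(ens.predict_proba(Xh), yh) <= 0.65


class TestEvaluate:
    def test_perfect_separation(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        rep = evaluate(probs, labels, n_boot=200, seed=0)
        assert rep.auroc == 1.0 and rep.auprc == 1.0
        assert rep.p_auroc == 0.0

    def test_hand_counted_toy(self):
        # 3 of 4 (pos, neg) pairs concordant
        assert auroc(np.array([0.9, 0.8, 0.3, 0.2]),
                     np.array([1, 0, 1, 0])) == pytest.approx(0.75)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        a = auroc(scores, labels)
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(a)

    def test_auprc_matches_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        assert auprc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_ci_brackets_point_estimate(self, rng):
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        rep = evaluate(scores, labels, n_boot=300, seed=3)
        assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]


class TestPermutationInference:
    def test_p_floor_and_planted_feature(self, rng):
        # strong planted feature: no null |beta| should exceed it
        n, p = 120, 8
        groups = np.repeat(np.arange(4), 2)
        X = rng.normal(size=(n, p))
        logits = 2.5 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        kw = dict(n_lambda=6, n_inner=3, tol=1e-3)
        ens = nested_cv_ensemble(X, y, groups, seed=0, **kw)
        assert abs(ens.beta[0]) > 0
        B = 99
        out = permutation_beta_inference(X, y, groups, ens, B=B, seed=1, **kw)
        p_feat = out["p_feature"]
        assert np.all(p_feat >= 1 / (B + 1) - 1e-12)
        assert p_feat[0] == pytest.approx(1 / (B + 1))

    def test_small_b_warns(self, rng):
        n, p = 60, 4
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, n).astype(float)
        y[:6] = [0, 1] * 3
        groups = np.array([0, 0, 1, 1])
        kw = dict(n_lambda=4, n_inner=3, tol=1e-2)
        ens = nested_cv_ensemble(X, y, groups, seed=3, **kw)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_beta_inference(X, y, groups, ens, B=5, seed=4, **kw)
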