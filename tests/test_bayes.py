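"""Random projection, the logistic Gibbs sampler, pseudo-R^2 and WAIC."""

import math

import numpy as np
import pytest

from fluencygraph import (ModelSpec, canonical_specs, compare_models,
                          fit_bayes_logistic, pseudo_r2, random_project, waic,
                          waic_from_loglik)

FAST = (300, 300, 1)


def logistic_data(rng, n, p, beta=None, intercept=0.0):
    X = rng.standard_normal((n, p))
    eta = intercept + (X @ beta if beta is not None else np.zeros(n))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y


class TestRandomProjection:
    def test_zero_row_maps_to_zero(self):
        X = np.zeros((1, 64))
        assert np.all(random_project(X, 8, seed=0) == 0)

    def test_deterministic(self, rng):
        X = rng.standard_normal((5, 64))
        assert np.array_equal(random_project(X, 8, seed=3),
                              random_project(X, 8, seed=3))

    def test_dimension_constraints(self, rng):
        X = rng.standard_normal((5, 16))
        with pytest.raises(ValueError):
            random_project(X, 16, seed=0)
        with pytest.raises(ValueError):
            random_project(X, 1, seed=0)

    def test_distance_preservation(self, rng):
        X = rng.standard_normal((100, 1024))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        Z = random_project(X, 256, seed=1)
        iu = np.triu_indices(100, 1)
        d0 = ((X[iu[0]] - X[iu[1]]) ** 2).sum(axis=1)
        d1 = ((Z[iu[0]] - Z[iu[1]]) ** 2).sum(axis=1)
        assert np.mean(np.abs(d1 / d0 - 1.0) < 0.3) >= 0.99


class TestGibbsSampler:
    def test_reproducible_under_seed(self, rng):
        X, y = logistic_data(rng, 80, 3, np.array([1.0, 0.0, -1.0]))
        spec = ModelSpec("m", ("a", "b", "c"), "ridge", FAST, seed=9)
        a = fit_bayes_logistic(X, y, spec)
        b = fit_bayes_logistic(X, y, spec)
        assert np.array_equal(a.draws, b.draws)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValueError):
            fit_bayes_logistic(X, np.ones(20),
                               ModelSpec("m", ("a", "b"), "ridge", FAST))

    def test_intercept_only_balanced_data(self, rng):
        y = np.tile([0.0, 1.0], 100)
        fit = fit_bayes_logistic(np.empty((200, 0)), y,
                                 ModelSpec("m", (), "ridge", FAST, seed=2))
        assert abs(fit.draws[:, 0].mean()) < 0.25

    def test_strong_predictor_recovered(self, rng):
        X, y = logistic_data(rng, 500, 10,
                             np.array([3.0] + [0.0] * 9))
        fit = fit_bayes_logistic(
            X, y, ModelSpec("m", tuple("abcdefghij"), "horseshoe", FAST, seed=3))
        bm = np.abs(fit.coef_posterior_mean())
        assert fit.coef_posterior_mean()[0] > 0
        assert np.argmax(bm) == 0

    def test_null_coverage_calibrated(self):
        """95% intervals cover zero for ~95% of null coefficients."""
        rng = np.random.default_rng(42)
        covered = total = 0
        for rep in range(20):
            X, y = logistic_data(rng, 150, 6)
            fit = fit_bayes_logistic(
                X, y, ModelSpec("m", tuple("abcdef"), "ridge", FAST, seed=rep))
            lo = np.percentile(fit.draws[:, 1:], 2.5, axis=0)
            hi = np.percentile(fit.draws[:, 1:], 97.5, axis=0)
            covered += int(((lo <= 0) & (0 <= hi)).sum())
            total += 6
        assert 0.88 <= covered / total <= 1.0

    def test_horseshoe_shrinks_more_than_ridge(self, rng):
        X, y = logistic_data(rng, 300, 50,
                             np.array([3.0, -3.0] + [0.0] * 48))
        fits = {}
        for prior in ("ridge", "horseshoe"):
            fits[prior] = fit_bayes_logistic(
                X, y, ModelSpec("m", tuple(f"x{i}" for i in range(50)),
                                prior, FAST, seed=5))
        inactive = slice(2, None)
        hs = np.median(np.abs(fits["horseshoe"].coef_posterior_mean()[inactive]))
        rd = np.median(np.abs(fits["ridge"].coef_posterior_mean()[inactive]))
        assert hs < rd


class TestFitIndices:
    def test_pseudo_r2_intercept_only_is_zero(self, rng):
        y = np.tile([0.0, 1.0], 20)
        fit = fit_bayes_logistic(np.empty((40, 0)), y,
                                 ModelSpec("m", (), "ridge", FAST, seed=0))
        assert pseudo_r2(fit, np.empty((40, 0)), y) == 0.0

    def test_pseudo_r2_approaches_one_for_separable_data(self, rng):
        X = np.concatenate([np.full(50, -3.0), np.full(50, 3.0)])[:, None]
        y = (X[:, 0] > 0).astype(float)
        fit = fit_bayes_logistic(X, y, ModelSpec("m", ("x",), "ridge",
                                                 FAST, seed=1))
        assert 0.7 < fit.pseudo_r2 <= 1.0

    def test_pseudo_r2_matches_direct_computation(self, rng):
        X = np.array([[-2.0], [-1.0], [-0.5], [0.5], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        fit = fit_bayes_logistic(X, y, ModelSpec("m", ("x",), "ridge",
                                                 FAST, seed=4))
        # independent direct computation from the stored draws
        Xz = (X - X.mean(0)) / X.std(0)
        lls = []
        for b0, b1 in fit.draws:
            eta = b0 + b1 * Xz[:, 0]
            prob = 1.0 / (1.0 + np.exp(-eta))
            lls.append(sum(math.log(p if yi else 1 - p)
                           for p, yi in zip(prob, y)))
        ll0 = 6 * (0.5 * math.log(0.5) + 0.5 * math.log(0.5))
        expected = 1.0 - np.mean(lls) / ll0
        assert fit.pseudo_r2 == pytest.approx(expected, abs=1e-10)

    def test_pseudo_r2_invariant_to_column_rescaling(self, rng):
        X, y = logistic_data(rng, 100, 3, np.array([1.0, -1.0, 0.5]))
        spec = ModelSpec("m", ("a", "b", "c"), "ridge", FAST, seed=6)
        a = fit_bayes_logistic(X, y, spec)
        b = fit_bayes_logistic(X * np.array([10.0, 0.2, 5.0]) + 7.0, y, spec)
        assert a.pseudo_r2 == pytest.approx(b.pseudo_r2, abs=1e-12)


class TestWaic:
    def test_identical_draws_zero_penalty(self):
        ll = np.log(np.array([[0.7, 0.4]] * 3))
        expected = -2.0 * (math.log(0.7) + math.log(0.4))
        assert waic_from_loglik(ll) == pytest.approx(expected, abs=1e-12)

    def test_three_draw_toy_table(self):
        probs = np.array([[0.9, 0.8], [0.7, 0.6], [0.5, 0.4]])
        ll = np.log(probs)
        # independent hand computation of lppd and p_waic
        lppd = sum(math.log(np.mean(probs[:, i])) for i in range(2))
        p_waic = sum(np.var(ll[:, i], ddof=1) for i in range(2))
        assert waic_from_loglik(ll) == pytest.approx(
            -2.0 * (lppd - p_waic), abs=1e-12)
        assert waic_from_loglik(ll) == pytest.approx(2.151495006721884, abs=1e-9)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            waic_from_loglik(np.array([[math.log(0.5)]]))

    def test_fit_waic_consistent_with_table(self, rng):
        X, y = logistic_data(rng, 60, 2, np.array([1.0, -0.5]))
        fit = fit_bayes_logistic(X, y, ModelSpec("m", ("a", "b"), "ridge",
                                                 FAST, seed=8))
        eta = fit.linear_predictor(X)
        prob = 1.0 / (1.0 + np.exp(-eta))
        ll = np.where(y[None, :] > 0.5, np.log(prob), np.log(1 - prob))
        assert waic(fit, X, y) == pytest.approx(waic_from_loglik(ll), rel=1e-9)


class TestCompareModels:
    def test_identical_seed_identical_table(self, rng):
        import pandas as pd
        feats = pd.DataFrame({
            "age": rng.normal(50, 10, 60), "nart": rng.normal(105, 10, 60),
            "fluency": rng.normal(15, 4, 60), "pct_rulebreak": rng.random(60),
            "pct_lowfreq": rng.random(60), "n_switches": rng.integers(0, 10, 60),
            "relative_switches": rng.random(60) * 100,
            "mean_cluster_size": rng.random(60),
        })
        y = (rng.random(60) < 0.4).astype(float)
        E = rng.standard_normal((60, 128))
        E /= np.linalg.norm(E, axis=1, keepdims=True)
        kw = dict(embeddings=E, seed=3, k_project=8, mcmc=FAST)
        a = compare_models(feats, y, **kw)
        b = compare_models(feats, y, **kw)
        assert a.equals(b)
        assert list(a.model) == ["baseline", "errors", "full"]

    def test_canonical_nesting_and_priors(self):
        specs = canonical_specs()
        names = {s.name: s for s in specs}
        assert set(names["baseline"].features) < set(names["errors"].features)
        assert names["baseline"].prior == names["errors"].prior == "ridge"
        assert names["full"].prior == "horseshoe"
        assert names["full"].use_embeddings

    def test_no_signal_pseudo_r2_near_zero(self, rng):
        import pandas as pd
        n = 150
        feats = pd.DataFrame({k: rng.standard_normal(n) for k in (
            "age", "nart", "fluency", "pct_rulebreak", "pct_lowfreq",
            "n_switches", "relative_switches", "mean_cluster_size")})
        y = (rng.random(n) < 0.5).astype(float)
        vals = []
        for seed in range(3):
            tab = compare_models(feats, y, specs=canonical_specs(FAST, seed)[:2],
                                 seed=seed, mcmc=FAST)
            vals.extend(tab.pseudo_r2)
        assert np.median(vals) <= 0.05
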