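"""Ridge LOOCV machinery against closed-form and brute-force oracles."""

from collections import Counter

import numpy as np
import pytest
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import norm

from dyspredict.core import round_half_up
from dyspredict.predict import (
    CvResult,
    RidgeConfig,
    aggregate_rankings,
    evaluate_feature,
    fisher_compare,
    loo_predictions,
    loocv_evaluate,
    permutation_test,
    rank_pcs,
    ridge_fit_predict,
    select_hyperparams,
    skill_r2,
)

GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


class TestRidge:
    def test_huge_lambda_predicts_training_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (20, 5))
        y = rng.normal(3, 1, 20)
        _, _, preds = ridge_fit_predict(X, y, 1e12, X)
        np.testing.assert_allclose(preds, y.mean(), atol=1e-6)

    def test_zero_lambda_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 4))
        y = rng.normal(0, 1, 30)
        coef, intercept, _ = ridge_fit_predict(X, y, 0.0)
        A = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(coef, beta[1:], atol=1e-9)
        assert intercept == pytest.approx(beta[0], abs=1e-9)

    @pytest.mark.parametrize("lam", [0.01, 1.0, 50.0])
    def test_normal_equations_oracle(self, lam):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 5))
        y = rng.normal(0, 1, 20)
        coef, intercept, _ = ridge_fit_predict(X, y, lam)
        Xc = X - X.mean(axis=0)
        expected = np.linalg.inv(Xc.T @ Xc + lam * np.eye(5)) @ Xc.T @ (y - y.mean())
        np.testing.assert_allclose(coef, expected, atol=1e-9)

    def test_training_error_nondecreasing_in_lambda(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (25, 6))
        y = X[:, 0] + rng.normal(0, 0.3, 25)
        errs = []
        for lam in GRID:
            coef, b0, preds = ridge_fit_predict(X, y, lam, X)
            errs.append(np.mean((y - preds) ** 2))
        assert np.all(np.diff(errs) >= -1e-12)


class TestLooIdentity:
    def _naive_loo(self, X, y, lam):
        n = len(y)
        preds = np.empty(n)
        for i in range(n):
            tr = np.arange(n) != i
            _, _, p = ridge_fit_predict(X[tr], y[tr], lam, X[i][None])
            preds[i] = p[0]
        return preds

    @pytest.mark.parametrize("lam", [0.001, 0.5, 20.0])
    def test_matches_per_fold_refitting(self, lam):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (18, 6))
        y = rng.normal(0, 1, 18)
        np.testing.assert_allclose(
            loo_predictions(X, y, lam), self._naive_loo(X, y, lam), atol=1e-10
        )

    def test_matrix_y_columns_independent(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (15, 4))
        Y = rng.normal(0, 1, (15, 7))
        batch = loo_predictions(X, Y, 0.3)
        for b in range(7):
            np.testing.assert_allclose(batch[:, b], loo_predictions(X, Y[:, b], 0.3))


class TestSkillR2:
    def test_anticorrelated_predictions_score_zero(self):
        y = np.arange(10.0)
        assert skill_r2(-y, y) == 0.0
        assert skill_r2(y * 2 + 1, y) == pytest.approx(1.0)

    def test_constant_predictions_score_zero(self):
        assert skill_r2(np.full(8, 3.0), np.arange(8.0)) == 0.0


class TestRanking:
    def test_exact_match_ranked_first(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (20, 5))
        perm = rank_pcs(X, X[:, 3])
        assert perm[0] == 3

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (25, 8))
        y = rng.normal(0, 1, 25)
        perm = rank_pcs(X, y)
        r = [abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(8)]
        expected = sorted(range(8), key=lambda j: (-r[j], j))
        np.testing.assert_array_equal(perm, expected)

    def test_ascending_flag_reverses_preference(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (20, 4))
        y = X[:, 1] + rng.normal(0, 0.1, 20)
        assert rank_pcs(X, y)[0] == 1
        assert rank_pcs(X, y, ascending=True)[-1] == 1

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_pcs(np.zeros((5, 3)), np.ones(5))


class TestAggregate:
    def test_identical_rankings(self):
        r = np.array([2, 0, 1])
        np.testing.assert_array_equal(aggregate_rankings([r, r, r]), r)

    def test_reversed_pair_ties_to_index_order(self):
        out = aggregate_rankings([np.array([0, 1]), np.array([1, 0])])
        np.testing.assert_array_equal(out, [0, 1])

    def test_mean_rank_oracle(self):
        rng = np.random.default_rng(9)
        folds = [rng.permutation(6) for _ in range(10)]
        out = aggregate_rankings(folds)
        mean_rank = np.zeros(6)
        for perm in folds:
            for pos, pc in enumerate(perm):
                mean_rank[pc] += pos / 10
        expected = sorted(range(6), key=lambda j: (mean_rank[j], j))
        np.testing.assert_array_equal(out, expected)

    def test_inconsistent_sets_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rankings([np.array([0, 1]), np.array([0, 2])])


class TestSelect:
    def _naive(self, X, y, ranking, grid=GRID):
        """Independent double-loop reimplementation of the selection rule."""
        Xr = X[:, ranking]
        n, m = Xr.shape
        ns, lams = [], []
        for i in range(n):
            tr = np.arange(n) != i
            best = (-np.inf, 1, grid[0])
            for k in range(1, m + 1):
                for lam in grid:
                    pred = loo_predictions(Xr[tr][:, :k], y[tr], lam)
                    r2 = skill_r2(pred, y[tr])
                    if r2 > best[0]:
                        best = (r2, k, lam)
            ns.append(best[1])
            lams.append(best[2])
        n_star = max(1, round_half_up(float(np.mean(ns))))
        c = Counter(lams)
        top = max(c.values())
        return n_star, min(l for l, v in c.items() if v == top)

    def test_noise_free_signal_in_first_three_ranked_pcs(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (24, 8))
        ranking = np.arange(8)
        y = X[:, 0] - 2 * X[:, 1] + 0.5 * X[:, 2]
        n_star, lam_star = select_hyperparams(X, y, ranking, RidgeConfig())
        assert n_star == 3
        assert lam_star <= 0.01

    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (10, 1))
        y = rng.normal(0, 1, 10)
        cfg = RidgeConfig(fixed_lambda=0.01)
        assert select_hyperparams(X, y, np.array([0]), cfg) == (1, 0.01)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (12, 5))
        y = X[:, 2] * 0.7 + rng.normal(0, 1, 12)
        ranking = rank_pcs(X, y)
        assert select_hyperparams(X, y, ranking, RidgeConfig()) == self._naive(
            X, y, ranking
        )

    def test_pure_noise_is_deterministic(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (15, 6))
        y = rng.normal(0, 1, 15)
        ranking = rank_pcs(X, y)
        a = select_hyperparams(X, y, ranking, RidgeConfig())
        b = select_hyperparams(X, y, ranking, RidgeConfig())
        assert a == b


class TestLoocvEvaluate:
    def test_perfect_signal_limit(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (30, 6))
        y = X[:, 0] + 2 * X[:, 1]
        res = loocv_evaluate(X, y, np.arange(6), 2, 0.001)
        assert res.r2 >= 0.999
        assert res.mse <= 1e-4 * np.var(y)

    def test_matches_two_pass_reimplementation(self):
        rng = np.random.default_rng(14)
        X = rng.normal(0, 1, (30, 8))
        y = X[:, 1] + rng.normal(0, 0.5, 30)
        ranking = rank_pcs(X, y)
        res = loocv_evaluate(X, y, ranking, 3, 0.1)
        cols = ranking[:3]
        preds = np.empty(30)
        for i in range(30):
            tr = np.arange(30) != i
            _, _, p = ridge_fit_predict(X[tr][:, cols], y[tr], 0.1, X[i][None, cols])
            preds[i] = p[0]
        r = np.corrcoef(preds, y)[0, 1]
        exp_r2 = r**2 if r > 0 else 0.0
        assert res.r2 == pytest.approx(exp_r2, abs=1e-10)
        assert res.mse == pytest.approx(np.mean((y - preds) ** 2), abs=1e-10)

    def test_tev_bookkeeping(self):
        rng = np.random.default_rng(15)
        X = rng.normal(0, 1, (20, 4))
        y = X[:, 0] + rng.normal(0, 0.2, 20)
        evr = np.array([0.5, 0.3, 0.15, 0.05])
        res = loocv_evaluate(X, y, np.array([1, 0, 2, 3]), 2, 0.01,
                             explained_variance_ratio=evr)
        assert res.total_explained_variance == pytest.approx(100 * (0.3 + 0.5))

    def test_n_star_exceeding_pcs_rejected(self):
        rng = np.random.default_rng(16)
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError):
            loocv_evaluate(X, rng.normal(0, 1, 10), np.arange(3), 4, 0.1)


class TestPermutation:
    def test_perfect_signal_p_zero(self):
        rng = np.random.default_rng(17)
        X = rng.normal(0, 1, (25, 4))
        y = X[:, 0]
        ranking = rank_pcs(X, y)
        p, perm = permutation_test(X, y, ranking, 1, 0.001, B=50, seed=0)
        assert p == 0.0
        assert perm.shape == (50,)

    def test_single_permutation_extremes(self):
        rng = np.random.default_rng(18)
        X = rng.normal(0, 1, (12, 3))
        y = X[:, 0]
        ranking = rank_pcs(X, y)
        p, _ = permutation_test(X, y, ranking, 1, 0.001, B=1, seed=3)
        assert p in (0.0, 1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(19)
        X = rng.normal(0, 1, (20, 5))
        y = rng.normal(0, 1, 20)
        ranking = rank_pcs(X, y)
        a = permutation_test(X, y, ranking, 2, 0.1, B=60, seed=5)
        b = permutation_test(X, y, ranking, 2, 0.1, B=60, seed=5)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_add_one_estimator(self):
        rng = np.random.default_rng(20)
        X = rng.normal(0, 1, (15, 3))
        y = X[:, 0]
        ranking = rank_pcs(X, y)
        p, _ = permutation_test(X, y, ranking, 1, 0.001, B=19, seed=1,
                                estimator="add_one")
        assert p == pytest.approx(1 / 20)

    def test_fixed_refit_mode_matches_vectorized_convention(self):
        """refit='none' keeps ranking and hyperparameters fixed."""
        rng = np.random.default_rng(21)
        X = rng.normal(0, 1, (20, 4))
        y = rng.normal(0, 1, 20)
        ranking = rank_pcs(X, y)
        p, perm = permutation_test(X, y, ranking, 2, 1.0, B=100, seed=2, refit="none")
        # manual recomputation of a couple of permutations
        prng = np.random.default_rng(2)
        cols = ranking[:2]
        for b in range(3):
            yp = y[prng.permutation(20)]
            r2 = skill_r2(loo_predictions(X[:, cols], yp, 1.0), yp)
            assert perm[b] == pytest.approx(r2, abs=1e-12)


class TestFisher:
    def _cv(self, r2, n=40):
        return CvResult("f", "s", r2, r2, 0.1, 1, 50.0, 0.01, n)

    def test_self_comparison_p_one(self):
        a = self._cv(0.8)
        assert fisher_compare(a, a).p_value == pytest.approx(1.0)

    def test_zero_vs_zero_p_one(self):
        assert fisher_compare(self._cv(0.0), self._cv(0.0)).p_value == pytest.approx(1.0)

    def test_direct_formula_oracle(self):
        a, b = self._cv(0.94, 340), self._cv(0.82, 340)
        out = fisher_compare(a, b)
        za, zb = np.arctanh(np.sqrt(0.94)), np.arctanh(np.sqrt(0.82))
        se = np.sqrt(2 / (340 - 3))
        expected = 2 * (1 - norm.cdf(abs(za - zb) / se))
        assert out.p_value == pytest.approx(expected, abs=1e-12)

    def test_confidence_intervals_on_r2_scale(self):
        out = fisher_compare(self._cv(0.6), self._cv(0.3))
        for lo, hi in (out.ci_r2_a, out.ci_r2_b):
            assert 0.0 <= lo < hi <= 1.0
        assert out.ci_r2_a[0] < 0.6 < out.ci_r2_a[1]

    def test_perfect_model_sentinel(self):
        out = fisher_compare(self._cv(1.0), self._cv(0.5))
        assert np.isinf(out.z_a)
        assert out.p_value == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(self._cv(0.5, 3), self._cv(0.5, 40))


def honest_eval_oracle(X, y, grid=GRID):
    """Independent numpy reimplementation of the fold-safe nested evaluation."""

    def corr_rank(Xs, ys):
        xc = Xs - Xs.mean(0)
        yc = ys - ys.mean()
        dn = np.sqrt((xc**2).sum(0) * (yc @ yc))
        r = np.where(dn > 0, xc.T @ yc / np.where(dn > 0, dn, 1), 0)
        return np.argsort(-np.abs(r), kind="stable")

    def prefix_preds(Xtr, ytr, xnew, lam):
        rk = corr_rank(Xtr, ytr)
        n = Xtr.shape[0]
        Xa = np.column_stack([np.ones(n), Xtr[:, rk]])
        xa = np.concatenate([[1.0], xnew[rk]])
        pen = np.concatenate([[0.0], np.full(len(rk), lam)])
        L = cholesky(Xa.T @ Xa + np.diag(pen), lower=True)
        u = solve_triangular(L, Xa.T @ ytr, lower=True)
        z = solve_triangular(L, xa, lower=True)
        return np.cumsum(z * u)[1:]

    n, m = X.shape
    preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        Xt, yt = X[tr], y[tr]
        ntr = n - 1
        allp = np.empty((len(grid), m, ntr))
        for f in range(ntr):
            itr = np.arange(ntr) != f
            for li, lam in enumerate(grid):
                allp[li, :, f] = prefix_preds(Xt[itr], yt[itr], Xt[f], lam)
        err2 = (allp - yt[None, None, :]) ** 2
        mse = err2.mean(axis=2)
        li0, k0 = np.unravel_index(np.argmin(mse), mse.shape)
        sd = err2[li0, k0].std()
        thresh = mse[li0, k0] + sd / np.sqrt(ntr)
        chosen = None
        for k in range(m):
            for li in range(len(grid)):
                if mse[li, k] <= thresh:
                    chosen = (k, li)
                    break
            if chosen:
                break
        k, li = chosen
        preds[i] = prefix_preds(Xt, yt, X[i], grid[li])[k]
    return preds


class TestFoldSafeEvaluation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kernel_matches_numpy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (14, 6)) * np.linspace(2, 0.5, 6)
        y = X[:, 0] + rng.normal(0, 0.8, 14)
        res = evaluate_feature(X, y, RidgeConfig())
        oracle_preds = honest_eval_oracle(X, y)
        np.testing.assert_allclose(res.predicted, oracle_preds, atol=1e-8)
        assert res.r2 == pytest.approx(skill_r2(oracle_preds, y), abs=1e-10)

    def test_no_information_leak_from_held_out_score(self):
        """Changing patient i's score must not change the *model* that
        predicts patient i when its feature row is unchanged... the honest
        prediction of i depends on others' scores only."""
        rng = np.random.default_rng(30)
        X = rng.normal(0, 1, (12, 4))
        y = X[:, 0] + rng.normal(0, 0.5, 12)
        res1 = evaluate_feature(X, y, RidgeConfig())
        y2 = y.copy()
        y2[5] += 100.0
        res2 = evaluate_feature(X, y2, RidgeConfig())
        assert res2.predicted[5] == pytest.approx(res1.predicted[5], rel=1e-9)

    def test_global_variant_reproduces_spec_composition(self):
        rng = np.random.default_rng(31)
        X = rng.normal(0, 1, (16, 5))
        y = X[:, 1] + rng.normal(0, 0.5, 16)
        res = evaluate_feature(X, y, RidgeConfig(), fold_safe=False)
        folds = [rank_pcs(X[np.arange(16) != i], y[np.arange(16) != i]) for i in range(16)]
        ranking = aggregate_rankings(folds)
        n_star, lam_star = select_hyperparams(X, y, ranking, RidgeConfig())
        expected = loocv_evaluate(X, y, ranking, n_star, lam_star)
        assert res.r2 == pytest.approx(expected.r2, abs=1e-12)
        assert res.n_pcs == expected.n_pcs

    def test_deterministic(self):
        rng = np.random.default_rng(32)
        X = rng.normal(0, 1, (15, 5))
        y = rng.normal(0, 1, 15)
        a = evaluate_feature(X, y, RidgeConfig(), permutations=30, seed=4)
        b = evaluate_feature(X, y, RidgeConfig(), permutations=30, seed=4)
        np.testing.assert_array_equal(a.predicted, b.predicted)
        assert a.permutation_p == b.permutation_p
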