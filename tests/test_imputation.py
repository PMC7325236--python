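"""Imputation methods: guards, worked oracles, pass-through invariants."""

import numpy as np
import pytest

from methylbench import (
    ImputerSpec,
    Scale,
    apply_method_guards,
    impute_chained_reg,
    impute_iter_pca,
    impute_knn,
    impute_mean,
    impute_methylimp,
    impute_soft_svd,
    impute_svd_iter,
    run_imputer,
)
from methylbench.imputation import METHODS, NoCompleteVariablesError, _iter_pca_kernel

from conftest import make_matrix

M = Scale.M  # unbounded scale, convenient for synthetic linear-algebra fixtures


def random_missing(values, n_miss, rng, scale=M):
    x = make_matrix(values, scale=scale)
    flat = rng.choice(values.size, size=n_miss, replace=False)
    pos = np.column_stack(np.unravel_index(flat, values.shape))
    x.values[pos[:, 0], pos[:, 1]] = np.nan
    return x, pos


class TestGuards:
    def test_all_missing_cpg_unimputable_for_every_method(self):
        vals = np.random.default_rng(0).uniform(0.1, 0.9, (4, 5))
        vals[:, 2] = np.nan
        x = make_matrix(vals)
        for method in ("mean", "knn", "svd_iter", "soft_svd", "iter_pca", "chained_reg"):
            _, unimputable, dropped = apply_method_guards(x, ImputerSpec(method))
            assert {(i, 2) for i in range(4)} <= unimputable
            assert 2 in dropped

    def test_iter_pca_drops_zero_variance_column(self):
        vals = np.random.default_rng(0).uniform(0.1, 0.9, (5, 4))
        vals[:, 1] = 0.5
        x = make_matrix(vals)
        _, _, dropped = apply_method_guards(x, ImputerSpec("iter_pca"))
        assert dropped == [1]

    def test_chained_reg_drops_single_observation_column(self):
        vals = np.random.default_rng(0).uniform(0.1, 0.9, (5, 4))
        vals[1:, 3] = np.nan
        x = make_matrix(vals)
        _, unimputable, dropped = apply_method_guards(x, ImputerSpec("chained_reg"))
        assert dropped == [3]
        assert {(i, 3) for i in range(1, 5)} == unimputable

    def test_fully_observed_matrix_guards_are_identity(self):
        x = make_matrix(np.random.default_rng(0).uniform(0.1, 0.9, (5, 6)))
        for method in METHODS:
            included, unimputable, dropped = apply_method_guards(x, ImputerSpec(method))
            assert len(included) == 6 and not unimputable and not dropped

    def test_methylimp_requires_a_complete_column(self):
        vals = np.random.default_rng(0).uniform(0.1, 0.9, (4, 3))
        vals[0, 0] = vals[1, 1] = vals[2, 2] = np.nan
        x = make_matrix(vals)
        with pytest.raises(NoCompleteVariablesError):
            impute_methylimp(x)


class TestMean:
    def test_column_mean_examples(self):
        x = make_matrix([[0.2], [np.nan], [0.4]])
        out = impute_mean(x)
        assert out.imputed.values[1, 0] == pytest.approx(0.3)

    def test_repeated_values(self):
        x = make_matrix([[0.1], [np.nan], [np.nan], [0.1]])
        out = impute_mean(x)
        np.testing.assert_allclose(out.imputed.values[:, 0], 0.1)

    def test_no_missing_is_identity(self, rng):
        vals = rng.uniform(0.1, 0.9, (6, 8))
        out = impute_mean(make_matrix(vals))
        np.testing.assert_array_equal(out.imputed.values, vals)


class TestKnn:
    def test_identical_twin_column_zero_distance(self, rng):
        base = rng.uniform(0.1, 0.9, size=8)
        vals = np.column_stack([base, base, rng.uniform(0.1, 0.9, 8)])
        vals[3, 0] = np.nan
        out = impute_knn(make_matrix(vals), k=1)
        assert out.imputed.values[3, 0] == pytest.approx(base[3], abs=1e-9)

    def test_k_larger_than_candidates_uses_all(self, rng):
        vals = rng.uniform(0.1, 0.9, (5, 3))
        vals[0, 0] = np.nan
        out_big = impute_knn(make_matrix(vals), k=50)
        out_all = impute_knn(make_matrix(vals), k=2)
        assert out_big.imputed.values[0, 0] == pytest.approx(out_all.imputed.values[0, 0])

    def test_matches_brute_force_search(self, rng):
        """Independent re-computation: naive python loops over candidate CpGs
        ranked by mean squared difference on shared samples."""
        vals = rng.uniform(0.0, 1.0, (5, 8))
        x, pos = random_missing(vals.copy(), 6, rng, scale=Scale.BETA)
        k = 3
        out = impute_knn(x, k=k)
        X = x.values
        for i, j in pos:
            dists = []
            for jj in range(8):
                if jj == j:
                    continue
                shared = ~np.isnan(X[:, j]) & ~np.isnan(X[:, jj])
                if not shared.any() or np.isnan(X[i, jj]):
                    continue
                d2 = np.mean((X[shared, j] - X[shared, jj]) ** 2)
                dists.append((d2, jj))
            dists.sort()
            nb = dists[:k]
            w = np.array([1.0 / (np.sqrt(d) + 1e-12) for d, _ in nb])
            expect = np.dot(w, [X[i, jj] for _, jj in nb]) / w.sum()
            assert out.imputed.values[i, j] == pytest.approx(expect, abs=1e-9)


class TestSvdIter:
    def test_rank_one_recovery(self, rng):
        u = rng.uniform(0.5, 1.5, 12)
        v = rng.uniform(0.5, 1.5, 20)
        vals = np.outer(u, v)
        x = make_matrix(vals.copy(), scale=M)
        x.values[4, 7] = np.nan
        out = impute_svd_iter(x, rank=1, tol=1e-9, max_iter=500)
        assert abs(out.imputed.values[4, 7] - u[4] * v[7]) < 1e-4
        assert out.diagnostics["converged"]

    def test_fully_observed_identity_zero_iterations(self, rng):
        vals = rng.normal(size=(6, 9))
        out = impute_svd_iter(make_matrix(vals, scale=M))
        np.testing.assert_array_equal(out.imputed.values, vals)
        assert out.diagnostics["iterations"] == 0

    def test_infinite_tol_is_single_reconstruction_pass(self, rng):
        vals = rng.normal(size=(6, 9))
        x, _ = random_missing(vals.copy(), 5, rng)
        out = impute_svd_iter(x, rank=2, tol=np.inf)
        assert out.diagnostics["iterations"] == 1

    def test_rank_too_large_rejected(self, rng):
        x, _ = random_missing(rng.normal(size=(4, 6)), 2, rng)
        with pytest.raises(ValueError):
            impute_svd_iter(x, rank=10)


class TestSoftSvd:
    def test_zero_lambda_full_rank_matches_svd_iter(self, rng):
        vals = rng.normal(size=(7, 10))
        x, _ = random_missing(vals.copy(), 6, rng)
        soft = impute_soft_svd(x, lambda_frac=0.0)
        hard = impute_svd_iter(x, rank=7)
        np.testing.assert_allclose(soft.imputed.values, hard.imputed.values, atol=1e-10)

    def test_large_lambda_shrinks_fill_toward_zero(self, rng):
        vals = rng.uniform(1.0, 2.0, size=(8, 10))
        x, pos = random_missing(vals.copy(), 6, rng)
        out = impute_soft_svd(x, lambda_frac=0.999)
        filled = out.imputed.values[pos[:, 0], pos[:, 1]]
        assert np.all(np.abs(filled) < 0.1)

    def test_rank_one_recovery_within_shrinkage_bound(self, rng):
        """Rank-1 spectrum sigma shrinks to sigma - lambda, so the masked-entry
        error is bounded by ~ (lambda/sigma) * |entry|; allow 2x slack."""
        u = rng.uniform(0.5, 1.5, 15)
        v = rng.uniform(0.5, 1.5, 25)
        vals = np.outer(u, v)
        sigma = np.linalg.norm(u) * np.linalg.norm(v)
        lam_frac = 0.01
        x = make_matrix(vals.copy(), scale=M)
        x.values[3, 5] = np.nan
        out = impute_soft_svd(x, lambda_frac=lam_frac, tol=1e-9, max_iter=500)
        bound = 2 * lam_frac * abs(vals[3, 5]) + 2 * lam_frac * sigma / np.sqrt(vals.size)
        assert abs(out.imputed.values[3, 5] - vals[3, 5]) < max(bound, 2 * lam_frac * abs(vals[3, 5]))


class TestIterPca:
    def test_fully_observed_identity(self, rng):
        vals = rng.normal(size=(6, 9))
        out = impute_iter_pca(make_matrix(vals, scale=M), ncp=2)
        np.testing.assert_array_equal(out.imputed.values, vals)

    def test_mean_plus_rank_one_recovery(self, rng):
        mu = rng.uniform(-1, 1, 18)
        f = rng.normal(size=10)
        w = rng.normal(size=18)
        vals = mu + np.outer(f, w)
        x = make_matrix(vals.copy(), scale=M)
        x.values[2, 6] = np.nan
        out = impute_iter_pca(x, ncp=1, tol=1e-10, max_iter=1000)
        assert abs(out.imputed.values[2, 6] - vals[2, 6]) < 1e-3

    def test_centering_absorbs_constant_columns(self, rng):
        """Kernel-level property: a constant column's masked entry is restored
        to the constant by the column-centering step."""
        vals = rng.normal(size=(8, 5))
        vals[:, 2] = 0.7
        X = vals.copy()
        X[4, 2] = np.nan
        filled = _iter_pca_kernel(X, {}, ncp=1, tol=1e-10, max_iter=200)
        assert filled[4, 2] == pytest.approx(0.7, abs=1e-6)


class TestChainedReg:
    def test_exact_linear_combination_recovered(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        target = 1.5 * a - 0.7 * b + 0.2
        vals = np.column_stack([a, b, target])
        x = make_matrix(vals.copy(), scale=M)
        x.values[5, 2] = np.nan
        out = impute_chained_reg(x, learner="linear")
        assert abs(out.imputed.values[5, 2] - target[5]) < 1e-8

    def test_single_incomplete_column_is_one_fit(self, rng):
        vals = rng.normal(size=(10, 5))
        x = make_matrix(vals.copy(), scale=M)
        x.values[[1, 4], 2] = np.nan
        out = impute_chained_reg(x, learner="linear")
        assert out.diagnostics["sweeps"] == 1

    def test_pure_noise_regresses_to_mean_imputation(self, rng):
        """On independent noise columns with many observations per predictor
        the fitted coefficients vanish, so the fill collapses onto the
        column-mean imputation."""
        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(4000, 6))
            x, pos = random_missing(vals.copy(), 20, r)
            cr = impute_chained_reg(x, learner="linear")
            mn = impute_mean(x)
            diffs.append(
                np.mean(
                    np.abs(
                        cr.imputed.values[pos[:, 0], pos[:, 1]]
                        - mn.imputed.values[pos[:, 0], pos[:, 1]]
                    )
                )
            )
        assert np.mean(diffs) < 0.05

    def test_forest_learner_runs(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(15, 6))
        x, pos = random_missing(vals.copy(), 5, rng, scale=Scale.BETA)
        out = impute_chained_reg(x, learner="forest", n_estimators=10)
        filled = out.imputed.values[pos[:, 0], pos[:, 1]]
        assert np.all(np.isfinite(filled))
        assert np.all((filled >= 0) & (filled <= 1))


class TestMethylimp:
    def test_exact_linear_relation_recovered(self, rng):
        pred = rng.uniform(0.1, 0.9, size=14)
        target = 2.0 * pred - 0.3
        ones = np.ones(14)
        extra = rng.normal(size=14)
        vals = np.column_stack([ones, pred, extra, target])
        x = make_matrix(vals.copy(), scale=M)
        x.values[6, 3] = np.nan
        out = impute_methylimp(x)
        assert abs(out.imputed.values[6, 3] - target[6]) < 1e-8

    def test_every_column_incomplete_raises(self, rng):
        vals = rng.uniform(0.1, 0.9, (3, 3))
        np.fill_diagonal(vals, np.nan)
        with pytest.raises(NoCompleteVariablesError):
            impute_methylimp(make_matrix(vals))

    def test_beta_scale_predictions_clipped(self):
        # the target equals 1.3x the complete predictor on its observed rows,
        # so the masked entry's linear prediction exceeds 1 and is stored as 1.0
        pred = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.9])
        vals = np.column_stack([pred, np.minimum(pred * 1.4, 1.0)])
        x = make_matrix(vals)
        x.values[-1, 1] = np.nan  # linear prediction 0.9 * 1.4 = 1.26
        out = impute_methylimp(x)
        assert out.imputed.values[-1, 1] == pytest.approx(1.0)

    def test_pattern_without_training_rows_unimputable(self, rng):
        vals = rng.uniform(0.1, 0.9, (4, 3)).astype(float)
        vals[:, 1] = np.nan  # missing everywhere: no row observes it
        x = make_matrix(vals)
        out = impute_methylimp(x)
        assert {(i, 1) for i in range(4)} <= out.unimputable


@pytest.mark.parametrize("method", METHODS)
def test_observed_entries_pass_through_and_coverage(method, rng):
    """For every method: observed entries unchanged bit-exactly, and the
    missing positions are exactly partitioned into imputed and unimputable."""
    vals = rng.uniform(0.05, 0.95, size=(20, 30))
    x, pos = random_missing(vals.copy(), 25, rng, scale=Scale.BETA)
    out = run_imputer(x, ImputerSpec(method))
    obs = ~x.mask
    np.testing.assert_array_equal(out.imputed.values[obs], x.values[obs])
    for i, j in pos:
        filled = not np.isnan(out.imputed.values[i, j])
        assert filled != ((int(i), int(j)) in out.unimputable)
    # beta-scale outputs lie in [0, 1] after clipping
    imputed_vals = out.imputed.values[~np.isnan(out.imputed.values)]
    assert np.all((imputed_vals >= 0) & (imputed_vals <= 1))


def test_low_rank_recovery_rmse(rng):
    """Noiseless rank-3 matrix with <=1% masked: truncated-SVD completion
    reaches RMSE below 1e-3."""
    U = rng.normal(size=(30, 3))
    V = rng.normal(size=(3, 60))
    vals = U @ V
    x, pos = random_missing(vals.copy(), 18, rng)  # 1% of 1800
    out = impute_svd_iter(x, rank=3, tol=1e-10, max_iter=1000)
    pred = out.imputed.values[pos[:, 0], pos[:, 1]]
    truth = vals[pos[:, 0], pos[:, 1]]
    assert np.sqrt(np.mean((pred - truth) ** 2)) < 1e-3
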