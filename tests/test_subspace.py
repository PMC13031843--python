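import numpy as np
import pytest

from corticomm.subspace import (
    AblationProjection,
    RRRFit,
    ablate_predictive_dims,
    ablated_performance,
    cv_ridge_performance,
    performance_curve,
    ridge_fit,
    rrr_fit,
    spatial_degeneracy,
    subspace_similarity,
    temporal_degeneracy,
)


def make_low_rank_problem(rng, t=200, p=10, q=10, rank=3, noise=0.3, sv=(1.0, 0.7, 0.5)):
    X = rng.normal(size=(t, p))
    U = np.linalg.qr(rng.normal(size=(p, rank)))[0]
    V = np.linalg.qr(rng.normal(size=(q, rank)))[0]
    B = U @ np.diag(sv[:rank]) @ V.T
    Y = X @ B + noise * rng.normal(size=(t, q))
    return X, Y, B


class TestRidgeFit:
    def test_lambda_zero_matches_pinv_oracle(self, rng):
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 5))
        fit = ridge_fit(X, Y, lambda_grid=0.0)
        assert np.allclose(fit.B_ridge, np.linalg.pinv(X) @ Y, atol=1e-10)

    def test_identity_recovery(self, rng):
        X = rng.normal(size=(60, 6))
        fit = ridge_fit(X, X, lambda_grid=0.0)
        assert np.allclose(fit.B_ridge, np.eye(6), atol=1e-10)

    def test_rank_deficient_lambda_zero_raises(self, rng):
        X = rng.normal(size=(40, 5))
        X[:, 4] = X[:, 0]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError):
            ridge_fit(X, rng.normal(size=(40, 2)), lambda_grid=0.0)

    def test_collinear_selects_positive_lambda_and_beats_ols(self, rng):
        # near-collinear X: CV should regularize and beat lambda ~ 0 held out
        t = 120
        base = rng.normal(size=(t, 3))
        X = np.hstack([base, base + 1e-4 * rng.normal(size=(t, 3))])
        B = rng.normal(size=(6, 4))
        Y = X @ B + 0.5 * rng.normal(size=(t, 4))
        fit = ridge_fit(X[:80], Y[:80], folds=5)
        assert fit.lam > 0
        ols = ridge_fit(X[:80], Y[:80], lambda_grid=1e-12)
        err_cv = np.linalg.norm(Y[80:] - X[80:] @ fit.B_ridge)
        err_ols = np.linalg.norm(Y[80:] - X[80:] @ ols.B_ridge)
        assert err_cv < err_ols

    def test_shrinkage_limit(self, rng):
        X = rng.normal(size=(50, 5))
        Y = rng.normal(size=(50, 3))
        fit = ridge_fit(X, Y, lambda_grid=1e12)
        assert np.abs(fit.B_ridge).max() < 1e-6


class TestRRRFit:
    def test_full_rank_equals_ridge(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        ridge = ridge_fit(X, Y, folds=5)
        fit = rrr_fit(X, Y, m=Y.shape[1], ridge=ridge)
        assert np.allclose(fit.B_rrr, ridge.B_ridge, atol=1e-10)

    def test_rank_one_ground_truth(self, rng):
        # noiseless rank-1 relation: m=1 prediction matches ridge within 1e-8
        X = rng.normal(size=(100, 6))
        b = rng.normal(size=(6, 1))
        v = rng.normal(size=(1, 4))
        Y = X @ b @ v
        ridge = ridge_fit(X, Y, lambda_grid=0.0)
        fit = rrr_fit(X, Y, m=1, ridge=ridge)
        assert np.allclose(X @ fit.B_rrr, X @ ridge.B_ridge, atol=1e-8)

    def test_rank_zero_predicts_nothing(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        fit = rrr_fit(X, Y, m=0, ridge=ridge_fit(X, Y, folds=5))
        assert np.allclose(fit.B_rrr, 0.0)

    def test_invalid_rank(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        with pytest.raises(ValueError):
            rrr_fit(X, Y, m=Y.shape[1] + 1)

    def test_v_orthonormal(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        fit = rrr_fit(X, Y, m=4, ridge=ridge_fit(X, Y, folds=5))
        assert np.allclose(fit.V.T @ fit.V, np.eye(4), atol=1e-8)


class TestPerformanceCurve:
    def test_rank_recovery(self, rng):
        hits = 0
        for seed in range(15):
            r = np.random.default_rng(seed)
            X, Y, _ = make_low_rank_problem(r)
            fit = performance_curve(X, Y, ranks=range(1, 11), folds=10)
            hits += fit.optimal_rank == 3
        assert hits >= 13

    def test_near_monotone_nested_performance(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        fit = performance_curve(X, Y, ranks=range(1, 11), folds=10)
        perf = [fit.perf_by_rank[r][0] for r in range(1, 11)]
        sems = [fit.perf_by_rank[r][1] for r in range(1, 11)]
        for m in range(9):
            assert perf[m] <= perf[m + 1] + 2 * sems[m + 1] + 1e-9

    def test_degenerate_flat_curve_gives_rank_one(self, rng):
        # Y independent of X: performance flat/noisy around 0 -> rank 1
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(100, 5))
        fit = performance_curve(X, Y, ranks=range(1, 6), folds=5)
        assert fit.optimal_rank == 1

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            performance_curve(
                rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), folds=10
            )


class TestSubspaceSimilarity:
    def test_identical(self, rng):
        Q = np.linalg.qr(rng.normal(size=(10, 3)))[0]
        assert subspace_similarity(Q, Q) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal(self):
        a = np.eye(6)[:, :2]
        b = np.eye(6)[:, 2:4]
        assert subspace_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_svd_oracle(self, rng):
        for _ in range(100):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            got = subspace_similarity(A, B)
            Qa = np.linalg.qr(A)[0]
            Qb = np.linalg.qr(B)[0]
            oracle = np.linalg.svd(Qa.T @ Qb, compute_uv=False).min()
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_rotation_invariance(self, rng):
        A = rng.normal(size=(12, 3))
        B = rng.normal(size=(12, 3))
        base = subspace_similarity(A, B)
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        assert subspace_similarity(A @ R, B) == pytest.approx(base, abs=1e-10)
        assert subspace_similarity(A, B @ R) == pytest.approx(base, abs=1e-10)

    def test_zero_dimensional_basis(self):
        with pytest.raises(ValueError):
            subspace_similarity(np.zeros((5, 0)), np.eye(5)[:, :2])

    def test_smallest_angle_variant(self, rng):
        a = np.eye(5)[:, :2]
        b = np.stack([np.eye(5)[:, 0], np.eye(5)[:, 3]], axis=1)
        assert subspace_similarity(a, b, angle="smallest") == pytest.approx(1.0)
        assert subspace_similarity(a, b, angle="largest") == pytest.approx(0.0)


class TestSpatialDegeneracy:
    def test_duplicate_target(self, rng):
        X, Y, _ = make_low_rank_problem(rng, noise=0.1)
        Yb = Y + 0.01 * rng.normal(size=Y.shape)
        assert spatial_degeneracy(X, Y, Yb, dims=3, folds=5) >= 0.99

    def test_shared_vs_disjoint_channels(self, rng):
        # targets driven by the same 3-d source channel vs orthogonal channels
        t, p = 400, 12
        X = rng.normal(size=(t, p))
        W = np.linalg.qr(rng.normal(size=(p, 6)))[0]
        shared, other = W[:, :3], W[:, 3:]
        mix_a = rng.normal(size=(3, 8))
        mix_b = rng.normal(size=(3, 8))
        Ya = X @ shared @ mix_a + 0.2 * rng.normal(size=(t, 8))
        Yb_shared = X @ shared @ mix_b + 0.2 * rng.normal(size=(t, 8))
        Yb_disjoint = X @ other @ mix_b + 0.2 * rng.normal(size=(t, 8))
        sim_shared = spatial_degeneracy(X, Ya, Yb_shared, dims=3, folds=5)
        sim_disjoint = spatial_degeneracy(X, Ya, Yb_disjoint, dims=3, folds=5)
        assert sim_shared > 0.9
        # Monte-Carlo baseline for random 3-d subspaces of a 12-d space
        baseline = [
            subspace_similarity(rng.normal(size=(p, 3)), rng.normal(size=(p, 3)))
            for _ in range(200)
        ]
        assert sim_disjoint < np.quantile(baseline, 0.99) + 0.1
        assert sim_disjoint < sim_shared

    def test_rank_below_dims_raises(self, rng):
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(100, 2))
        with pytest.raises(ValueError):
            spatial_degeneracy(X, Y, Y, dims=3, folds=5)


class TestTemporalDegeneracy:
    def test_diagonal_is_one_and_stationary_high(self, rng):
        t, p = 300, 10
        W = np.linalg.qr(rng.normal(size=(p, 2)))[0]
        mix = rng.normal(size=(2, 6))
        windows = []
        for _ in range(4):
            X = rng.normal(size=(t, p))
            Y = X @ W @ mix + 0.2 * rng.normal(size=(t, 6))
            windows.append((X, Y))
        sim = temporal_degeneracy(windows, dims=2, folds=5)
        assert np.allclose(np.diag(sim), 1.0)
        off = sim[np.triu_indices_from(sim, k=1)]
        assert off.min() > 0.85

    def test_latent_switch_block_structure(self, rng):
        t, p = 300, 10
        W = np.linalg.qr(rng.normal(size=(p, 4)))[0]
        wa, wb = W[:, :2], W[:, 2:]
        mix = rng.normal(size=(2, 6))
        windows = []
        for k in range(4):
            X = rng.normal(size=(t, p))
            chan = wa if k < 2 else wb
            windows.append((X, X @ chan @ mix + 0.2 * rng.normal(size=(t, 6))))
        sim = temporal_degeneracy(windows, dims=2, folds=5)
        within = (sim[0, 1] + sim[2, 3]) / 2
        across = (sim[0, 2] + sim[0, 3] + sim[1, 2] + sim[1, 3]) / 4
        assert within > 0.85
        assert across < 0.5

    def test_insufficient_frames(self, rng):
        with pytest.raises(ValueError):
            temporal_degeneracy([(rng.normal(size=(4, 10)), rng.normal(size=(4, 5)))])


class TestAblation:
    def test_mq_zero_and_orthonormal(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        fit = rrr_fit(X, Y, m=3, ridge=ridge_fit(X, Y, folds=5))
        proj = ablate_predictive_dims(X, fit, m_remove=3)
        assert np.abs(proj.M @ proj.Q).max() <= 1e-8
        assert np.allclose(proj.Q.T @ proj.Q, np.eye(proj.Q.shape[1]), atol=1e-8)

    def test_m_remove_zero_keeps_performance(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        fit = rrr_fit(X, Y, m=3, ridge=ridge_fit(X, Y, folds=5))
        res = ablated_performance(X, Y, fit, m_remove=0, folds=5)
        assert res["performance"] == pytest.approx(
            res["unablated_performance"], abs=1e-8
        )
        assert res["projection"].Q.shape == (X.shape[1], X.shape[1])

    def test_exact_rank3_ablation_kills_prediction(self, rng):
        X, Y, _ = make_low_rank_problem(rng, noise=0.05)
        fit = rrr_fit(X, Y, m=3, ridge=ridge_fit(X, Y, folds=5))
        res = ablated_performance(X, Y, fit, m_remove=3, folds=5)
        assert res["performance"] <= 0.05
        assert res["unablated_performance"] > 0.5

    def test_orthogonal_dims_ablation_harmless(self, rng):
        X, Y, _ = make_low_rank_problem(rng, noise=0.05)
        fit = rrr_fit(X, Y, m=3, ridge=ridge_fit(X, Y, folds=5))
        # forge a fit whose "predictive dimensions" span the orthogonal
        # complement of the true ones
        comp = np.linalg.svd(fit.B_bar, full_matrices=True)[0][:, 3:6]
        fake = RRRFit(
            V=fit.V, B_bar=comp, B_rrr=fit.B_rrr, rank=3, lam=fit.lam
        )
        res = ablated_performance(X, Y, fake, m_remove=3, folds=5)
        assert res["normalized"] >= 0.9

    def test_shared_vs_disjoint_channel_ablation(self, rng):
        # ablating A's dims degrades B iff B shares the source channel
        t, p = 400, 12
        X = rng.normal(size=(t, p))
        W = np.linalg.qr(rng.normal(size=(p, 4)))[0]
        ch_a, ch_other = W[:, :2], W[:, 2:]
        Ya = X @ ch_a @ rng.normal(size=(2, 6)) + 0.1 * rng.normal(size=(t, 6))
        Yb_shared = X @ ch_a @ rng.normal(size=(2, 6)) + 0.1 * rng.normal(size=(t, 6))
        Yb_disjoint = X @ ch_other @ rng.normal(size=(2, 6)) + 0.1 * rng.normal(
            size=(t, 6)
        )
        fit_a = rrr_fit(X, Ya, m=2, ridge=ridge_fit(X, Ya, folds=5))
        shared = ablated_performance(X, Yb_shared, fit_a, m_remove=2, folds=5)
        disjoint = ablated_performance(X, Yb_disjoint, fit_a, m_remove=2, folds=5)
        assert shared["normalized"] < 0.5
        assert disjoint["normalized"] >= 0.9

    def test_invalid_m_remove(self, rng):
        X, Y, _ = make_low_rank_problem(rng)
        fit = rrr_fit(X, Y, m=3, ridge=ridge_fit(X, Y, folds=5))
        with pytest.raises(ValueError):
            ablate_predictive_dims(X, fit, m_remove=X.shape[1])


def test_cv_ridge_performance_noiseless_copy(rng):
    X = rng.normal(size=(200, 10))
    Y = X @ rng.normal(size=(10, 10))
    perf, sem = cv_ridge_performance(X, Y, folds=5)
    assert perf >= 0.99


def test_cv_ridge_performance_independent_near_zero(rng):
    X = rng.normal(size=(300, 10))
    Y = rng.normal(size=(300, 10))
    perf, _ = cv_ridge_performance(X, Y, folds=5)
    assert -0.2 < perf < 0.1
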