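import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lowrankdti as lr
from conftest import random_factors


class TestSoftThreshold:
    def test_direct_arithmetic(self):
        np.testing.assert_array_equal(
            lr.soft_threshold_singular_values(np.array([3.0, 1.0, 0.2]), 0.5),
            [2.5, 0.5, 0.0])

    def test_zero_threshold_is_identity(self):
        s = np.array([2.0, 1.0, 0.5])
        np.testing.assert_array_equal(
            lr.soft_threshold_singular_values(s, 0.0), s)

    def test_full_shrinkage(self):
        s = np.array([2.0, 1.0])
        assert lr.soft_threshold_singular_values(s, 2.0).max() == 0.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            lr.soft_threshold_singular_values(np.array([-1.0]), 0.1)


class TestSvtOracle:
    def test_no_shrinkage_full_rank_reproduces_input(self, rng):
        Y = rng.standard_normal((5, 4))
        fac = lr.svt_oracle(Y, 0.0, 4)
        np.testing.assert_allclose(fac.reconstruct(), Y, atol=1e-10)

    def test_full_shrinkage_gives_zero(self, rng):
        Y = rng.standard_normal((5, 4))
        s1 = np.linalg.svd(Y, compute_uv=False)[0]
        assert np.abs(lr.svt_oracle(Y, s1, 4).reconstruct()).max() <= 1e-12

    def test_nuclear_norm_of_output(self):
        Y = np.random.default_rng(1).standard_normal((6, 5))
        s = np.linalg.svd(Y, compute_uv=False)
        fac = lr.svt_oracle(Y, 0.3, 3)
        expected = np.maximum(s[:3] - 0.3, 0).sum()
        assert fac.nuclear_norm() == pytest.approx(expected, abs=1e-10)


class TestRankRestrictedSoftSVD:
    def test_identity_limit(self, rng):
        Y = rng.standard_normal((6, 5))
        cfg = lr.SolverConfig(lam=0.0, r=5, tol=1e-14, max_iter=5000, seed=0)
        fac, trace = lr.rank_restricted_soft_svd(Y, cfg)
        np.testing.assert_allclose(fac.reconstruct(), Y, atol=1e-6)
        assert trace.converged

    @pytest.mark.parametrize("lam", [0.1, 0.5])
    def test_oracle_equivalence_sweep(self, lam):
        worst = 0.0
        for seed in range(50):
            g = np.random.default_rng(seed)
            m, n = int(g.integers(5, 21)), int(g.integers(4, 16))
            Y = g.standard_normal((m, n))
            cfg = lr.SolverConfig(lam=lam, r=4, tol=1e-15, max_iter=5000,
                                  seed=seed)
            fac, _ = lr.rank_restricted_soft_svd(Y, cfg)
            Z_oracle = lr.svt_oracle(Y, lam, 4).reconstruct()
            worst = max(worst, np.abs(fac.reconstruct() - Z_oracle).max())
        assert worst <= 1e-6

    def test_variational_identity_at_solution(self):
        # 1/2(|A|^2 + |B|^2) equals the nuclear norm of AB^T at the optimum
        Y = np.random.default_rng(3).standard_normal((12, 9))
        cfg = lr.SolverConfig(lam=0.4, r=4, tol=1e-14, max_iter=5000, seed=3)
        fac, _ = lr.rank_restricted_soft_svd(Y, cfg)
        half_sq = 0.5 * (np.linalg.norm(fac.A) ** 2 + np.linalg.norm(fac.B) ** 2)
        nuc = np.linalg.norm(fac.reconstruct(), ord="nuc")
        assert abs(half_sq - nuc) <= 1e-6

    def test_monotone_shrinkage_in_lambda(self):
        Y = np.random.default_rng(5).standard_normal((10, 8))
        prev_nuc, prev_rank = np.inf, np.inf
        for lam in (0.1, 0.5, 1.0, 2.0):
            cfg = lr.SolverConfig(lam=lam, r=5, tol=1e-12, max_iter=3000,
                                  seed=0)
            fac, _ = lr.rank_restricted_soft_svd(Y, cfg)
            nuc = fac.nuclear_norm()
            rank = int((fac.d > 1e-10).sum())
            assert nuc <= prev_nuc + 1e-9
            assert rank <= prev_rank
            prev_nuc, prev_rank = nuc, rank

    def test_factor_orthonormality_and_order(self):
        Y = np.random.default_rng(8).standard_normal((9, 7))
        cfg = lr.SolverConfig(lam=0.2, r=4, tol=1e-12, max_iter=3000, seed=8)
        fac, _ = lr.rank_restricted_soft_svd(Y, cfg)
        np.testing.assert_allclose(fac.U.T @ fac.U, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(fac.V.T @ fac.V, np.eye(4), atol=1e-8)
        assert (np.diff(fac.d) <= 1e-12).all()
        np.testing.assert_allclose(fac.A @ fac.B.T, fac.reconstruct(),
                                   atol=1e-10)


class TestSoftImputeMasked:
    def test_full_mask_reduces_to_fully_observed(self, rng):
        Y = rng.standard_normal((8, 6))
        cfg = lr.SolverConfig(lam=0.3, r=3, tol=1e-12, max_iter=2000, seed=0)
        fac_m, _ = lr.soft_impute_masked(Y, np.ones_like(Y), cfg)
        warm = lr.svt_oracle(Y, cfg.lam, cfg.r)
        fac_f, _ = lr.rank_restricted_soft_svd(Y, cfg, warm=warm)
        np.testing.assert_allclose(fac_m.reconstruct(), fac_f.reconstruct(),
                                   atol=1e-8)
        # and both sit at the closed-form solution
        np.testing.assert_allclose(fac_m.reconstruct(), warm.reconstruct(),
                                   atol=1e-8)

    def test_noiseless_low_rank_recovery(self):
        inst = lr.generate(lr.SyntheticSpec(m=30, n=25, rank=2, seed=7,
                                            mask_fraction=0.6))
        Y, mask = inst.truth, inst.data.mask
        cfg = lr.SolverConfig(lam=1e-3, r=4, tol=1e-15, max_iter=30000,
                              seed=0)
        fac, _ = lr.soft_impute_masked(Y, mask, cfg)
        un = mask == 0
        err = (np.linalg.norm((fac.reconstruct() - Y)[un])
               / np.linalg.norm(Y[un]))
        assert err <= 1e-2

    def test_objective_nonincreasing(self, rng):
        Y = rng.standard_normal((12, 10))
        mask = (rng.uniform(size=Y.shape) < 0.7).astype(float)
        cfg = lr.SolverConfig(lam=0.2, r=3, tol=1e-12, max_iter=2000, seed=1)
        _, trace = lr.soft_impute_masked(Y, mask, cfg)
        obj = np.array(trace.objective)
        assert (np.diff(obj) <= 1e-9 * np.abs(obj[:-1]) + 1e-12).all()

    def test_all_unobserved_mask_raises(self):
        with pytest.raises(ValueError, match="no observed"):
            lr.soft_impute_masked(np.ones((3, 3)), np.zeros((3, 3)),
                                  lr.SolverConfig())


class TestSylvester:
    def test_scalar_case(self):
        X = lr.solve_sylvester(2 * np.eye(2), 3 * np.eye(2), np.ones((2, 2)))
        np.testing.assert_allclose(X, np.ones((2, 2)) / 5, atol=1e-12)

    def test_diagonal_decoupling(self):
        Aq, Bq = np.diag([1.0, 2.0]), np.diag([3.0, 4.0])
        C = np.arange(1.0, 5.0).reshape(2, 2)
        X = lr.solve_sylvester(Aq, Bq, C)
        expected = C / (np.array([1.0, 2.0])[:, None] + np.array([3.0, 4.0]))
        np.testing.assert_allclose(X, expected, atol=1e-12)

    def test_random_residual(self):
        g = np.random.default_rng(3)
        Aq = g.standard_normal((5, 5)) + 5 * np.eye(5)
        Bq = g.standard_normal((5, 5)) + 5 * np.eye(5)
        C = g.standard_normal((5, 5))
        X = lr.solve_sylvester(Aq, Bq, C)
        resid = np.linalg.norm(Aq @ X + X @ Bq - C)
        assert resid <= 1e-8 * np.linalg.norm(C)


class TestRelativeFrobeniusChange:
    def test_identical_factors_zero(self):
        fac = random_factors(6, 5, 3, seed=0)
        assert lr.relative_frobenius_change(fac, fac) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_zero_new_solution_gives_one(self):
        fac = random_factors(6, 5, 3, seed=1)
        zero = lr.LowRankFactors(fac.U, np.zeros(3), fac.V)
        assert lr.relative_frobenius_change(fac, zero) == pytest.approx(1.0)

    def test_zero_old_solution_sentinel(self):
        fac = random_factors(6, 5, 3, seed=2)
        zero = lr.LowRankFactors(fac.U, np.zeros(3), fac.V)
        assert lr.relative_frobenius_change(zero, fac) == np.inf
        assert lr.relative_frobenius_change(zero, zero) == 0.0

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_matches_dense_evaluation(self, seed):
        old = random_factors(7, 6, 3, seed=seed)
        new = random_factors(7, 6, 3, seed=seed + 10_000)
        dense = (np.linalg.norm(old.reconstruct() - new.reconstruct()) ** 2
                 / np.linalg.norm(old.reconstruct()) ** 2)
        assert lr.relative_frobenius_change(old, new) == pytest.approx(
            dense, abs=1e-10)
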