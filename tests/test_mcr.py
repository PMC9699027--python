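import numpy as np
import pytest

from mcrkin.mcr import (
    MCRALS,
    ClosureSpec,
    ComponentSystem,
    ConstraintSpec,
    apply_closure,
    c_step,
    lack_of_fit,
    minimize_spectral_admixture,
    run_als,
    s_step,
)


def gaussians(grid, peaks):
    s = np.zeros_like(grid)
    for c, w, a in peaks:
        s += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return s


@pytest.fixture
def toy_system():
    """3-component bilinear system with overlapping bands, exact data."""
    grid = np.linspace(4000, 9000, 300)
    S = np.column_stack([
        gaussians(grid, [(4400, 150, 1.0), (6000, 200, 0.5)]),
        gaussians(grid, [(5000, 150, 0.9), (4500, 180, 0.4)]),
        gaussians(grid, [(4300, 120, 0.8), (5400, 160, 0.6)]),
    ])
    t = np.linspace(0, 120, 12)
    cA = np.exp(-0.03 * t)
    cB = 0.03 / 0.02 * (np.exp(-0.01 * t) - np.exp(-0.03 * t))
    C = np.column_stack([cA, cB, 1 - cA - cB])
    return C, S, C @ S.T


class TestCStep:
    def test_exact_least_squares_recovery(self, toy_system):
        C, S, X = toy_system
        out = c_step(X, S, ConstraintSpec(nonneg_C=False, nonneg_S=False))
        np.testing.assert_allclose(out, C, atol=1e-10)

    def test_identity(self):
        out = c_step(np.eye(2), np.eye(2), ConstraintSpec(nonneg_C=False))
        np.testing.assert_allclose(out, np.eye(2), atol=1e-12)

    def test_nnls_matches_brute_force_grid(self):
        # orthonormal spectra, single row x = s1 - 0.1*s2: best c >= 0 is (1, 0)
        s1 = np.array([1.0, 0.0, 0.0, 0.0])
        s2 = np.array([0.0, 1.0, 0.0, 0.0])
        S = np.column_stack([s1, s2])
        x = (s1 - 0.1 * s2)[None, :]
        out = c_step(x, S, ConstraintSpec(nonneg_C=True))
        # independent brute-force oracle on a grid of non-negative coefficients
        cs = np.arange(0, 1.5, 1e-3)
        best, best_r = None, np.inf
        for c1 in cs:
            r = x[0] - c1 * s1  # c2's optimum given c1 is max(proj, 0) = 0 here
            for c2 in (0.0, 1e-3):
                rr = float(np.sum((r - c2 * s2) ** 2))
                if rr < best_r:
                    best, best_r = (c1, c2), rr
        np.testing.assert_allclose(out[0], best, atol=2e-3)
        np.testing.assert_allclose(out[0], [1.0, 0.0], atol=1e-8)

    def test_fixed_and_shared_scalar_constraints(self, toy_system):
        C, S, X = toy_system
        cs = ConstraintSpec(
            fixed_C={"c1": 0.25}, free_scalar_C=("c0",), nonneg_C=True
        )
        out = c_step(X, S, cs, names=["c0", "c1", "c2"])
        assert np.allclose(out[:, 1], 0.25)
        assert np.ptp(out[:, 0]) < 1e-12  # one shared scalar

    def test_zero_spectrum_column_error(self):
        S = np.column_stack([np.ones(4), np.zeros(4)])
        with pytest.raises(ValueError, match="all-zero"):
            c_step(np.ones((2, 4)), S, ConstraintSpec())

    def test_rank_deficient_warns(self):
        s = np.linspace(1, 2, 5)
        S = np.column_stack([s, s])  # identical columns
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            c_step(s[None, :], S, ConstraintSpec(nonneg_C=False))


class TestSStep:
    def test_all_known_returned_unchanged(self, toy_system):
        C, S, X = toy_system
        system = ComponentSystem(["a", "b", "c"], S, [True, True, True])
        out = s_step(np.random.default_rng(0).random(X.shape), C, system,
                     ConstraintSpec())
        np.testing.assert_array_equal(out, S)

    def test_no_known_recovers_truth(self, toy_system):
        C, S, X = toy_system
        system = ComponentSystem(["a", "b", "c"], np.zeros_like(S),
                                 [False, False, False])
        out = s_step(X, C, system, ConstraintSpec(nonneg_S=False))
        np.testing.assert_allclose(out, S, atol=1e-10)

    def test_partial_known_matches_deflation_oracle(self, toy_system):
        C, S, X = toy_system
        system = ComponentSystem(["a", "b", "c"], S, [True, False, False])
        out = s_step(X, C, system, ConstraintSpec(nonneg_S=False))
        np.testing.assert_array_equal(out[:, 0], S[:, 0])
        # independent oracle: direct LS on the deflated matrix
        D = X - np.outer(C[:, 0], S[:, 0])
        expected = np.linalg.lstsq(C[:, 1:], D, rcond=None)[0].T
        np.testing.assert_allclose(out[:, 1:], expected, atol=1e-8)
        np.testing.assert_allclose(out[:, 1:], S[:, 1:], atol=1e-8)

    def test_zero_concentration_column_unidentifiable(self, toy_system):
        C, S, X = toy_system
        C = C.copy()
        C[:, 2] = 0.0
        system = ComponentSystem(["a", "b", "c"], S, [True, False, False])
        with pytest.raises(ValueError, match="[Uu]nidentifiable"):
            s_step(X, C, system, ConstraintSpec())


class TestClosure:
    def test_already_closed_unchanged(self):
        C = np.array([[0.2, 0.2, 0.6]])
        out, flagged = apply_closure(C, np.arange(3), 1.0)
        np.testing.assert_allclose(out, C)
        assert flagged.size == 0

    def test_rescaling(self):
        out, _ = apply_closure(np.array([[2.0, 2.0, 6.0]]), np.arange(3), 1.0)
        np.testing.assert_allclose(out, [[0.2, 0.2, 0.6]])

    def test_zero_row_flagged_not_rescaled(self):
        C = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        out, flagged = apply_closure(C, np.arange(3), 1.0)
        np.testing.assert_array_equal(out[0], 0.0)
        assert flagged.tolist() == [0]

    def test_subset_closure_leaves_rest(self):
        C = np.array([[2.0, 2.0, 5.0]])
        out, _ = apply_closure(C, np.array([0, 1]), 1.0)
        np.testing.assert_allclose(out, [[0.5, 0.5, 5.0]])


class TestLackOfFit:
    def test_exact_fit_is_zero(self, toy_system):
        C, S, X = toy_system
        assert lack_of_fit(X, C, S) < 1e-14

    def test_zero_model_is_one(self, toy_system):
        C, S, X = toy_system
        assert lack_of_fit(X, np.zeros_like(C), S) == pytest.approx(1.0)

    def test_matches_direct_frobenius_ratio(self, rng):
        X = rng.random((4, 6))
        C = rng.random((4, 2))
        S = rng.random((6, 2))
        direct = np.sqrt(np.sum((X - C @ S.T) ** 2)) / np.sqrt(np.sum(X**2))
        assert lack_of_fit(X, C, S) == pytest.approx(direct, abs=1e-12)

    def test_zero_data_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            lack_of_fit(np.zeros((2, 2)), np.ones((2, 1)), np.ones((2, 1)))


class TestRunALS:
    def test_all_known_collapses_to_single_c_step(self, toy_system):
        C, S, X = toy_system
        system = ComponentSystem(["a", "b", "c"], S, [True, True, True])
        cs = ConstraintSpec(nonneg_C=True,
                            closure=ClosureSpec(("a", "b", "c"), 1.0))
        res = run_als(X, system, cs)
        assert res.iterations == 1
        assert res.converged
        np.testing.assert_allclose(res.C, c_step(X, S, cs, ["a", "b", "c"]),
                                   atol=1e-14)

    def test_noiseless_recovery_from_perturbed_truth(self, toy_system, rng):
        C, S, X = toy_system
        S0 = S.copy()
        S0[:, 1:] = np.clip(S[:, 1:] * (1 + 0.05 * rng.standard_normal(S[:, 1:].shape)), 0, None)
        system = ComponentSystem(["a", "b", "c"], S0, [True, False, False])
        cs = ConstraintSpec(closure=ClosureSpec(("a", "b", "c"), 1.0))
        res = run_als(X, system, cs)
        assert res.lof < 1e-3  # < 0.1 %
        for j in (1, 2):
            cos = res.S[:, j] @ S[:, j] / np.linalg.norm(res.S[:, j]) / np.linalg.norm(S[:, j])
            assert cos > 0.999

    @pytest.mark.parametrize("seed", [0, 1])
    def test_lof_trace_non_increasing(self, toy_system, seed):
        C, S, X = toy_system
        rng = np.random.default_rng(seed)
        Xn = X + 0.005 * X.mean() * rng.standard_normal(X.shape)
        S0 = S * (1 + 0.1 * rng.standard_normal(S.shape))
        system = ComponentSystem(["a", "b", "c"], np.clip(S0, 0, None),
                                 [True, False, False])
        cs = ConstraintSpec(closure=ClosureSpec(("a", "b", "c"), 1.0))
        res = run_als(Xn, system, cs)
        diffs = np.diff(res.lof_trace)
        assert np.all(diffs <= 1e-10)

    def test_closure_and_nonneg_hold_on_output(self, toy_system, rng):
        C, S, X = toy_system
        Xn = X + 0.01 * X.mean() * rng.standard_normal(X.shape)
        system = ComponentSystem(["a", "b", "c"], S, [True, False, False])
        cs = ConstraintSpec(closure=ClosureSpec(("a", "b", "c"), 1.0))
        res = run_als(Xn, system, cs)
        assert res.C.min() >= -1e-12
        assert res.S.min() >= -1e-12
        np.testing.assert_allclose(res.C.sum(axis=1), 1.0, atol=1e-8)

    def test_scaling_consistency_all_known(self, toy_system):
        C, S, X = toy_system
        system = ComponentSystem(["a", "b", "c"], S, [True, True, True])
        cs = ConstraintSpec(nonneg_C=True)
        res1 = run_als(X, system, cs)
        res2 = run_als(3.0 * X, system, cs)
        np.testing.assert_allclose(res2.C, 3.0 * res1.C, atol=1e-9)

    def test_matches_independent_unconstrained_als(self, toy_system, rng):
        """Cross-check against a minimal lstsq-alternation reference."""
        C, S, X = toy_system
        Xn = X + 0.01 * X.mean() * rng.standard_normal(X.shape)
        S0 = np.clip(S * (1 + 0.02 * rng.standard_normal(S.shape)), 1e-9, None)

        S_ref = S0.copy()
        for _ in range(200):
            C_ref = np.linalg.lstsq(S_ref, Xn.T, rcond=None)[0].T
            S_ref = np.linalg.lstsq(C_ref, Xn, rcond=None)[0].T
        lof_ref = np.linalg.norm(Xn - C_ref @ S_ref.T) / np.linalg.norm(Xn)

        system = ComponentSystem(["a", "b", "c"], S0, [False, False, False])
        cs = ConstraintSpec(nonneg_C=False, nonneg_S=False)
        res = run_als(Xn, system, cs, max_iter=200)
        assert res.lof == pytest.approx(lof_ref, abs=1e-6)

    def test_unknowns_need_init(self, toy_system):
        C, S, X = toy_system
        S0 = S.copy()
        S0[:, 2] = np.nan
        system = ComponentSystem(["a", "b", "c"], S0, [True, False, False])
        with pytest.raises(ValueError, match="initial values"):
            run_als(X, system, ConstraintSpec())


class TestAdmixtureMinimization:
    def test_strips_constructed_admixture_and_preserves_fit(self, toy_system):
        C, S, X = toy_system
        # build a mixed-but-equivalent solution: Inter column contaminated
        g = 0.04
        S_mix = S.copy()
        C_mix = C.copy()
        S_mix[:, 1] = (1 - g) * S[:, 1] + g * S[:, 0]
        C_mix[:, 1] = C[:, 1] / (1 - g)
        C_mix[:, 0] = C[:, 0] - g * C_mix[:, 1]
        np.testing.assert_allclose(C_mix @ S_mix.T, X, atol=1e-12)
        C2, S2 = minimize_spectral_admixture(
            C_mix, S_mix, unknown=[False, True, False], smooth_window=1
        )
        # fit preserved up to the tiny Gaussian-tail overlap (~1e-4)
        assert np.abs(C2 @ S2.T - X).max() < 1e-3 * X.max()
        np.testing.assert_allclose(C2.sum(1), C_mix.sum(1), atol=1e-10)
        cos = S2[:, 1] @ S[:, 1] / np.linalg.norm(S2[:, 1]) / np.linalg.norm(S[:, 1])
        assert cos > 1 - 1e-6

    def test_noop_at_extreme_point(self, toy_system):
        # the true Inter spectrum vanishes on the other components' supports,
        # so it is already extreme: nothing to strip
        C, S, X = toy_system
        C2, S2 = minimize_spectral_admixture(C, S, unknown=[False, True, False],
                                             smooth_window=1)
        assert np.abs(S2 - S).max() < 1e-3 * S.max()
        assert np.abs(C2 - C).max() < 1e-3
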