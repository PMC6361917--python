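"""Coordinate-descent solver: oracle equivalence, residual integrity,
paths, warm starts, and prediction."""

import warnings

import numpy as np
import pytest

from ctpr.penalty_core import PenaltySpec, lasso_update, objective_value
from ctpr.solver import (
    CoefficientState,
    FitData,
    PathSpec,
    fit,
    fit_path,
    lambda1_max,
    predict,
    prediction_r2,
    update_residual,
    zero_state,
)
from tests.conftest import standardized_design


def make_instance(rng, n=200, P=50, n_causal=5, sd=0.5):
    X = standardized_design(rng, n, P)
    beta = np.zeros(P)
    beta[rng.choice(P, n_causal, replace=False)] = rng.normal(0, sd, n_causal)
    y = X @ beta + rng.standard_normal(n)
    y -= y.mean()
    return X, y


class TestLambda1Max:
    def test_phenotype_equal_to_column(self, rng):
        X = standardized_design(rng, 100, 8)
        y = X[:, 3].copy()
        data = FitData([X], [y])
        assert lambda1_max(data) == pytest.approx(1.0, abs=1e-12)

    def test_zero_when_orthogonal(self, rng):
        X = standardized_design(rng, 50, 3)
        y = rng.standard_normal(50)
        y -= y.mean()
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        data = FitData([X], [y], check=False)
        assert lambda1_max(data) < 1e-10  # numerically orthogonal
        with pytest.warns(UserWarning, match="lambda1_max is 0"):
            assert lambda1_max(FitData([X], [np.zeros(50)], check=False)) == 0.0

    def test_fit_just_above_lambda1_max_is_all_zero(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = make_instance(r)
            data = FitData([X], [y])
            lam = lambda1_max(data) * 1.0001
            st = fit(data, PenaltySpec("lasso", lam))
            assert np.count_nonzero(st.beta) == 0
            assert st.converged


class TestFitAgainstReferenceSolver:
    @pytest.mark.parametrize("seed", range(5))
    def test_lasso_matches_sklearn(self, seed):
        from sklearn.linear_model import Lasso

        r = np.random.default_rng(seed)
        X, y = make_instance(r)
        data = FitData([X], [y])
        lam = 0.5 * lambda1_max(data)
        st = fit(data, PenaltySpec("lasso", lam), tol=1e-8)
        ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=200_000).fit(X, y)
        np.testing.assert_allclose(st.beta[0], ref.coef_, atol=1e-4)

    def test_orthonormal_design_closed_form(self, rng):
        # center first, then orthonormalize: Q spans a space orthogonal
        # to the 1-vector, so columns keep mean 0; rescale to sum(x^2)=n
        n, P = 64, 8
        A = rng.standard_normal((n, P))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(n)
        y = rng.standard_normal(n)
        y -= y.mean()
        data = FitData([X], [y], check=False)
        lam = 0.05
        st = fit(data, PenaltySpec("lasso", lam), tol=1e-10)
        expected = np.array([lasso_update(X[:, j] @ y / n, lam, 0.0, 0.0) for j in range(P)])
        np.testing.assert_allclose(st.beta[0], expected, atol=1e-8)

    def test_warm_start_from_fixed_point(self, rng):
        X, y = make_instance(rng)
        data = FitData([X], [y])
        spec = PenaltySpec("lasso", 0.05)
        st = fit(data, spec, tol=1e-6)
        st2 = fit(data, spec, init=st, tol=1e-6)
        assert st2.converged
        # a single verification cycle suffices at a fixed point
        assert st2.n_cycles - st.n_cycles == 1
        np.testing.assert_allclose(st2.beta, st.beta, atol=1e-8)


class TestResidualIntegrity:
    def test_noop_and_linearity(self, rng):
        X, y = make_instance(rng, n=50, P=10)
        data = FitData([X], [y])
        st = zero_state(data)
        before = st.residuals[0].copy()
        update_residual(st, data, 0, 3, 0.0, 0.0)
        np.testing.assert_array_equal(st.residuals[0], before)
        update_residual(st, data, 0, 3, 0.0, 0.7)
        np.testing.assert_allclose(st.residuals[0], before - 0.7 * X[:, 3], atol=1e-14)

    def test_drift_under_many_updates(self, rng):
        X, y = make_instance(rng, n=100, P=30)
        data = FitData([X], [y])
        st = zero_state(data)
        for _ in range(1000):
            j = int(rng.integers(30))
            new = float(rng.normal(0, 0.1))
            update_residual(st, data, 0, j, float(st.beta[0, j]), new)
        recomputed = y - X @ st.beta[0]
        assert np.abs(st.residuals[0] - recomputed).max() < 1e-8

    def test_stale_old_beta_rejected(self, rng):
        X, y = make_instance(rng, n=30, P=5)
        data = FitData([X], [y])
        st = zero_state(data)
        with pytest.raises(ValueError, match="old_beta"):
            update_residual(st, data, 0, 0, 0.5, 0.1)

    def test_residual_identity_after_fit(self, rng):
        X, y = make_instance(rng)
        data = FitData([X], [y])
        st = fit(data, PenaltySpec("lasso", 0.02), tol=1e-6)
        np.testing.assert_allclose(st.residuals[0], y - X @ st.beta[0], atol=1e-8)
        assert st.active_set == {(0, j) for j in np.nonzero(st.beta[0])[0]}


class TestPath:
    def test_single_point_at_lambda1_max(self, rng):
        X, y = make_instance(rng)
        data = FitData([X], [y])
        lam = lambda1_max(data) * 1.0001
        pts = fit_path(data, PathSpec(np.array([lam])), PenaltySpec("lasso", lam))
        assert np.count_nonzero(pts[0].state.beta) == 0

    def test_support_grows_down_the_path(self):
        drops = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, y = make_instance(r, n=120, P=40)
            data = FitData([X], [y])
            lam = lambda1_max(data)
            path = PathSpec.from_lambda1_max(lam, n_lambda1=10, ratio=0.05)
            pts = fit_path(data, path, PenaltySpec("lasso", lam))
            sizes = [np.count_nonzero(p.state.beta) for p in pts]
            drops += sum(a > b for a, b in zip(sizes, sizes[1:]))
        assert drops <= 2  # rare small drops tolerated

    def test_warm_equals_cold_for_lasso(self, rng):
        X, y = make_instance(rng)
        data = FitData([X], [y])
        lam = lambda1_max(data)
        path = PathSpec.from_lambda1_max(lam, n_lambda1=8, ratio=0.05)
        warm = fit_path(data, path, PenaltySpec("lasso", lam), tol=1e-8)
        for pt in warm:
            cold = fit(data, PenaltySpec("lasso", pt.lambda1), tol=1e-8)
            assert np.abs(cold.beta - pt.state.beta).max() < 1e-6


class TestCrossTraitStructure:
    def test_lambda2_zero_decouples_traits(self, rng):
        n, P = 80, 20
        Xs = [standardized_design(rng, n, P) for _ in range(2)]
        ys = []
        for X in Xs:
            y = X @ np.r_[rng.normal(0, 0.5, 3), np.zeros(P - 3)] + rng.standard_normal(n)
            ys.append(y - y.mean())
        joint = fit(FitData(Xs, ys), PenaltySpec("lasso", 0.05, lambda2=0.0), tol=1e-8)
        for k in range(2):
            solo = fit(FitData([Xs[k]], [ys[k]]), PenaltySpec("lasso", 0.05), tol=1e-8)
            np.testing.assert_allclose(joint.beta[k], solo.beta[0], atol=1e-10)

    def test_equal_rows_zero_cross_penalty(self, rng):
        # both traits identical data: coupled fit keeps rows equal, and
        # the cross-trait term at the solution is 0
        from ctpr.penalty_core import cross_trait_penalty_value

        X, y = make_instance(rng, n=60, P=15)
        st = fit(FitData([X, X], [y, y]), PenaltySpec("lasso", 0.05, lambda2=0.5), tol=1e-8)
        np.testing.assert_allclose(st.beta[0], st.beta[1], atol=1e-8)
        assert cross_trait_penalty_value(st.beta, None, 0.5) < 1e-14

    def test_anchors_pull_monotonically_with_lambda2(self, rng):
        X, y = make_instance(rng, n=100, P=20)
        anchors = rng.normal(0, 0.3, (1, 20))
        dists = []
        for lam2 in (0.0, 0.5, 1.0, 2.0, 4.0):
            data = FitData([X], [y], anchors=anchors)
            st = fit(data, PenaltySpec("lasso", 0.02, lambda2=lam2), tol=1e-8)
            dists.append(float(np.sum((st.beta[0] - anchors[0]) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(dists, dists[1:]))

    def test_objective_nonincreasing_across_cycles(self, rng):
        X, y = make_instance(rng)
        anchors = rng.normal(0, 0.2, (1, 50))
        data = FitData([X], [y], anchors=anchors)
        st = fit(data, PenaltySpec("lasso", 0.03, lambda2=0.4), track_objective=True)
        trace = st.objective_trace
        assert len(trace) >= 2
        assert all(b <= a + 1e-10 for a, b in zip(trace, trace[1:]))

    def test_mcp_fit_converges_and_gamma_guard(self, rng):
        X, y = make_instance(rng)
        data = FitData([X], [y])
        st = fit(data, PenaltySpec("mcp", 0.05, gamma=3.0), tol=1e-6)
        assert st.converged
        with pytest.raises(ValueError, match="gamma > 1"):
            PenaltySpec("mcp", 0.05, gamma=1.0)


class TestPredict:
    def test_perfect_and_affine_prediction(self, rng):
        y = rng.standard_normal(50)
        assert prediction_r2(y, y) == pytest.approx(1.0)
        assert prediction_r2(y, 3.0 + 2.0 * y) == pytest.approx(1.0)

    def test_constant_prediction_warns_zero(self, rng):
        y = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert prediction_r2(y, np.ones(50)) == 0.0

    def test_predict_applies_mean_offset(self, rng):
        X = standardized_design(rng, 30, 4)
        beta = rng.normal(0, 1, 4)
        np.testing.assert_allclose(predict(beta, X, y_mean=1.5), X @ beta + 1.5)

    def test_unstandardized_genotypes_rejected(self, geno_factory, rng):
        G = geno_factory()
        with pytest.raises(ValueError, match="standardize"):
            predict(rng.normal(0, 1, G.n_snps), G)
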