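"""Closed-form coordinate updates, penalty values, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from ctpr.penalty_core import (
    PenaltySpec,
    b_tilde,
    cross_trait_penalty_value,
    d_coeff,
    lasso_update,
    mcp_update,
    objective_value,
    sparsity_penalty_value,
    xi,
    zeta,
)

finite = st.floats(allow_nan=False, allow_infinity=False)


def _univariate_objective(beta, bt, lam1, lam2, gamma, d, kind):
    """Independent restatement of the one-coefficient problem:
    (1/2)(beta - b_tilde)^2 + p_sp(beta) + (lambda2/2) d beta^2."""
    quad = 0.5 * (beta - bt) ** 2 + 0.5 * lam2 * d * beta**2
    if kind == "lasso":
        return quad + lam1 * abs(beta)
    ab = abs(beta)
    if gamma * lam1 == 0.0:
        pen = 0.0
    elif ab <= gamma * lam1:
        pen = lam1 * ab - beta**2 / (2 * gamma)
    else:
        pen = gamma * lam1**2 / 2
    return quad + pen


class TestLassoUpdate:
    @pytest.mark.parametrize(
        "bt,lam1,lam2,d,expected",
        [
            (0.5, 0.2, 0.0, 0.0, 0.3),
            (0.1, 0.2, 5.0, 3.0, 0.0),
            (-0.5, 0.2, 1.0, 1.0, -0.15),
            (0.0, 0.0, 0.0, 0.0, 0.0),
            (1.0, 0.0, 1.0, 1.0, 0.5),
        ],
    )
    def test_hand_evaluated(self, bt, lam1, lam2, d, expected):
        assert lasso_update(bt, lam1, lam2, d) == pytest.approx(expected, abs=1e-15)

    def test_is_argmin_of_univariate_problem(self, rng):
        for _ in range(200):
            bt = rng.normal(0, 1)
            lam1, lam2, d = rng.uniform(0, 0.5), rng.uniform(0, 2), rng.uniform(0, 3)
            ours = lasso_update(bt, lam1, lam2, d)
            num = minimize_scalar(
                _univariate_objective, args=(bt, lam1, lam2, 3.0, d, "lasso"),
                bounds=(-10, 10), method="bounded", options={"xatol": 1e-12},
            ).x
            assert ours == pytest.approx(num, abs=1e-6)


class TestMcpUpdate:
    @pytest.mark.parametrize(
        "bt,lam1,lam2,gamma,d,expected",
        [
            (0.5, 0.2, 0.0, 3.0, 0.0, 0.45),  # inner region: 3*0.3/(3-1)
            (1.0, 0.2, 0.0, 3.0, 0.0, 1.0),  # outer region: unbiased
            (-0.5, 0.2, 0.0, 3.0, 0.0, -0.45),  # odd
            (0.15, 0.2, 0.0, 3.0, 0.0, 0.0),  # thresholded
        ],
    )
    def test_hand_evaluated(self, bt, lam1, lam2, gamma, d, expected):
        assert mcp_update(bt, lam1, lam2, gamma, d) == pytest.approx(expected, abs=1e-15)

    def test_gamma_limit_recovers_lasso(self, rng):
        # coefficient-scale inputs (|b| < 1), where the gamma = 1e6
        # approximation error is below 1e-6 absolutely
        for _ in range(100):
            bt = rng.uniform(-1, 1)
            lam1, lam2, d = rng.uniform(0, 0.5), rng.uniform(0, 2), rng.uniform(0, 3)
            assert mcp_update(bt, lam1, lam2, 1e6, d) == pytest.approx(
                lasso_update(bt, lam1, lam2, d), abs=1e-6
            )

    def test_degenerate_gamma_rejected(self):
        with pytest.raises(ValueError, match="non-convex"):
            mcp_update(0.5, 0.1, 0.0, 0.9, 0.0)

    def test_is_argmin_in_convex_regime(self, rng):
        for _ in range(200):
            bt = rng.normal(0, 1)
            lam1, lam2, d = rng.uniform(0, 0.5), rng.uniform(0, 2), rng.uniform(0, 3)
            gamma = rng.uniform(1.5, 10)
            if gamma * (1 + lam2 * d) <= 1:
                continue
            ours = mcp_update(bt, lam1, lam2, gamma, d)
            num = minimize_scalar(
                _univariate_objective, args=(bt, lam1, lam2, gamma, d, "mcp"),
                bounds=(-10, 10), method="bounded", options={"xatol": 1e-12},
            ).x
            assert ours == pytest.approx(num, abs=1e-5)


class TestUpdateInvariants:
    @settings(max_examples=300, deadline=None)
    @given(
        bt=st.floats(-5, 5),
        lam1=st.floats(0, 1),
        lam2=st.floats(0, 2),
        d=st.floats(0, 4),
        gamma=st.floats(1.2, 50),
    )
    def test_odd_nonexpansive_monotone(self, bt, lam1, lam2, d, gamma):
        for update in (
            lambda b: lasso_update(b, lam1, lam2, d),
            lambda b: mcp_update(b, lam1, lam2, gamma, d)
            if gamma * (1 + lam2 * d) > 1
            else None,
        ):
            out = update(bt)
            if out is None:
                continue
            assert update(-bt) == pytest.approx(-out, abs=1e-12)  # odd
            assert abs(out) <= abs(bt) / (1 + lam2 * d) + 1e-12  # non-expansive
            # monotone nondecreasing in b_tilde
            assert update(bt + 0.1) >= out - 1e-12


class TestBTildeComponents:
    def test_lambda2_zero_reduces_to_zeta(self, rng):
        x = rng.standard_normal(30)
        r = rng.standard_normal(30)
        z = zeta(x, r, 30)
        assert z == pytest.approx(float(x @ r) / 30)
        assert b_tilde(z, 0.0) == z
        assert xi(np.array([0.4]), np.array([]), np.array([1.0]), np.array([]), 0.0) == 0.0

    def test_single_anchor_arithmetic(self):
        # one primary trait, one anchor, a=1, lambda2=0.5, s=0.4, zeta=0.1
        x = xi(np.array([]), np.array([0.4]), np.array([]), np.array([1.0]), 0.5)
        assert b_tilde(0.1, x) == pytest.approx(0.3)
        assert d_coeff(np.array([]), np.array([1.0])) == 1.0

    def test_update_is_stationary_point_of_full_objective(self, rng):
        """The closed-form update must minimize the full objective as a
        function of one coordinate (numeric oracle over a grid)."""
        from tests.conftest import standardized_design

        n, P, K = 40, 4, 2
        Xs = [standardized_design(rng, n, P) for _ in range(K)]
        ys = [rng.standard_normal(n) for _ in range(K)]
        ys = [y - y.mean() for y in ys]
        anchors = rng.normal(0, 0.2, size=(1, P))
        beta = rng.normal(0, 0.3, size=(K, P))
        spec = PenaltySpec("lasso", lambda1=0.08, lambda2=0.4)
        k0, j0 = 1, 2
        # closed-form update for coordinate (k0, j0)
        r = ys[k0] - Xs[k0] @ beta[k0] + Xs[k0][:, j0] * beta[k0, j0]
        z = zeta(Xs[k0][:, j0], r, n)
        others = np.array([beta[k, j0] for k in range(K) if k != k0])
        x_val = xi(others, anchors[:, j0], np.ones(K - 1), np.ones(1), spec.lambda2)
        d = d_coeff(np.ones(K - 1), np.ones(1))
        closed = lasso_update(b_tilde(z, x_val), spec.lambda1, spec.lambda2, d)

        def obj(v):
            b = beta.copy()
            b[k0, j0] = v
            return objective_value(b, Xs, ys, spec, anchors)

        grid = np.linspace(closed - 0.05, closed + 0.05, 2001)
        vals = np.array([obj(v) for v in grid])
        assert abs(grid[vals.argmin()] - closed) < 1e-4
        assert obj(closed) <= vals.min() + 1e-12


class TestObjectiveValues:
    def test_zero_state(self, rng):
        from tests.conftest import standardized_design

        X = standardized_design(rng, 20, 3)
        y = rng.standard_normal(20)
        y -= y.mean()
        spec = PenaltySpec("lasso", 0.1, 0.5)
        val = objective_value(np.zeros((1, 3)), [X], [y], spec)
        assert val == pytest.approx(float(y @ y) / 40)

    def test_equal_rows_kill_pairwise_term(self, rng):
        beta = np.vstack([rng.standard_normal(5)] * 2)
        assert cross_trait_penalty_value(beta, None, 1.7) == 0.0

    def test_matches_brute_force_resummation(self, rng):
        K, M, P = 3, 2, 6
        beta = rng.standard_normal((K, P))
        S = rng.standard_normal((M, P))
        lam2 = 0.9
        ours = cross_trait_penalty_value(beta, S, lam2)
        brute = 0.0
        for k in range(K):
            for kp in range(k + 1, K):  # each unordered pair once
                for j in range(P):
                    brute += (beta[k, j] - beta[kp, j]) ** 2
        for k in range(K):
            for m in range(M):
                for j in range(P):
                    brute += (beta[k, j] - S[m, j]) ** 2
        assert ours == pytest.approx(lam2 / 2 * brute, rel=1e-12)

    def test_mcp_penalty_closed_form_matches_integral(self, rng):
        from scipy.integrate import quad

        spec = PenaltySpec("mcp", lambda1=0.3, gamma=2.5)
        kink = spec.gamma * spec.lambda1
        for t in (-1.2, -0.2, 0.0, 0.4, 0.74, 0.76, 2.0):
            numeric, _ = quad(
                lambda x: spec.lambda1 * max(0.0, 1 - x / kink),
                0.0,
                abs(t),
                points=[kink] if abs(t) > kink else None,
            )
            assert sparsity_penalty_value(np.array([[t]]), spec) == pytest.approx(
                numeric, abs=1e-10
            )

    def test_single_update_weakly_decreases_objective(self, rng):
        """1000 random single-coordinate updates, each must not increase
        the objective (Lasso always; MCP in the convex regime)."""
        from tests.conftest import standardized_design

        n, P, K = 30, 5, 2
        for trial in range(100):
            trial_rng = np.random.default_rng(trial)
            Xs = [standardized_design(trial_rng, n, P) for _ in range(K)]
            ys = [trial_rng.standard_normal(n) for _ in range(K)]
            ys = [y - y.mean() for y in ys]
            S = trial_rng.normal(0, 0.2, (1, P))
            kind = "lasso" if trial % 2 else "mcp"
            spec = PenaltySpec(kind, lambda1=0.05, lambda2=0.3, gamma=3.0)
            beta = trial_rng.normal(0, 0.3, (K, P))
            before = objective_value(beta, Xs, ys, spec, S)
            for _ in range(10):
                k0 = int(trial_rng.integers(K))
                j0 = int(trial_rng.integers(P))
                r = ys[k0] - Xs[k0] @ beta[k0] + Xs[k0][:, j0] * beta[k0, j0]
                z = zeta(Xs[k0][:, j0], r, n)
                others = np.array([beta[k, j0] for k in range(K) if k != k0])
                xv = xi(others, S[:, j0], np.ones(K - 1), np.ones(1), spec.lambda2)
                d = d_coeff(np.ones(K - 1), np.ones(1))
                beta[k0, j0] = spec.update(b_tilde(z, xv), d)
                after = objective_value(beta, Xs, ys, spec, S)
                assert after <= before + 1e-12
                before = after
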