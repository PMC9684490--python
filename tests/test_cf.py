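import numpy as np
import pytest

from grncf import (
    CFTargets,
    LatentFactors,
    PenaltyMatrices,
    cf_objective,
    fit_cf,
    init_factors,
    solve_unit_ball_qp,
    update_cf_targets,
    update_X,
    update_Y,
)
from grncf.cf import BALL_EPS


def _pen(C, Cbar, B):
    return PenaltyMatrices(C=np.asarray(C, float), Cbar=np.asarray(Cbar, float), B=np.asarray(B, float))


def _qp_objective(phi, varphi, v):
    return v @ phi @ v - varphi @ v


def _grid_min(phi, varphi, steps=400):
    """Dense polar grid search over the closed unit disk (h = 2 oracle)."""
    rad = np.linspace(0.0, 1.0, steps)
    ang = np.linspace(0.0, 2 * np.pi, steps, endpoint=False)
    R, T = np.meshgrid(rad, ang)
    V = np.stack([R * np.cos(T), R * np.sin(T)], axis=-1).reshape(-1, 2)
    vals = np.einsum("ki,ij,kj->k", V, phi, V) - V @ varphi
    k = int(np.argmin(vals))
    return V[k], float(vals[k])


class TestCFTargets:
    @pytest.mark.parametrize(
        "s, b, theta_exp, omega_exp",
        [(0.7, 0.0, 1.0, "cbar"), (0.0, 1.0, 1.0, "c"), (0.0, 0.0, 0.0, "c")],
    )
    def test_support_or_prior_cases(self, s, b, theta_exp, omega_exp):
        pen = _pen([[5.0]], [[9.0]], [[b]])
        t = update_cf_targets(np.array([[s]]), pen)
        assert t.Theta[0, 0] == theta_exp
        assert t.Omega[0, 0] == (9.0 if omega_exp == "cbar" else 5.0)


class TestCFObjective:
    def test_zero_factors(self):
        targets = CFTargets(Theta=np.array([[1.0, 0.0]]), Omega=np.array([[3.0, 2.0]]))
        f = LatentFactors(np.zeros((1, 2)), np.zeros((2, 2)))
        assert cf_objective(f, targets) == pytest.approx(3.0)

    def test_perfect_fit_is_zero(self):
        # Theta = x.y everywhere -> objective 0
        X = np.array([[1.0, 0.0]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        targets = CFTargets(Theta=np.array([[1.0, 0.0]]), Omega=np.array([[4.0, 4.0]]))
        assert cf_objective(LatentFactors(X, Y), targets) == 0.0

    @pytest.mark.parametrize("shape", [(3, 2), (7, 5), (20, 20)])
    def test_matches_double_loop_oracle(self, shape, rng):
        n, m = shape
        h = 3
        f = LatentFactors(rng.uniform(-0.5, 0.5, (n, h)), rng.uniform(-0.5, 0.5, (m, h)))
        targets = CFTargets(
            Theta=(rng.random((n, m)) < 0.5).astype(float), Omega=rng.uniform(1.0, 60.0, (n, m))
        )
        naive = 0.0
        for i in range(n):
            for j in range(m):
                naive += targets.Omega[i, j] * (targets.Theta[i, j] - f.X[i] @ f.Y[j]) ** 2
        assert cf_objective(f, targets) == pytest.approx(naive, rel=1e-10)


class TestUnitBallQP:
    def test_infeasible_stationary_point_lands_on_boundary(self):
        v = solve_unit_ball_qp(np.eye(2), np.array([4.0, 0.0]))
        np.testing.assert_allclose(v, [1.0, 0.0], atol=1e-7)

    def test_zero_linear_term_gives_origin(self):
        v = solve_unit_ball_qp(np.array([[2.0, 0.5], [0.5, 1.0]]), np.zeros(2))
        np.testing.assert_array_equal(v, 0.0)

    def test_interior_solution(self):
        v = solve_unit_ball_qp(np.eye(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(v, [0.5, 0.0], atol=1e-9)

    def test_matches_grid_search_on_random_instances(self, rng):
        for _ in range(20):
            A = rng.standard_normal((2, 2))
            phi = A @ A.T + rng.uniform(0.0, 0.5) * np.eye(2)
            varphi = rng.uniform(-3, 3, 2)
            v = solve_unit_ball_qp(phi, varphi)
            assert v @ v <= 1.0 + BALL_EPS
            _, best = _grid_min(phi, varphi)
            assert _qp_objective(phi, varphi, v) <= best + 1e-3

    def test_singular_phi_with_null_component(self):
        # phi has a zero eigenvalue and varphi points into the null space:
        # no interior stationary point; the solution sits on the boundary
        phi = np.diag([1.0, 0.0])
        v = solve_unit_ball_qp(phi, np.array([0.0, 2.0]))
        assert v @ v == pytest.approx(1.0, abs=1e-8)
        _, best = _grid_min(phi, np.array([0.0, 2.0]))
        assert _qp_objective(phi, np.array([0.0, 2.0]), v) <= best + 1e-3

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            solve_unit_ball_qp(np.array([[np.nan, 0], [0, 1.0]]), np.zeros(2))


class TestFactorUpdates:
    def _random_problem(self, rng, n=2, m=2, h=2):
        pen = _pen(
            rng.uniform(1, 20, (n, m)),
            rng.uniform(1, 30, (n, m)),
            (rng.random((n, m)) < 0.5).astype(float),
        )
        S = np.where(rng.random((n, m)) < 0.5, rng.uniform(-1, 1, (n, m)), 0.0)
        factors = init_factors(n, m, h, rng)
        targets = update_cf_targets(S, pen)
        return pen, S, factors, targets

    def test_lambda_zero_is_fixed_point(self, rng):
        pen, S, factors, targets = self._random_problem(rng)
        out = update_X(factors, targets, S, pen, lam=0.0)
        np.testing.assert_allclose(out.X, factors.X, atol=1e-9)
        out = update_Y(factors, targets, S, pen, lam=0.0)
        np.testing.assert_allclose(out.Y, factors.Y, atol=1e-9)

    def test_rows_stay_in_unit_ball(self, rng):
        pen, S, factors, targets = self._random_problem(rng, n=6, m=5, h=3)
        out = update_Y(update_X(factors, targets, S, pen, lam=2.0), targets, S, pen, lam=2.0)
        assert ((out.X**2).sum(axis=1) <= 1 + BALL_EPS).all()
        assert ((out.Y**2).sum(axis=1) <= 1 + BALL_EPS).all()

    def test_row_update_matches_bruteforce_prox(self, rng):
        """Each new x_i minimizes lam*sum_j Omega_ij (Theta_ij - x.y_j)^2
        + (mu/2)||x - x_old||^2 over the unit disk (grid-search oracle)."""
        lam = 1.5
        mu = 3.0
        pen, S, factors, targets = self._random_problem(rng)
        out = update_X(factors, targets, S, pen, lam=lam, mu_x=mu)
        s0 = (S != 0).astype(float)
        Omega = pen.C + (pen.Cbar - pen.C) * s0
        for i in range(2):
            def obj(x):
                cf = sum(
                    lam * Omega[i, j] * (targets.Theta[i, j] - x @ factors.Y[j]) ** 2
                    for j in range(2)
                )
                return cf + 0.5 * mu * ((x - factors.X[i]) ** 2).sum()

            rad = np.linspace(0, 1, 300)
            ang = np.linspace(0, 2 * np.pi, 300, endpoint=False)
            best = min(
                obj(np.array([r * np.cos(t), r * np.sin(t)])) for r in rad for t in ang
            )
            assert obj(out.X[i]) <= best + 1e-4

    def test_update_never_raises_prox_objective(self, rng):
        """Exact prox: F + (mu/2)||dX||^2 never exceeds the pre-update F."""
        pen, S, factors, targets = self._random_problem(rng, n=5, m=4, h=3)
        lam = 2.0
        for _ in range(3):
            before = cf_objective(factors, targets)
            out = update_X(factors, targets, S, pen, lam=lam)
            after = cf_objective(out, targets)
            drift = ((out.X - factors.X) ** 2).sum()
            assert lam * after + 0.5 * drift <= lam * before + 1e-9 * max(1.0, before)
            assert after <= before + 1e-9 * max(1.0, before)
            factors = out


class TestHeldOutRecovery:
    def test_masked_true_edges_score_above_never_true(self):
        """CF alone, fit on a block-structured observation with 20% of true
        edges masked, assigns masked true pairs a higher mean x.y than
        never-true pairs."""
        rng = np.random.default_rng(7)
        n, m, groups = 40, 8, 4
        gene_grp = np.repeat(np.arange(groups), n // groups)
        tf_grp = np.repeat(np.arange(groups), m // groups)
        true = (gene_grp[:, None] == tf_grp[None, :]).astype(float)
        ii, jj = np.nonzero(true)
        mask_idx = rng.choice(len(ii), size=int(0.2 * len(ii)), replace=False)
        B = true.copy()
        B[ii[mask_idx], jj[mask_idx]] = 0.0
        pen = _pen(1.0 + 60.0 * B, 1.0 + 60.0 * np.maximum(B, 1.0), B)
        factors = fit_cf(pen, h=8, rng=rng, sweeps=30)
        T = factors.dot()
        masked_mean = T[ii[mask_idx], jj[mask_idx]].mean()
        never_mean = T[true == 0].mean()
        assert masked_mean > never_mean
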