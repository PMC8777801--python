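"""Subproblem oracles and solver-level contracts for the DP-ADMM scheme."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from tvkl.admm import (
    ADMMState,
    SolverConfig,
    discrepancy_root,
    g_update,
    lambda_closed_form,
    posterior_mu_sweep,
    proposition1_check,
    run,
    tv_kl_objective,
    x_update,
    z_update,
)
from tvkl.discrepancy import PUBLISHED_FIT, DeltaSpec, kl_divergence
from tvkl.operators import DegradationModel, grad, grad_adjoint


def _config(variant="approximate", **kw):
    spec = (
        DeltaSpec("nearly_exact", params=PUBLISHED_FIT)
        if variant == "nearly_exact"
        else DeltaSpec(variant, **({"reference_lambda": kw.pop("ref")} if variant == "theoretical" else {}))
    )
    return SolverConfig(dp_variant=spec, **kw)


class TestGUpdate:
    def test_small_vectors_shrink_to_zero(self):
        w = np.zeros((2, 4, 4))
        w[0, 0, 0] = 0.5  # norm 0.5 <= 1/beta_g with beta_g = 1
        assert np.all(g_update(w, 1.0) == 0.0)

    def test_explicit_shrinkage_value(self):
        w = np.zeros((2, 1, 1))
        w[0, 0, 0] = 2.0
        out = g_update(w, 1.0)
        assert out[0, 0, 0] == pytest.approx(1.0)
        assert out[1, 0, 0] == 0.0

    def test_matches_numerical_minimizer(self, rng):
        """Per-pixel closed form vs direct 2-D minimization of |g| + (b/2)|g-w|^2."""
        for _ in range(100):
            w = rng.normal(0, 2, 2)
            beta = rng.uniform(0.3, 3.0)
            closed = g_update(w.reshape(2, 1, 1), beta).ravel()
            obj = lambda g: np.linalg.norm(g) + beta / 2 * np.sum((g - w) ** 2)
            num = minimize(obj, x0=w, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14}).x
            assert closed == pytest.approx(num, abs=5e-5)


class TestZUpdate:
    def test_componentwise_clipping(self):
        assert z_update(np.array([-1.0, 0.0, 2.0])) == pytest.approx([0.0, 0.0, 2.0])

    def test_identity_on_feasible_input(self, rng):
        q = rng.uniform(0, 5, 20)
        assert np.array_equal(z_update(q), q)

    def test_is_euclidean_projection(self, rng):
        """No feasible point is closer than the clipped vector."""
        for _ in range(50):
            q = rng.normal(0, 2, 6)
            z = z_update(q)
            others = np.abs(rng.normal(0, 2, (40, 6)))
            d_z = np.sum((z - q) ** 2)
            assert np.all(np.sum((others - q) ** 2) >= d_z - 1e-12)


def dense_operator(apply_fn, shape):
    n = shape[0] * shape[1]
    cols = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        cols.append(apply_fn(e.reshape(shape)).ravel())
    return np.array(cols).T


class TestXUpdate:
    def make_state(self, rng, model, shape):
        return ADMMState(
            x=rng.normal(0, 1, shape),
            lambda_=rng.uniform(0.1, 5, shape),
            g=rng.normal(0, 1, (2, *shape)),
            z=rng.uniform(0, 2, shape),
            rho_lambda=rng.normal(0, 1, shape),
            rho_g=rng.normal(0, 1, (2, *shape)),
            rho_z=rng.normal(0, 1, shape),
            gamma=1.0,
        )

    def test_matches_dense_solve_on_random_problems(self, rng):
        shape = (8, 8)
        n = 64
        for trial in range(5):
            psf = rng.uniform(0.1, 1.0, (3, 3))
            psf /= psf.sum()
            model = DegradationModel(psf=psf, background=0.1, shape=shape)
            cfg = _config(beta_lambda=rng.uniform(0.5, 2), beta_g=rng.uniform(0.5, 2),
                          beta_z=rng.uniform(0.5, 2))
            state = self.make_state(rng, model, shape)
            x = x_update(state, model, cfg)

            H = dense_operator(model.blur, shape)
            Dh = dense_operator(lambda im: np.roll(im, -1, 1) - im, shape)
            Dv = dense_operator(lambda im: np.roll(im, -1, 0) - im, shape)
            bl, bg, bz = cfg.beta_lambda, cfg.beta_g, cfg.beta_z
            A = Dh.T @ Dh + Dv.T @ Dv + (bl / bg) * H.T @ H + (bz / bg) * np.eye(n)
            rhs = (
                Dh.T @ (state.g[0] - state.rho_g[0] / bg).ravel()
                + Dv.T @ (state.g[1] - state.rho_g[1] / bg).ravel()
                + (bl / bg) * H.T @ (state.lambda_ - 0.1 - state.rho_lambda / bl).ravel()
                + (bz / bg) * (state.z - state.rho_z / bz).ravel()
            )
            dense = np.linalg.solve(A, rhs)
            assert x.ravel() == pytest.approx(dense, abs=1e-9)
            # linear-system residual contract
            res = np.linalg.norm(A @ x.ravel() - rhs) / np.linalg.norm(rhs)
            assert res <= 1e-10

    def test_consistency_fixed_point(self, rng):
        """With H = I, zero multipliers and subproblem data built from x0, x0 solves the system."""
        shape = (8, 8)
        x0 = rng.uniform(0.5, 2.0, shape)
        model = DegradationModel.identity(shape, background=0.3)
        cfg = _config(beta_lambda=1.0, beta_g=1.0, beta_z=1.0)
        state = ADMMState(
            x=x0, lambda_=x0 + 0.3, g=grad(x0), z=x0.copy(),
            rho_lambda=np.zeros(shape), rho_g=np.zeros((2, *shape)),
            rho_z=np.zeros(shape), gamma=1.0,
        )
        assert x_update(state, model, cfg) == pytest.approx(x0, abs=1e-10)


class TestLambdaClosedForm:
    def test_zero_gamma_is_positive_part(self):
        v = np.array([-2.0, 0.0, 3.5])
        y = np.array([1, 0, 2])
        assert lambda_closed_form(0.0, v, y) == pytest.approx([0.0, 0.0, 3.5])

    def test_large_gamma_tends_to_counts(self):
        out = lambda_closed_form(1e12, np.array([-3.0]), np.array([5]))
        assert out[0] == pytest.approx(5.0, rel=1e-5)

    def test_matches_golden_section_oracle(self, rng):
        for _ in range(100):
            gamma = rng.uniform(0.01, 20)
            v = rng.normal(0, 3)
            y = rng.integers(0, 10)
            closed = lambda_closed_form(gamma, np.array([v]), np.array([y]))[0]
            obj = lambda lam: gamma * (lam - y * np.log(lam) if y > 0 else lam) + 0.5 * (lam - v) ** 2
            num = minimize_scalar(obj, bounds=(1e-12, 100.0), method="bounded",
                                  options={"xatol": 1e-12}).x
            assert closed == pytest.approx(num, abs=1e-6)

    def test_rejects_negative_gamma(self):
        with pytest.raises(ValueError):
            lambda_closed_form(-1.0, np.zeros(1), np.zeros(1))


class TestProposition1:
    def test_all_zero_counts_never_admissible(self):
        ok, diag = proposition1_check(np.ones(10), np.zeros(10), PUBLISHED_FIT)
        assert not ok and not diag["any_counts"]

    def test_zero_intensity_with_counts_dominates(self):
        # v << 0 so t = 0 while some y_i >= 1: F(0; y) = +inf makes the sum pass
        v = np.full(9, -5.0)
        y = np.zeros(9)
        y[0] = 1
        ok, diag = proposition1_check(v, y, PUBLISHED_FIT)
        assert ok and diag["T_sum"] == float("inf")

    def test_admissible_implies_bracketable_root(self, rng):
        """Whenever the check passes, the expansion + bisection finds a root."""
        spec = DeltaSpec("nearly_exact", params=PUBLISHED_FIT)
        cfg = _config("nearly_exact", root_tol=1e-8)
        found = 0
        for trial in range(30):
            m = 64
            lam_true = rng.uniform(0.0, 6.0, m)
            y = rng.poisson(lam_true).astype(float)
            v = lam_true + rng.normal(0, 1.0, m)
            ok, _ = proposition1_check(v, y, PUBLISHED_FIT)
            if not ok:
                continue
            found += 1
            gamma = discrepancy_root(v, y, spec, cfg)
            assert gamma is not None and gamma >= 0
            lam = lambda_closed_form(gamma, v, y)
            d_val = kl_divergence(np.maximum(lam, 1e-12), y)
            from tvkl.discrepancy import delta_value
            assert abs(d_val - delta_value(spec, lam, y)) <= cfg.root_tol * m * 1.01
        assert found >= 5  # the scenario must actually exercise the branch


class TestDiscrepancyRoot:
    def test_accepted_root_satisfies_equation(self, rng):
        m = 256
        lam_true = rng.uniform(20.0, 60.0, m)
        y = rng.poisson(lam_true).astype(float)
        v = lam_true + rng.normal(0, 2.0, m)
        spec = DeltaSpec("approximate")
        cfg = _config(root_tol=1e-8)
        gamma = discrepancy_root(v, y, spec, cfg)
        lam = lambda_closed_form(gamma, v, y)
        assert kl_divergence(lam, y) == pytest.approx(m / 2, abs=cfg.root_tol * m * 1.01)

    def test_boundary_convention_returns_zero(self, rng):
        # v already fits the counts better than Delta requires
        y = rng.poisson(50.0, 100).astype(float)
        v = y.copy()  # D(0) = 0 < m/2
        spec = DeltaSpec("approximate")
        assert discrepancy_root(v, y, spec, _config()) == 0.0

    def test_discrepancy_monotone_decreasing_in_gamma(self, rng):
        m = 128
        lam_true = rng.uniform(1.0, 10.0, m)
        y = rng.poisson(lam_true).astype(float)
        v = lam_true + rng.normal(0, 1.0, m)
        gammas = np.logspace(-3, 3, 40)
        d_vals = [
            kl_divergence(np.maximum(lambda_closed_form(g, v, y), 1e-12), y)
            for g in gammas
        ]
        assert all(b <= a + 1e-8 for a, b in zip(d_vals, d_vals[1:]))

    def test_secant_variant_agrees_with_bisection(self, rng):
        m = 128
        lam_true = rng.uniform(2.0, 12.0, m)
        y = rng.poisson(lam_true).astype(float)
        v = lam_true + rng.normal(0, 1.0, m)
        spec = DeltaSpec("approximate")
        g_b = discrepancy_root(v, y, spec, _config(root_tol=1e-10))
        g_s = discrepancy_root(v, y, spec, _config(root_tol=1e-10, root_solver="secant"))
        assert g_s == pytest.approx(g_b, rel=1e-3)


class TestRun:
    def test_noiseless_identity_blur_returns_data(self):
        """With no blur, no background and self-consistent counts, the oracle
        discrepancy value is ~0, gamma grows large and the restoration hugs y."""
        rng = np.random.default_rng(0)
        x0 = rng.integers(20, 60, (32, 32)).astype(float)
        model = DegradationModel.identity((32, 32))
        cfg = _config("theoretical", ref=x0, max_iter=300)
        res = run(x0, model, cfg)
        rel = np.linalg.norm(res.x - x0) / np.linalg.norm(x0)
        assert rel < 0.05
        assert res.gamma > 10.0

    def test_constraint_residuals_vanish_at_convergence(self, mid_problem):
        """Classical ADMM feasibility at fixed gamma; the DP-driven run keeps the
        same residuals within a small multiple (re-selecting gamma each iteration
        perturbs the lambda update, so its feasibility floor is slightly higher)."""
        model, y = mid_problem["model"], mid_problem["y"]
        n = np.sqrt(y.size)

        fixed = _config(fixed_gamma=0.93, tol=1e-6, max_iter=3000)
        res = run(y, model, fixed)
        st = res.state
        assert res.converged
        assert np.linalg.norm(st.lambda_ - model.forward(st.x)) <= 1e-3 * n
        assert np.linalg.norm(st.g - grad(st.x)) <= 1e-3 * n
        assert np.linalg.norm(st.z - st.x) <= 1e-3 * n

        cfg = _config("nearly_exact", tol=1e-5, max_iter=1000)
        res = run(y, model, cfg)
        st = res.state
        assert res.converged
        assert np.linalg.norm(st.lambda_ - model.forward(st.x)) <= 2.5e-3 * n
        assert np.linalg.norm(st.g - grad(st.x)) <= 1e-3 * n
        assert np.linalg.norm(st.z - st.x) <= 1e-3 * n

    def test_final_discrepancy_residual_within_tolerance(self, small_problem):
        model, y = small_problem["model"], small_problem["y"]
        cfg = _config("approximate", tol=1e-4, max_iter=800, root_tol=1e-7)
        res = run(y, model, cfg)
        k, gamma, d_val, delta, eps_x, ok = res.trace[-1]
        assert abs(d_val - delta) <= cfg.root_tol * y.size * 1.01

    def test_fixed_mu_objective_nonincreasing(self, small_problem):
        """DP disabled: the ADMM should drive the TV-KL objective downhill."""
        model, y = small_problem["model"], small_problem["y"]
        mu = 1.0
        cfg = _config(fixed_gamma=mu, tol=1e-7, max_iter=150)
        # record objective along the run by replaying from the trace is not
        # possible; instead compare objective at increasing iteration budgets
        objs = []
        for iters in (10, 40, 150):
            cfg_i = _config(fixed_gamma=mu, tol=1e-12, max_iter=iters)
            res = run(y, model, cfg_i)
            objs.append(tv_kl_objective(res.x, y, model, mu))
        assert objs[1] <= objs[0] * (1 + 1e-6)
        assert objs[2] <= objs[1] * (1 + 1e-6)

    def test_rejects_negative_counts(self, small_problem):
        model = small_problem["model"]
        bad = -np.ones(model.shape)
        with pytest.raises(ValueError):
            run(bad, model, _config())


class TestPosteriorSweep:
    def test_sweep_agrees_with_iterated_selection(self, small_problem):
        """A fine-grid a-posteriori selection lands near the in-iteration root."""
        model, y = small_problem["model"], small_problem["y"]
        spec = DeltaSpec("nearly_exact", params=PUBLISHED_FIT)
        res = run(y, model, _config("nearly_exact", tol=1e-4, max_iter=800))
        grid = res.mu_hat * np.logspace(-0.8, 0.8, 9)
        sweep = posterior_mu_sweep(y, model, grid, spec, tol=1e-5, max_iter=400)
        assert sweep["mu_selected"] is not None
        assert abs(sweep["mu_selected"] - res.mu_hat) / res.mu_hat < 0.2
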