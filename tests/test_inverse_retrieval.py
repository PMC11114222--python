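"""ADMM/FISTA solver: operators, closed forms, and convergence behaviour."""

import numpy as np
import pytest

from sisifus.core import ConfigError, LifetimeImage, SamplingSpec, decimate_array, embed_adjoint
from sisifus.inverse_retrieval import (
    ADMMConfig,
    admm_reconstruct,
    div_Dt,
    evaluate_cost,
    fista_primal_update,
    grad_D,
    soft_threshold,
)
from sisifus.priors import PriorImage


class TestGradD:
    def test_constant_image_zero_gradient(self):
        assert not grad_D(np.full((5, 7), 3.0)).any()

    def test_ramp_gradient_slope(self):
        img = np.outer(np.arange(6, dtype=float) * 2.0, np.ones(6))
        g = grad_D(img)
        np.testing.assert_allclose(g[0, :-1, :], 2.0)
        assert not g[0, -1, :].any()  # Neumann trailing row
        assert not g[1].any()

    def test_adjoint_identity(self, rng):
        for _ in range(20):
            x = rng.normal(size=(6, 6))
            y = rng.normal(size=(2, 6, 6))
            lhs = np.sum(grad_D(x) * y)
            rhs = np.sum(x * div_Dt(y))
            assert abs(lhs - rhs) < 1e-12


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,t,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)]
    )
    def test_definition(self, v, t, expected):
        assert soft_threshold(np.array([v]), t)[0] == pytest.approx(expected)

    def test_zero_threshold_identity(self, rng):
        v = rng.normal(size=10)
        np.testing.assert_array_equal(soft_threshold(v, 0.0), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            soft_threshold(np.zeros(3), -1.0)

    def test_matches_grid_search_minimiser(self, rng):
        # z* = soft(g + y/rho, alpha/rho) minimises
        # alpha|z| + y (g - z) + rho/2 (g - z)^2 elementwise
        alpha, rho = 0.7, 1.3
        zgrid = np.linspace(-6, 6, 240001)
        for _ in range(20):
            g = float(rng.normal())
            y = float(rng.normal())
            vals = alpha * np.abs(zgrid) + y * (g - zgrid) + 0.5 * rho * (g - zgrid) ** 2
            brute = zgrid[np.argmin(vals)]
            closed = soft_threshold(np.array([g + y / rho]), alpha / rho)[0]
            assert abs(brute - closed) < 1e-4


def _dense_operator(shape, apply):
    n = shape[0] * shape[1]
    A = np.zeros((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        A[:, k] = apply(e.reshape(shape)).ravel()
    return A


class TestFistaPrimal:
    def test_constant_stationary_point(self):
        spec = SamplingSpec(factor=2)
        c = 2.0
        tau_lr = LifetimeImage(tau=np.full((4, 4), c))
        x0 = np.full((8, 8), c)
        cfg = ADMMConfig(gamma=0.0, beta=0.0, alpha=0.0, rho=1e-12, fista_iters=30)
        z = grad_D(x0)
        y = np.zeros_like(z)
        out = fista_primal_update(x0, z, y, tau_lr, None, None, spec, cfg)
        np.testing.assert_allclose(out, c, atol=1e-9)

    def test_matches_dense_linear_solve(self, rng):
        # quadratic-only objective (y = 0, z fixed): the minimiser solves
        # (2 A^T A + 2 gamma + 2 beta + rho D^T D) x = rhs
        spec = SamplingSpec(factor=2)
        shape = (8, 8)
        cfg = ADMMConfig(gamma=0.2, beta=0.3, alpha=0.0, rho=0.8, fista_iters=4000)
        tau_lr = LifetimeImage(tau=rng.uniform(2, 4, (4, 4)))
        lp = PriorImage(values=rng.uniform(2, 4, shape))
        gp = PriorImage(values=rng.uniform(2, 4, shape))
        x0 = rng.uniform(2, 4, shape)
        z = grad_D(x0)
        y = np.zeros_like(z)

        H = _dense_operator(
            shape,
            lambda v: 2.0 * embed_adjoint(decimate_array(v, spec), spec, shape)
            + 2.0 * cfg.gamma * v
            + 2.0 * cfg.beta * v
            + cfg.rho * div_Dt(grad_D(v)),
        )
        rhs = (
            2.0 * embed_adjoint(tau_lr.tau, spec, shape)
            + 2.0 * cfg.gamma * lp.values
            + 2.0 * cfg.beta * gp.values
            + cfg.rho * div_Dt(z)
        ).ravel()
        exact = np.linalg.solve(H, rhs).reshape(shape)
        assert exact.min() > 0  # constraint inactive: comparison is fair

        out = fista_primal_update(x0, z, y, tau_lr, lp, gp, spec, cfg)
        np.testing.assert_allclose(out, exact, rtol=1e-4)

    def test_objective_monotone_over_iterations(self, rng):
        spec = SamplingSpec(factor=2)
        tau_lr = LifetimeImage(tau=rng.uniform(1, 4, (6, 6)))
        x0 = rng.uniform(0, 5, (12, 12))
        z = grad_D(x0)
        y = rng.normal(size=z.shape)
        cfg = ADMMConfig(gamma=0.1, beta=0.5, alpha=0.01, rho=1.0, fista_iters=90)
        lp = PriorImage(values=rng.uniform(1, 4, (12, 12)))
        _, trace = fista_primal_update(
            x0, z, y, tau_lr, lp, None, spec, cfg, return_trace=True
        )
        assert np.all(np.diff(trace) <= 1e-10)


class TestEvaluateCost:
    def test_zero_fidelity_leaves_tv_only(self, rng):
        spec = SamplingSpec(factor=2)
        tau_lr = LifetimeImage(tau=rng.uniform(1, 3, (4, 4)))
        x = embed_adjoint(tau_lr.tau, spec, (8, 8))
        cfg = ADMMConfig(gamma=0.3, beta=0.4, alpha=0.05)
        priors = PriorImage(values=x.copy())
        cost = evaluate_cost(x, tau_lr, priors, priors, spec, cfg)
        assert cost == pytest.approx(cfg.alpha * np.abs(grad_D(x)).sum())

    def test_consistent_constant_zero_cost(self):
        spec = SamplingSpec(factor=2)
        c = 2.5
        tau_lr = LifetimeImage(tau=np.full((4, 4), c))
        x = np.full((8, 8), c)
        prior = PriorImage(values=x.copy())
        cost = evaluate_cost(x, tau_lr, prior, prior, spec, ADMMConfig(alpha=0.01))
        assert cost == pytest.approx(0.0, abs=1e-12)

    def test_term_by_term_hand_computation(self, rng):
        spec = SamplingSpec(factor=2)
        tau_lr = LifetimeImage(tau=rng.uniform(1, 3, (3, 3)))
        x = rng.uniform(0, 4, (6, 6))
        lp = PriorImage(values=rng.uniform(1, 3, (6, 6)), valid=rng.random((6, 6)) > 0.3)
        gp = PriorImage(values=rng.uniform(1, 3, (6, 6)), valid=rng.random((6, 6)) > 0.3)
        cfg = ADMMConfig(gamma=0.15, beta=0.25, alpha=0.07)
        # independent summation
        expect = 0.0
        for i in range(3):
            for j in range(3):
                expect += (x[2 * i, 2 * j] - tau_lr.tau[i, j]) ** 2
        for img, w in ((lp, cfg.gamma), (gp, cfg.beta)):
            for i in range(6):
                for j in range(6):
                    if img.valid[i, j]:
                        expect += w * (x[i, j] - img.values[i, j]) ** 2
        tv = 0.0
        for i in range(6):
            for j in range(6):
                if i < 5:
                    tv += abs(x[i + 1, j] - x[i, j])
                if j < 5:
                    tv += abs(x[i, j + 1] - x[i, j])
        expect += cfg.alpha * tv
        got = evaluate_cost(x, tau_lr, lp, gp, spec, cfg)
        assert got == pytest.approx(expect, rel=1e-12)


def _subgradient_oracle(tau_lr, lp, gp, spec, cfg, shape, iters=60000, seed=0):
    """Long-run projected subgradient descent on the fused cost."""
    rng = np.random.default_rng(seed)
    from sisifus.pipeline import bilinear_baseline

    x = bilinear_baseline(tau_lr, spec, shape).tau
    beta = cfg.resolved_beta(spec.factor)
    alpha = cfg.resolved_alpha(tau_lr)
    lr_mask = tau_lr.valid.astype(float)
    scale = max(float(np.abs(tau_lr.tau).max()), 1.0)
    best = evaluate_cost(x, tau_lr, lp, gp, spec, cfg)
    best_x = x.copy()
    for k in range(1, iters + 1):
        g = 2.0 * embed_adjoint((decimate_array(x, spec) - tau_lr.tau) * lr_mask, spec, shape)
        if lp is not None:
            g += 2.0 * cfg.gamma * lp.valid * (x - lp.values)
        if gp is not None:
            g += 2.0 * beta * gp.valid * (x - gp.values)
        g += alpha * div_Dt(np.sign(grad_D(x)))
        x = np.maximum(x - (0.05 * scale / np.sqrt(k)) * g, 0.0)
        c = evaluate_cost(x, tau_lr, lp, gp, spec, cfg)
        if c < best:
            best, best_x = c, x.copy()
    return best, best_x


class TestADMM:
    def test_all_constant_recovers_constant(self):
        spec = SamplingSpec(factor=2)
        c = 3.0
        tau_lr = LifetimeImage(tau=np.full((6, 6), c))
        prior = PriorImage(values=np.full((12, 12), c))
        cfg = ADMMConfig(admm_iters=5, fista_iters=30)
        out, state = admm_reconstruct(tau_lr, prior, prior, spec, cfg)
        np.testing.assert_allclose(out.tau, c, atol=1e-6)
        assert state.cost_trace[-1] < 1e-8

    def test_data_fidelity_only_interpolates_samples(self, rng):
        spec = SamplingSpec(factor=2)
        tau_lr = LifetimeImage(tau=rng.uniform(1, 4, (6, 6)))
        cfg = ADMMConfig(gamma=0.0, beta=0.0, alpha=0.0, admm_iters=5, fista_iters=200)
        out, _ = admm_reconstruct(tau_lr, None, None, spec, cfg)
        np.testing.assert_allclose(
            decimate_array(out.tau, spec), tau_lr.tau, atol=1e-6
        )
        assert out.tau.min() >= 0.0

    def test_tv_inpainting_preserves_step_edge(self, step_bundle):
        b = step_bundle
        tau_lr = b["tau_lr"]
        spec = b["sampling"]
        cfg = ADMMConfig(gamma=0.0, beta=0.0, admm_iters=20, fista_iters=90)
        out, _ = admm_reconstruct(tau_lr, None, None, spec, cfg)
        gt = b["tau_hr_gt"].tau
        edge_col = gt.shape[1] // 2
        # with only the data and TV terms, every monotone profile across the
        # single inter-sample gap is a minimiser, so the edge is localised to
        # within half the sampling pitch; the plateaus must be flat and exact
        mid = 0.5 * (2.0 + 4.0)
        crossings = np.argmax(out.tau > mid, axis=1)
        assert np.all(np.abs(crossings - edge_col) <= spec.factor // 2)
        np.testing.assert_allclose(out.tau[:, : edge_col - spec.factor], 2.0, atol=1e-2)
        np.testing.assert_allclose(out.tau[:, edge_col + spec.factor :], 4.0, atol=1e-2)
        assert np.all(np.diff(out.tau, axis=1) >= -1e-3)

    def test_nonnegative_and_monotone_cost(self, lp_exact_bundle, step_bundle):
        for b in (lp_exact_bundle, step_bundle):
            spec = b["sampling"]
            from sisifus.local_prior import build_local_prior

            lp = build_local_prior(b["tau_lr"], b["intensity_hr"], spec)
            out, state = admm_reconstruct(b["tau_lr"], lp, None, spec, ADMMConfig())
            assert out.tau.min() >= 0.0
            ct = state.cost_trace
            rel = np.diff(ct[2:]) / np.abs(ct[2:-1])
            assert np.all(rel <= 1e-6)
            assert state.primal_residual_trace[0] / state.primal_residual_trace[-1] >= 10.0

    def test_final_cost_matches_subgradient_oracle(self, rng):
        spec = SamplingSpec(factor=2)
        shape = (12, 12)
        tau_lr = LifetimeImage(tau=rng.uniform(1.5, 3.5, (6, 6)))
        lp = PriorImage(values=rng.uniform(1.5, 3.5, shape))
        # long iteration budget: this checks that the splitting converges to
        # the true optimum of the fused cost, not the production runtime
        cfg = ADMMConfig(gamma=0.1, beta=0.0, alpha=0.02, admm_iters=100, fista_iters=150)
        out, state = admm_reconstruct(tau_lr, lp, None, spec, cfg)
        admm_cost = evaluate_cost(out.tau, tau_lr, lp, None, spec, cfg)
        oracle_cost, _ = _subgradient_oracle(tau_lr, lp, None, spec, cfg, shape, iters=40000)
        assert admm_cost <= oracle_cost * 1.01
        assert admm_cost >= oracle_cost * 0.9
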