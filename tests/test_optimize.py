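import numpy as np
import pytest

import therapyopt as t
from therapyopt.objective import CostSpec, evaluate_functional
from therapyopt.optimize import (
    gradient,
    minimax_subgradient,
    project_to_admissible,
    project_to_tangent_cone,
    projected_gradient_descent,
    solve_adjoint,
)

from conftest import random_admissible_control


class TestProjections:
    def test_clamp(self):
        out = project_to_admissible(np.array([-0.2, 0.5, 1.3]))
        assert np.array_equal(out, [0.0, 0.5, 1.0])

    def test_idempotent_and_fixes_admissible(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 2, size=50)
        once = project_to_admissible(v)
        assert np.array_equal(project_to_admissible(once), once)
        u = rng.uniform(0, 1, size=50)
        assert np.array_equal(project_to_admissible(u), u)

    def test_tangent_cone_three_cases(self):
        u = np.array([0.0, 1.0, 0.5])
        v = np.array([-1.0, -1.0, -1.0])
        out = project_to_tangent_cone(v, u)
        assert np.array_equal(out, [0.0, -1.0, -1.0])
        out = project_to_tangent_cone(-v, u)
        assert np.array_equal(out, [1.0, 0.0, 1.0])

    def test_projected_step_identity(self):
        """Projecting the raw gradient step equals stepping along the
        tangent-cone-projected direction (boundary-touching controls)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            u = rng.choice([0.0, 1.0, 0.3, 0.7], size=40)
            g = rng.normal(size=40)
            eta = rng.uniform(0.01, 2.0)
            lhs = project_to_admissible(u - eta * g)
            rhs = project_to_admissible(u + eta * project_to_tangent_cone(-g, u))
            assert np.allclose(lhs, rhs, atol=1e-15)


class TestAdjoint:
    def test_terminal_condition_is_zero(self, fig_theta):
        control = t.ControlGrid.constant(0.5, 2.7)
        adj = solve_adjoint(control, fig_theta, CostSpec("hyperbolic", 0.5))
        assert np.array_equal(adj.g[-1], [0.0, 0.0])
        assert np.all(np.isfinite(adj.g))

    def test_gradient_assembles_from_single_member_adjoints(self):
        """Dual route: the kernel gradient equals the weighted per-member
        assembly built from the pure-Python adjoint paths."""
        ens = t.random_ensemble(2, seed=3)
        cost = CostSpec("linear", 0.5)
        rng = np.random.default_rng(6)
        control = random_admissible_control(rng, 80)
        G = gradient(control, ens, cost).values
        manual = np.zeros_like(G)
        for w, th in zip(ens.weights, ens.support):
            adj = solve_adjoint(control, th, cost)
            traj = t.simulate_open_loop(th, control)
            s = traj.s[:-1, 0]
            r = traj.r[:-1, 0]
            F1s = -th.d_hat_D * (1.0 - s - r) * s
            manual += w * adj.g[1:, 0] * F1s
        assert np.allclose(G, manual, rtol=1e-12, atol=1e-14)

    def test_gradient_linear_in_the_measure(self):
        thetas = t.random_ensemble(2, seed=8).support
        cost = CostSpec("hyperbolic", 0.5)
        control = t.ControlGrid.constant(0.4, 1.35)
        pair = t.EnsembleMeasure(thetas, [0.3, 0.7])
        g_pair = gradient(control, pair, cost).values
        g0 = gradient(control, t.EnsembleMeasure.singleton(thetas[0]), cost).values
        g1 = gradient(control, t.EnsembleMeasure.singleton(thetas[1]), cost).values
        assert np.allclose(g_pair, 0.3 * g0 + 0.7 * g1, rtol=1e-12, atol=1e-15)


def central_fd_gradient(control, ens, cost, eps=1e-6):
    """Finite-difference oracle for the discrete objective."""
    u = control.values
    h = control.step
    fd = np.empty_like(u)
    for k in range(len(u)):
        up = u.copy()
        up[k] += eps
        dn = u.copy()
        dn[k] -= eps
        Jp = evaluate_functional(t.ControlGrid(control.times, np.clip(up, 0, 1)), ens, cost).value
        Jm = evaluate_functional(t.ControlGrid(control.times, np.clip(dn, 0, 1)), ens, cost).value
        fd[k] = (Jp - Jm) / (2 * eps)
    return fd / h  # convert parameter derivative to the L2-Riesz field


class TestGradientOracle:
    @pytest.mark.parametrize("kind", ["linear", "hyperbolic"])
    def test_matches_central_finite_differences(self, kind):
        """The discrete adjoint is the exact gradient of the discrete
        functional; central differences agree to 1e-5 relative."""
        rng = np.random.default_rng(42)
        cost = CostSpec(kind, 0.5)
        for n_members in (1, 3):
            ens = t.random_ensemble(n_members, seed=n_members)
            for _ in range(3):
                # interior controls so the clipped FD stencil stays unbiased
                values = rng.uniform(0.05, 0.95, size=60)
                control = t.ControlGrid.from_values(values)
                G = gradient(control, ens, cost).values
                fd = central_fd_gradient(control, ens, cost)
                scale = np.abs(fd).max()
                assert np.allclose(G, fd, atol=1e-5 * scale)


class TestProjectedGradientDescent:
    def test_zero_iterations_returns_initial_guess(self, small_ensemble):
        run = projected_gradient_descent(
            small_ensemble, CostSpec("linear", 0.5), iterations=0, horizon=1.35
        )
        assert np.all(run.control.values == 0.5)
        assert len(run.objective_history) == 1

    def test_descent_with_reference_step(self, small_ensemble):
        run = projected_gradient_descent(
            small_ensemble, CostSpec("hyperbolic", 0.5), iterations=60, horizon=6.75
        )
        diffs = np.diff(run.objective_history)
        # projection can cause rare, tiny upward steps
        assert np.mean(diffs > 1e-12) <= 0.01
        assert run.final_value < run.objective_history[0]

    def test_iterates_stay_admissible(self, small_ensemble):
        run = projected_gradient_descent(
            small_ensemble, CostSpec("linear", 0.5), iterations=30, horizon=2.7,
            store_iterates=True,
        )
        for u in run.controls_history:
            assert u.min() >= 0.0 and u.max() <= 1.0

    def test_deterministic(self, small_ensemble):
        kwargs = dict(iterations=15, horizon=2.7)
        a = projected_gradient_descent(small_ensemble, CostSpec("hyperbolic", 0.5), **kwargs)
        b = projected_gradient_descent(small_ensemble, CostSpec("hyperbolic", 0.5), **kwargs)
        assert np.array_equal(a.control.values, b.control.values)
        assert np.array_equal(a.objective_history, b.objective_history)


class TestMinimaxSubgradient:
    def test_singleton_matches_averaged_descent(self, fig_theta):
        ens = t.EnsembleMeasure.singleton(fig_theta)
        kwargs = dict(iterations=25, horizon=2.7, store_iterates=True)
        mm = minimax_subgradient(ens, CostSpec("hyperbolic", 0.5), **kwargs)
        avg = projected_gradient_descent(ens, CostSpec("hyperbolic", 0.5), **kwargs)
        for ua, ub in zip(mm.controls_history, avg.controls_history):
            assert np.allclose(ua, ub, atol=1e-14)

    def test_worst_case_value_controlled_on_toy_ensemble(self):
        """On a smooth 2-member toy the worst-case value never jumps up
        by more than a step-size-bounded amount."""
        ens = t.random_ensemble(2, seed=21)
        run = minimax_subgradient(
            ens, CostSpec("hyperbolic", 0.5), iterations=40, horizon=0.675, eta=0.05
        )
        diffs = np.diff(run.objective_history)
        assert run.final_value <= run.objective_history[0] + 1e-12
        assert diffs.max() <= 0.05  # O(eta) bound on any single increase
        assert run.active_theta is not None
        assert set(run.active_theta) <= {0, 1}
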