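import numpy as np
import pytest

import therapyopt as t
from therapyopt.model import GeneralModelSpec, InvalidParameterError, SimplexGuardError


class TestNondimensionalize:
    def test_reference_rescaling(self):
        theta, T = t.nondimensionalize(
            r_S=0.027, r_R=0.027 * 0.66, d_D=0.75, d_T=0.0054,
            K=1e4, S0=4950.0, R0=50.0, T_hor=750.0,
        )
        assert T == pytest.approx(20.25, abs=1e-12)
        assert theta.d_hat_D == pytest.approx(1.5)
        assert theta.d_hat_T == pytest.approx(0.2)
        assert theta.r_hat_R == pytest.approx(0.66)
        assert theta.f_hat_0 == pytest.approx(0.01)
        assert theta.n0 == pytest.approx(0.5)

    def test_equal_rates_give_unit_ratio(self):
        theta, _ = t.nondimensionalize(0.03, 0.03, 0.5, 0.0, 1.0, 0.4, 0.1, 100.0)
        assert theta.r_hat_R == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [dict(r_S=0.0), dict(K=-1.0), dict(S0=2.0)])
    def test_invalid_inputs(self, bad):
        kwargs = dict(r_S=0.027, r_R=0.02, d_D=0.75, d_T=0.0, K=1.0,
                      S0=0.4, R0=0.1, T_hor=100.0)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            t.nondimensionalize(**kwargs)


class TestThetaTwoPop:
    def test_initial_state_split(self):
        th = t.ThetaTwoPop(1.5, 0.0, 0.66, 0.01, 0.5)
        s0, r0 = th.initial_state
        assert s0 == pytest.approx(0.495)
        assert r0 == pytest.approx(0.005)
        assert s0 + r0 == pytest.approx(th.n0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f_hat_0=1.5),
            dict(f_hat_0=-0.1),
            dict(n0=0.0),
            dict(n0=1.0),
            dict(r_hat_R=-1.0),
            dict(d_hat_D=np.nan),
        ],
    )
    def test_invalid_parameters(self, kwargs):
        base = dict(d_hat_D=1.5, d_hat_T=0.0, r_hat_R=0.66, f_hat_0=0.01, n0=0.5)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            t.ThetaTwoPop(**base)


class TestRhsTwoPop:
    def test_hand_evaluated_value(self):
        th = t.ThetaTwoPop(1.5, 0.0, 0.66, 0.01, 0.5)
        ds, dr = t.rhs_two_pop((0.495, 0.005), 1.0, th)
        assert ds == pytest.approx(-0.123750, abs=1e-12)
        assert dr == pytest.approx(0.001650, abs=1e-12)

    def test_extinction_is_fixed_point(self):
        th = t.ThetaTwoPop(1.5, 0.2, 0.8, 0.05, 0.3)
        assert t.rhs_two_pop((0.0, 0.0), 0.7, th) == (0.0, 0.0)

    def test_carrying_capacity_fixed_point_without_turnover(self):
        th = t.ThetaTwoPop(1.5, 0.0, 0.8, 0.05, 0.3)
        ds, dr = t.rhs_two_pop((0.6, 0.4), 0.3, th)
        assert ds == pytest.approx(0.0, abs=1e-15)
        assert dr == pytest.approx(0.0, abs=1e-15)

    def test_nan_state_rejected(self):
        th = t.ThetaTwoPop(1.5, 0.0, 0.8, 0.05, 0.3)
        with pytest.raises(t.InvalidStateError):
            t.rhs_two_pop((np.nan, 0.1), 0.5, th)


def two_species_spec(r_S=0.027, r_R=0.0178, d_D=0.75, d_T=0.002, K=1e4):
    return GeneralModelSpec(
        n_species=2,
        r=np.array([r_S, r_R]),
        K=K,
        d_I=np.array([d_D, 0.0]),
        d_T=np.array([d_T, d_T]),
        A=np.zeros((2, 2)),
        A_I=np.zeros((2, 2)),
        f=np.array([0.99, 0.01]),
        N0=0.5 * K,
        D_max=2.0,
    )


class TestRhsGeneral:
    def test_matches_two_population_specialization(self):
        """The 2-species model, rescaled, is exactly the dimensionless system."""
        spec = two_species_spec()
        theta, _ = t.nondimensionalize(
            r_S=0.027, r_R=0.0178, d_D=0.75, d_T=0.002, K=1e4,
            S0=0.99 * 5e3, R0=0.01 * 5e3, T_hor=100.0,
        )
        rng = np.random.default_rng(11)
        for _ in range(100):
            s, r = rng.uniform(0.0, 0.5, size=2)
            u = rng.uniform(0.0, 1.0)
            X = np.array([s, r]) * spec.K
            dX = t.rhs_general(X, u * spec.D_max, spec)
            ds, dr = t.rhs_two_pop((s, r), u, theta)
            expected = np.array([ds, dr])
            got = dX / (spec.K * 0.027)
            assert np.allclose(got, expected, rtol=1e-12, atol=1e-15)

    def test_zero_state_is_fixed(self):
        spec = two_species_spec()
        assert np.all(t.rhs_general(np.zeros(2), 1.0, spec) == 0.0)

    def test_transitions_conserve_total_mass(self):
        """Column-sum-zero transition matrices never change d/dt of the total."""
        rng = np.random.default_rng(3)
        n = 4
        for _ in range(20):
            A = rng.uniform(0.0, 1.0, size=(n, n))
            np.fill_diagonal(A, 0.0)
            A -= np.diag(A.sum(axis=0))
            A_I = rng.uniform(0.0, 1.0, size=(n, n))
            np.fill_diagonal(A_I, 0.0)
            A_I -= np.diag(A_I.sum(axis=0))
            f = rng.dirichlet(np.ones(n))
            spec = GeneralModelSpec(
                n_species=n, r=np.full(n, 0.03), K=1.0,
                d_I=np.array([1.0, 0.5, 0.2, 0.0]), d_T=np.zeros(n),
                A=A, A_I=A_I, f=f, N0=0.5, D_max=1.0,
            )
            base = GeneralModelSpec(
                n_species=n, r=np.full(n, 0.03), K=1.0,
                d_I=np.array([1.0, 0.5, 0.2, 0.0]), d_T=np.zeros(n),
                A=np.zeros((n, n)), A_I=np.zeros((n, n)), f=f, N0=0.5, D_max=1.0,
            )
            X = rng.uniform(0.0, 0.2, size=n)
            D = rng.uniform(0.0, 1.0)
            diff = t.rhs_general(X, D, spec) - t.rhs_general(X, D, base)
            assert abs(diff.sum()) < 1e-12

    def test_guard_radius(self):
        spec = two_species_spec()
        with pytest.raises(SimplexGuardError):
            t.rhs_general(np.array([3.0 * spec.K, 0.0]), 0.0, spec)

    @pytest.mark.parametrize(
        "mutate, fragment",
        [
            (lambda s: setattr(s, "A", np.array([[0.1, 0.0], [0.0, 0.0]])), "A"),
            (lambda s: setattr(s, "f", np.array([0.5, 0.4])), "f"),
            (lambda s: setattr(s, "N0", 2e4), "N0"),
            (lambda s: setattr(s, "d_I", np.array([-1.0, 0.0])), "d_I"),
        ],
    )
    def test_validation_names_the_invariant(self, mutate, fragment):
        spec = two_species_spec()
        mutate(spec)
        with pytest.raises(InvalidParameterError, match=fragment):
            spec.validate()


class TestEnsembles:
    def test_reference_grid_shape(self, grid_ensembles):
        ens = grid_ensembles[0.5]
        assert len(ens) == 1225
        assert np.allclose(ens.weights, 1.0 / 1225)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
        a = ens.arrays()
        assert a["r_hat_R"].min() == pytest.approx(0.5)
        assert a["r_hat_R"].max() == pytest.approx(1.0)
        assert a["f_hat_0"].min() == pytest.approx(0.002)
        assert a["f_hat_0"].max() == pytest.approx(0.1)
        assert np.all(a["d_hat_D"] == 1.5)
        assert np.all(a["d_hat_T"] == 0.0)

    def test_grid_warns_off_reference_burden(self):
        with pytest.warns(UserWarning):
            t.prostate_grid_ensemble(0.4)

    def test_random_ensemble_deterministic_and_in_box(self):
        a = t.random_ensemble(10, seed=0)
        b = t.random_ensemble(10, seed=0)
        assert [x.astuple() for x in a] == [y.astuple() for y in b]
        arr = a.arrays()
        assert np.all((arr["r_hat_R"] >= 0.5) & (arr["r_hat_R"] <= 1.0))
        assert np.all((arr["f_hat_0"] >= 0.002) & (arr["f_hat_0"] <= 0.1))

    def test_weight_validation(self):
        th = t.ThetaTwoPop(1.5, 0.0, 0.66, 0.01, 0.5)
        th2 = t.ThetaTwoPop(1.5, 0.0, 0.7, 0.01, 0.5)
        with pytest.raises(InvalidParameterError):
            t.EnsembleMeasure([th, th2], [0.6, 0.6])
        with pytest.raises(InvalidParameterError):
            t.EnsembleMeasure([th, th], [0.5, 0.5])
        with pytest.raises(InvalidParameterError):
            t.EnsembleMeasure([])
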