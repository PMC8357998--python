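"""Closed forms, CT<->DT conversion, equilibria, and shape classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import latentchange as lc
from latentchange import ShapeClass
from latentchange.model_spec import CTParameterSet, ParameterSet
from latentchange.simulate import TABLE1_DYNAMICS, fixture_config


def uni(mu0, mua, beta):
    return ParameterSet(mu0=[mu0], mua=[mua], phi=np.eye(2), beta=[beta], theta=[[0.5]])


class TestExponentialLevel:
    @pytest.mark.parametrize(
        "asymptote,initial,rate,time,expected",
        [
            (5.0, 0.0, 4.0, 1.0, 4.908422),
            (5.0, 10.0, -0.4, 1.0, 12.459124),
        ],
    )
    def test_frozen_values(self, asymptote, initial, rate, time, expected):
        assert lc.exponential_level(asymptote, initial, rate, time) == pytest.approx(
            expected, abs=1e-6
        )

    @given(
        st.floats(-20, 20),
        st.floats(-20, 20),
        st.floats(-3, 3),
    )
    def test_intercept_is_initial_level(self, asymptote, initial, rate):
        assert lc.exponential_level(asymptote, initial, rate, 0.0) == pytest.approx(
            initial, abs=1e-12
        )


class TestCTDerivative:
    def test_zero_at_equilibrium(self):
        ct = CTParameterSet(drift=[[-0.4]], ct_additive=[2.0])
        fp = -np.linalg.solve(ct.drift, ct.ct_additive)
        np.testing.assert_allclose(lc.ct_derivative(fp, ct), 0.0, atol=1e-12)

    @pytest.mark.parametrize("level,expected", [(0.0, 2.0), (10.0, -2.0)])
    def test_scalar_values(self, level, expected):
        ct = CTParameterSet(drift=[[-0.4]], ct_additive=[2.0])
        assert lc.ct_derivative([level], ct)[0] == pytest.approx(expected)

    def test_dimension_mismatch(self):
        ct = CTParameterSet(drift=[[-0.4]], ct_additive=[2.0])
        with pytest.raises(ValueError):
            lc.ct_derivative([1.0, 2.0], ct)


class TestAsymptoteIdentity:
    def test_additive_from_asymptote(self):
        assert lc.additive_from_asymptote(5.0, -0.4) == pytest.approx(2.0)

    def test_asymptote_from_additive(self):
        assert lc.asymptote_from_additive(2.0, -0.4) == pytest.approx(5.0)

    def test_zero_beta_has_no_asymptote(self):
        with pytest.raises(ZeroDivisionError):
            lc.asymptote_from_additive(2.0, 0.0)

    @given(st.floats(-10, 10), st.floats(0.05, 2.0), st.booleans())
    def test_mutual_inverses(self, asymptote, magnitude, negative):
        beta = -magnitude if negative else magnitude
        additive = lc.additive_from_asymptote(asymptote, beta)
        assert lc.asymptote_from_additive(additive, beta) == pytest.approx(
            asymptote, abs=1e-10
        )


class TestCTtoDT:
    def test_scalar_frozen_values(self):
        ct = CTParameterSet(drift=[[-0.4]], ct_additive=[2.0])
        A, a = lc.ct_to_dt(ct, 1.0)
        assert A[0, 0] == pytest.approx(-0.329680, abs=1e-6)
        assert a[0] == pytest.approx(1.648400, abs=1e-6)
        # the fixed point survives the metric change
        assert a[0] / -A[0, 0] == pytest.approx(5.0, abs=1e-10)

    def test_zero_drift_limit(self):
        ct = CTParameterSet(drift=[[0.0]], ct_additive=[2.0])
        A, a = lc.ct_to_dt(ct, 0.5)
        assert A[0, 0] == pytest.approx(0.0, abs=1e-14)
        assert a[0] == pytest.approx(1.0)

    def test_diagonal_drift_decouples(self):
        ct = CTParameterSet(drift=np.diag([-0.4, -0.9]), ct_additive=[2.0, 1.0])
        A, a = lc.ct_to_dt(ct, 1.0)
        for j, (b, add) in enumerate(zip([-0.4, -0.9], [2.0, 1.0])):
            A1, a1 = lc.ct_to_dt(CTParameterSet(drift=[[b]], ct_additive=[add]), 1.0)
            assert A[j, j] == pytest.approx(A1[0, 0], abs=1e-12)
            assert a[j] == pytest.approx(a1[0], abs=1e-12)
        assert A[0, 1] == A[1, 0] == 0.0

    def test_rejects_nonpositive_lag(self):
        ct = CTParameterSet(drift=[[-0.4]], ct_additive=[2.0])
        with pytest.raises(ValueError):
            lc.ct_to_dt(ct, 0.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            lc.ct_to_dt(CTParameterSet(drift=[[np.nan]], ct_additive=[1.0]), 1.0)


class TestDTtoCT:
    def test_scalar_round_trip(self):
        ct = lc.dt_to_ct([[-0.329679953964361]], [1.648399769821804], 1.0)
        assert ct.drift[0, 0] == pytest.approx(-0.4, abs=1e-9)
        assert ct.ct_additive[0] == pytest.approx(2.0, abs=1e-9)

    def test_zero_dynamics_gives_zero_drift(self):
        ct = lc.dt_to_ct([[0.0]], [1.5], 2.0)
        assert ct.drift[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert ct.ct_additive[0] == pytest.approx(0.75)

    def test_boundary_beta_minus_one_rejected(self):
        with pytest.raises(ValueError, match="negative real axis"):
            lc.dt_to_ct([[-1.0]], [1.0], 1.0)

    @given(
        st.floats(-0.9, 0.9),
        st.floats(-5, 5),
        st.floats(0.25, 2.0),
    )
    def test_round_trip_identity(self, beta_dt, a_dt, lag):
        ct = lc.dt_to_ct([[beta_dt]], [a_dt], lag)
        A, a = lc.ct_to_dt(ct, lag)
        assert A[0, 0] == pytest.approx(beta_dt, abs=1e-10)
        assert a[0] == pytest.approx(a_dt, abs=1e-10)

    def test_bivariate_round_trip(self):
        b = np.array([[-0.5, 0.2], [-0.1, -0.8]])
        a = np.array([1.0, -0.5])
        A, a_dt = lc.ct_to_dt(CTParameterSet(drift=b, ct_additive=a), 1.0)
        ct = lc.dt_to_ct(A, a_dt, 1.0)
        np.testing.assert_allclose(ct.drift, b, atol=1e-10)
        np.testing.assert_allclose(ct.ct_additive, a, atol=1e-10)


class TestDTCTEquivalence:
    """Iterating the discrete recursion on converted parameters must trace
    the exponential solution at integer multiples of the lag."""

    @pytest.mark.parametrize("rate,asymptote,initial", [
        (0.1, 5.0, 0.0), (0.5, -3.0, 4.0), (1.0, 5.0, 10.0), (2.5, 0.5, -8.0),
    ])
    def test_recursion_matches_exponential(self, rate, asymptote, initial):
        ct = CTParameterSet(drift=[[-rate]], ct_additive=[rate * asymptote])
        A, a = lc.ct_to_dt(ct, 1.0)
        level = initial
        for t in range(1, 11):
            level = level + A[0, 0] * level + a[0]
            assert level == pytest.approx(
                lc.exponential_level(asymptote, initial, rate, t), abs=1e-10
            )


class TestMeanTrajectory:
    def test_linear_regime_slope(self):
        traj = lc.mean_trajectory(lc.ModelSpec(n_occasions=5), uni(2.0, 0.5, 0.0), horizon=4)
        assert traj.levels[4, 0] == pytest.approx(4.0)
        np.testing.assert_allclose(np.diff(traj.levels[:, 0]), 0.5)

    def test_hand_recursion(self):
        traj = lc.mean_trajectory(lc.ModelSpec(n_occasions=4), uni(0.0, 1.0, -0.5), horizon=3)
        np.testing.assert_allclose(traj.levels[:, 0], [0.0, 1.0, 1.5, 1.75])

    def test_beta_minus_one_annihilates_history(self):
        traj = lc.mean_trajectory(lc.ModelSpec(n_occasions=6), uni(7.0, 2.0, -1.0), horizon=5)
        np.testing.assert_allclose(traj.levels[1:, 0], 2.0)

    def test_first_row_is_initial_means(self, biv_spec, biv_params):
        traj = lc.mean_trajectory(biv_spec, biv_params, horizon=3)
        np.testing.assert_allclose(traj.levels[0], biv_params.mu0)

    def test_rejects_zero_horizon(self, uni_spec, uni_params):
        with pytest.raises(ValueError):
            lc.mean_trajectory(uni_spec, uni_params, horizon=0)


class TestFixedPoint:
    def test_univariate_matches_asymptote(self):
        assert lc.fixed_point(uni(0.0, 2.0, -0.4))[0] == pytest.approx(5.0)
        assert lc.fixed_point(uni(0.0, 2.0, -0.4))[0] == pytest.approx(
            lc.asymptote_from_additive(2.0, -0.4)
        )

    def test_bivariate_linear_solve(self):
        params = ParameterSet(
            mu0=[0, 0], mua=[1, 1], phi=np.eye(4),
            beta=[0.3, -0.7], gamma=[0.6, -0.5], theta=np.eye(2),
        )
        np.testing.assert_allclose(
            lc.fixed_point(params), [14.4444, -8.8889], atol=1e-4
        )

    def test_singular_dynamics_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            lc.fixed_point(uni(0.0, 1.0, 0.0))

    def test_trajectory_started_at_fixed_point_stays(self, biv_params):
        fp = lc.fixed_point(biv_params)
        pinned = ParameterSet(
            mu0=fp, mua=biv_params.mua, phi=biv_params.phi,
            beta=biv_params.beta, gamma=biv_params.gamma, theta=biv_params.theta,
        )
        traj = lc.mean_trajectory(lc.ModelSpec(n_processes=2, n_occasions=4), pinned, horizon=10)
        np.testing.assert_allclose(traj.levels, np.tile(fp, (11, 1)), atol=1e-9)


class TestClassifyUnivariate:
    @pytest.mark.parametrize(
        "mu0,mua,beta,expected",
        [
            (0.0, 2.0, -0.4, ShapeClass.DECELERATED_GROWTH),
            (10.0, 2.0, -0.4, ShapeClass.DECELERATED_DECLINE),
            (10.0, 2.0, 0.4, ShapeClass.ACCELERATED_GROWTH),
            (-10.0, 2.0, 0.4, ShapeClass.ACCELERATED_DECLINE),
            (0.0, 1.0, 0.0, ShapeClass.LINEAR_GROWTH),
            (0.0, -1.0, 0.0, ShapeClass.LINEAR_DECLINE),
            (0.0, 0.0, 0.0, ShapeClass.CONSTANT),
            (5.0, 2.0, -0.4, ShapeClass.CONSTANT),  # starts at its asymptote
        ],
    )
    def test_shape_taxonomy(self, mu0, mua, beta, expected):
        assert lc.classify_univariate(uni(mu0, mua, beta)) is expected

    def test_growth_depends_on_position_not_additive_sign(self):
        """The same positive additive component yields growth or decline
        depending on which side of the asymptote the trajectory starts."""
        below = lc.classify_univariate(uni(0.0, 2.0, -0.4))   # asymptote 5 above
        above = lc.classify_univariate(uni(10.0, 2.0, -0.4))  # asymptote 5 below
        assert below is ShapeClass.DECELERATED_GROWTH
        assert above is ShapeClass.DECELERATED_DECLINE

    def test_rejects_bivariate_input(self, biv_params):
        with pytest.raises(ValueError):
            lc.classify_univariate(biv_params)


class TestClassifyBivariate:
    """The six canonical coupled regimes, classified by the eigenvalues of
    I + A: complex pair -> oscillation, spectral radius -> convergence."""

    @pytest.mark.parametrize(
        "column,oscillatory,convergent",
        [
            ("A", False, True),
            ("B", False, False),   # real eigenvalues 0.7 and 1.3
            ("C", True, True),     # complex pair, modulus sqrt(0.69)
            ("D", False, False),   # real eigenvalues 1.4 and 0.9
            ("E", True, False),
            ("F", True, True),
        ],
    )
    def test_canonical_regimes(self, column, oscillatory, convergent):
        _, params = fixture_config(f"table1_{column}")
        shape = lc.classify_bivariate(params)
        assert shape.oscillatory is oscillatory
        assert shape.convergent is convergent

    def test_explosive_oscillation_modulus(self):
        _, params = fixture_config("table1_E")
        shape = lc.classify_bivariate(params)
        assert shape.label is ShapeClass.OSCILLATORY_EXPLOSIVE
        assert shape.modulus == pytest.approx(np.sqrt(1.40), abs=1e-10)

    def test_damped_oscillation_modulus(self):
        _, params = fixture_config("table1_F")
        shape = lc.classify_bivariate(params)
        assert shape.label is ShapeClass.OSCILLATORY_DAMPED
        assert shape.modulus == pytest.approx(np.sqrt(0.78), abs=1e-10)

    def test_divergent_real_eigenvalues(self):
        _, params = fixture_config("table1_D")
        shape = lc.classify_bivariate(params)
        eigs = sorted(e.real for e in shape.eigenvalues)
        np.testing.assert_allclose(eigs, [0.9, 1.4], atol=1e-10)

    def test_decoupled_matches_univariate_classification(self):
        params = ParameterSet(
            mu0=[0.0, 10.0], mua=[2.0, 2.0], phi=np.eye(4),
            beta=[-0.4, 0.4], gamma=[0.0, 0.0], theta=np.eye(2),
        )
        shape = lc.classify_bivariate(params)
        assert shape.per_process == (
            lc.classify_univariate(uni(0.0, 2.0, -0.4)),
            lc.classify_univariate(uni(10.0, 2.0, 0.4)),
        )

    def test_rejects_univariate_input(self, uni_params):
        with pytest.raises(ValueError):
            lc.classify_bivariate(uni_params)
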