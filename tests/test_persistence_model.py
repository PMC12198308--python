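"""Unit and property tests for the segregational-loss / selection model."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from obelisktools.persistence_model import (
    DegenerateEigenvaluesError,
    SegregationParams,
    Trajectory,
    analytic_solution,
    analytic_state,
    analytic_states,
    crossing_time,
    dynamics_matrix,
    loss_probability,
    response_time,
    simulate,
    stability_threshold,
    sweep_response_time,
    type1_growth_rate,
)

# t* for r2=1, N=1, Nstar=2: r1=1/2, mu=1/2, eigen gap 3/4, hand-evaluable
T_STAR_HALF = math.log(4.0) / 0.75


class TestLossProbability:
    @pytest.mark.parametrize(
        "N, expected",
        [(0, 1.0), (1, 0.5), (2, 0.25), (10, 2.0 ** -10)],
    )
    def test_small_copy_numbers_exact(self, N, expected):
        assert loss_probability(N) == expected

    def test_matches_exact_rational_arithmetic(self):
        # independent oracle: exact rationals, converted to float at the end
        for N in range(0, 60):
            assert loss_probability(N) == float(Fraction(1, 2) ** N)

    def test_underflow_pair(self):
        smallest_subnormal = math.ulp(0.0)
        assert loss_probability(1074) == smallest_subnormal == 5e-324
        assert loss_probability(1075) == 0.0

    @pytest.mark.parametrize("bad", [-1, 2.5, "3", None, True])
    def test_invalid_copy_number_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            loss_probability(bad)

    def test_integral_float_accepted(self):
        assert loss_probability(3.0) == 0.125

    @given(N=st.integers(min_value=0, max_value=1200))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_nonincreasing(self, N):
        a, b = loss_probability(N), loss_probability(N + 1)
        assert b <= a
        if b > 0.0:
            assert b < a


class TestGrowthRate:
    @pytest.mark.parametrize(
        "r2, N, Nstar, expected",
        [(1.0, 0, 1000, 1.0), (1.0, 1000, 1000, 0.0), (1.0, 10, 1000, 0.99)],
    )
    def test_linear_burden(self, r2, N, Nstar, expected):
        assert type1_growth_rate(r2, N, Nstar) == pytest.approx(expected)

    def test_copy_number_above_capacity_rejected(self):
        with pytest.raises(ValueError):
            type1_growth_rate(1.0, 1001, 1000)


class TestSegregationParams:
    def test_derived_quantities(self, default_params):
        p = default_params
        assert p.mu == 2.0 ** -10
        assert p.alpha == pytest.approx(1e-3)
        assert p.r1 == pytest.approx(0.99)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=10, Nstar=10),       # violates N < Nstar
            dict(N=-1, Nstar=10),
            dict(N=1, Nstar=2, r2=0.0),
            dict(N=1, Nstar=2, r2=-1.0),
            dict(N=1, Nstar=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises((ValueError, TypeError)):
            SegregationParams(**kwargs)

    @given(
        N=st.integers(min_value=1, max_value=2000),
        extra=st.integers(min_value=1, max_value=3000),
        r2=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_eigenvalue_ordering_and_bounds(self, N, extra, r2):
        p = SegregationParams(N=N, Nstar=N + extra, r2=r2)
        assert 0.0 < p.r1 <= p.r2
        assert p.r1 * (1.0 - p.mu) < p.r2  # eigen1 < eigen2 for N >= 1
        assert 0.0 <= p.mu <= 0.5


class TestDynamicsMatrix:
    def test_default_entries(self, default_params):
        A = dynamics_matrix(default_params)
        assert A[0, 0] == pytest.approx(0.989033203125, abs=0, rel=1e-15)
        assert A[1, 0] == pytest.approx(0.000966796875, abs=0, rel=1e-15)
        assert A[0, 1] == 0.0
        assert A[1, 1] == 1.0

    def test_all_loss_limit(self):
        # N = 0: every carrier birth is element-free (mu == 1)
        A = dynamics_matrix(SegregationParams(N=0, Nstar=1000))
        assert A[0, 0] == 0.0
        assert A[1, 0] == pytest.approx(1.0)

    @given(
        N=st.integers(min_value=0, max_value=1100),
        extra=st.integers(min_value=1, max_value=2000),
        r2=st.floats(min_value=0.01, max_value=10.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_birth_events_conserved(self, N, extra, r2):
        """Both daughter classes of a carrier birth sum exactly to r1."""
        p = SegregationParams(N=N, Nstar=N + extra, r2=r2)
        A = dynamics_matrix(p)
        assert A[0, 0] + A[1, 0] == pytest.approx(p.r1, rel=1e-15)
        assert A[0, 1] == 0.0  # element-free cells never regain copies


class TestSimulate:
    def test_initial_condition(self, default_params):
        traj = simulate(default_params, t_end=1.0, n_points=11)
        assert traj.states[0] == pytest.approx([1.0, 0.0])

    def test_matrix_exponential_oracle(self, default_params):
        """Independent route: x(t) = expm(A t) @ x0."""
        A = dynamics_matrix(default_params)
        traj = simulate(default_params, t_end=30.0, n_points=31)
        for i in [5, 15, 30]:
            expected = expm(A * traj.times[i]) @ np.array([1.0, 0.0])
            assert traj.states[i] == pytest.approx(expected, rel=1e-7)

    def test_type2_frequency_monotone_to_one(self, default_params):
        traj = simulate(default_params, t_end=600.0, n_points=601)
        f2 = traj.frequencies[:, 1]
        assert np.all(np.diff(f2) >= -1e-12)
        # relaxation to fixation goes as exp((r2 - r1(1-mu)) t); use the
        # fast-relaxing N=1 parameterisation to see it within double range
        fast = simulate(SegregationParams(N=1, Nstar=2), t_end=30.0,
                        n_points=301)
        assert fast.frequencies[-1, 1] > 0.999

    def test_frequencies_sum_to_one(self, default_params):
        traj = simulate(default_params, t_end=100.0, n_points=101)
        assert traj.frequencies.sum(axis=1) == pytest.approx(
            np.ones(101), abs=1e-9
        )

    def test_half_crossing_matches_closed_form(self, default_params):
        traj = simulate(default_params, t_end=280.0, n_points=8001)
        t_cross = crossing_time(traj)
        assert t_cross == pytest.approx(229.1575, rel=1e-3)
        f2 = traj.frequencies[:, 1]
        i = int(np.searchsorted(traj.times, t_cross))
        assert f2[i] == pytest.approx(0.5, abs=1e-3)

    def test_past_threshold_no_type2_ever(self):
        p = SegregationParams(N=stability_threshold(), Nstar=2000)
        traj = simulate(p, t_end=500.0, n_points=101)
        assert np.all(traj.x2 == 0.0)

    @pytest.mark.parametrize(
        "kwargs", [dict(t_end=-1.0), dict(n_points=1), dict(x0=(0.0, 0.0)),
                   dict(x0=(-1.0, 1.0))]
    )
    def test_invalid_inputs_rejected(self, default_params, kwargs):
        with pytest.raises(ValueError):
            simulate(default_params, **{"t_end": 1.0, "n_points": 5, **kwargs})


class TestAnalyticSolution:
    def test_reproduces_initial_condition(self, default_params):
        state = analytic_state(default_params, 0.0)
        assert (state.x1, state.x2) == (1.0, 0.0)

    def test_constants(self, default_params):
        sol = analytic_solution(default_params)
        assert sol.c1 == -1.0
        assert sol.eigen2 == default_params.r2
        assert sol.eigen1 == default_params.r1 * (1 - default_params.mu)
        denom = sol.eigen2 - sol.eigen1
        assert sol.c2 == default_params.r1 * default_params.mu / denom

    def test_equal_abundances_at_response_time(self):
        p = SegregationParams(N=1, Nstar=2)
        state = analytic_state(p, T_STAR_HALF)
        assert state.x1 == pytest.approx(state.x2, rel=1e-12)

    def test_decoupled_when_mu_underflows(self):
        p = SegregationParams(N=1075, Nstar=2000, r2=1.0)
        for t in [0.5, 3.0, 10.0]:
            state = analytic_state(p, t)
            assert state.x2 == 0.0
            assert state.x1 == pytest.approx(math.exp(p.r1 * t), rel=1e-12)

    def test_agrees_with_ode_solver(self, default_params):
        t_grid = np.geomspace(0.5, 250.0, 50)
        traj = simulate(default_params, t_grid=t_grid,
                        atol=np.array([1e-12, 1e-15]))
        ana = analytic_states(default_params, t_grid)
        rel = np.abs(traj.states - ana) / np.abs(ana)
        assert rel.max() < 1e-6


class TestResponseTime:
    def test_hand_evaluable_case(self):
        assert response_time(SegregationParams(N=1, Nstar=2)) == pytest.approx(
            T_STAR_HALF, rel=1e-12
        )

    def test_default_parameterisation(self, default_params):
        assert response_time(default_params) == pytest.approx(229.1575, rel=1e-4)

    def test_high_precision_oracle(self, default_params):
        """Closed form evaluated in 50-digit arithmetic via sympy."""
        import sympy

        r2 = sympy.Integer(1)
        r1 = sympy.Rational(99, 100)
        mu = sympy.Rational(1, 2) ** 10
        delta = r2 - r1 * (1 - mu)
        expected = float((sympy.log(1 + delta / (r1 * mu)) / delta).evalf(50))
        assert response_time(default_params) == pytest.approx(expected, rel=1e-13)

    def test_strictly_increasing_in_copy_number(self):
        times = [response_time(SegregationParams(N=n, Nstar=1000))
                 for n in (10, 20, 100, 800)]
        assert times == sorted(times)
        assert len(set(times)) == 4

    def test_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            response_time(SegregationParams(N=0, Nstar=10))

    def test_underflowed_loss_rate_gives_infinity(self):
        assert response_time(SegregationParams(N=1075, Nstar=2000)) == math.inf

    def test_finite_just_below_threshold_despite_subnormal_mu(self):
        # at N=1074 mu is the smallest subnormal; t* is finite and huge
        p = SegregationParams(N=1074, Nstar=5000)
        t = response_time(p)
        assert math.isfinite(t)
        # oracle: t* = (log(delta) - log(r1*mu)) / delta in exact arithmetic
        import sympy

        r1 = sympy.Rational(p.r2) * (1 - sympy.Rational(p.N, p.Nstar))
        mu = sympy.Rational(1, 2) ** p.N
        delta = sympy.Rational(p.r2) - r1 * (1 - mu)
        expected = float((sympy.log(1 + delta / (r1 * mu)) / delta).evalf(40))
        # r1*mu rounds to a subnormal in doubles, so expect ~1 digit of slack
        assert t == pytest.approx(expected, rel=0.05)


class TestCrossingTime:
    def test_matches_closed_form(self):
        p = SegregationParams(N=1, Nstar=2)
        traj = simulate(p, t_end=2.5, n_points=5001)
        assert crossing_time(traj) == pytest.approx(T_STAR_HALF, rel=1e-6)

    def test_not_reached_when_no_source(self):
        p = SegregationParams(N=1075, Nstar=2000)
        traj = simulate(p, t_end=50.0, n_points=51)
        assert crossing_time(traj) is None

    def test_immediate_crossing_interpolates_toward_zero(self, default_params):
        times = np.array([0.0, 1.0, 2.0])
        states = np.array([[1.0, 0.0], [1.0, 3.0], [1.0, 9.0]])
        traj = Trajectory(params=default_params, times=times, states=states)
        # bracketing samples are (0, -1) and (1, +2): root at t = 1/3
        assert crossing_time(traj) == pytest.approx(1.0 / 3.0)


class TestStabilityThreshold:
    def test_value_and_minimality(self):
        n = stability_threshold()
        assert n == 1075
        assert loss_probability(n - 1) > 0.0
        assert loss_probability(n) == 0.0


class TestSweep:
    def test_increasing_in_capacity(self):
        table = sweep_response_time([10], [20, 200, 400, 600])
        assert list(table.columns)[:6] == ["N", "Nstar", "r1", "mu", "t_star",
                                           "stable"]
        t = table["t_star"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert not table["stable"].any()

    def test_stable_sentinel_past_threshold(self):
        table = sweep_response_time([1075], [2000])
        row = table.iloc[0]
        assert bool(row["stable"])
        assert math.isnan(row["t_star"])
        assert row["mu"] == 0.0

    def test_single_pair(self):
        table = sweep_response_time([1], [2])
        assert len(table) == 1
        assert table["t_star"].iloc[0] == pytest.approx(T_STAR_HALF, rel=1e-12)

    def test_invalid_pair_recorded_not_fatal(self):
        table = sweep_response_time([10, 30], [20])
        assert len(table) == 2
        ok = table[table["error"] == ""]
        bad = table[table["error"] != ""]
        assert len(ok) == 1 and len(bad) == 1
        assert bad.iloc[0]["N"] == 30  # 30 >= Nstar=20 is invalid
        assert math.isnan(bad.iloc[0]["t_star"])
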