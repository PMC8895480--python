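import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import linprog

from hurosim.design import (
    InfeasibleDesignError,
    PlateLoadCase,
    PressureProfile,
    StiffnessProfile,
    analytic_optimum,
    analytic_peak,
    design_sweep,
    optimal_bias_force,
    padding_stiffness,
    peak_pressure_cost,
    simulate_discrete_interface,
)
from hurosim.materials import series_elastic

L = 0.05


def lp_min_peak(case: PlateLoadCase, n=15):
    """LP oracle: minimise the max of n free pressure points under force and
    moment balance."""
    s = case.L / n
    x = (np.arange(n) - (n - 1) / 2) * s
    c = np.zeros(n + 1)
    c[-1] = 1.0
    A_ub = np.hstack([np.eye(n), -np.ones((n, 1))])
    A_eq = np.array([np.r_[np.ones(n) * s, 0.0], np.r_[x * s, 0.0]])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(n),
        A_eq=A_eq,
        b_eq=[case.F_total, case.M_L],
        bounds=[(0, None)] * (n + 1),
    )
    assert res.success
    return res.fun


class TestPeakPressureCost:
    def test_uniform(self):
        p = PressureProfile(np.linspace(-1, 1, 5), np.full(5, 7.0), 0.5)
        assert peak_pressure_cost(p) == 7.0

    def test_two_region_takes_higher(self):
        p = PressureProfile(np.linspace(-1, 1, 4), [1.0, 1.0, 3.0, 3.0], 0.5)
        assert peak_pressure_cost(p) == 3.0

    @given(st.lists(st.floats(0.0, 50.0), min_size=3, max_size=30))
    def test_equals_direct_scan(self, values):
        arr = np.array(values)
        p = PressureProfile(np.arange(arr.size, dtype=float), arr, 1.0)
        assert peak_pressure_cost(p) == max(values)


class TestAnalyticOptimum:
    def test_printed_formula_example(self):
        # x = M/(F_L+F_b) = 0.0125 m; P_peak = 40/(0.05-0.025) = 1600 N/m
        prof = analytic_optimum(PlateLoadCase(10.0, 0.5, 30.0, L))
        assert prof.center_high_region == pytest.approx(0.0125)
        assert prof.peak == pytest.approx(1600.0)
        assert prof.total_force() == pytest.approx(40.0, rel=1e-9)
        assert prof.total_moment() == pytest.approx(0.5, rel=1e-3)

    def test_zero_moment_degenerates_to_uniform(self):
        prof = analytic_optimum(PlateLoadCase(10.0, 0.0, 5.0, L))
        assert prof.peak == pytest.approx(15.0 / L)
        assert np.allclose(prof.pressures, prof.peak)

    def test_clockwise_moment_mirrors(self):
        ccw = analytic_optimum(PlateLoadCase(10.0, 0.5, 30.0, L))
        cw = analytic_optimum(PlateLoadCase(10.0, -0.5, 30.0, L))
        assert np.allclose(cw.pressures, ccw.pressures[::-1])

    def test_infeasible_advises_bias(self):
        with pytest.raises(InfeasibleDesignError, match="bias"):
            analytic_optimum(PlateLoadCase(1.0, 0.5, 0.0, L))

    def test_matches_lp_oracle_within_discretisation(self):
        case = PlateLoadCase(10.0, 0.5, 30.0, L)
        lp = lp_min_peak(case, n=15)
        exact = analytic_peak(case)
        s = L / 15
        upper = case.F_total / (L - 2 * abs(case.M_L / case.F_total) - 2 * s)
        assert exact - 1e-9 <= lp <= upper

    @given(
        F_L=st.floats(1.0, 30.0),
        M=st.floats(0.0, 0.4),
        F_b=st.floats(0.0, 60.0),
    )
    def test_balance_invariants(self, F_L, M, F_b):
        case = PlateLoadCase(F_L, M, F_b, L)
        if abs(M / case.F_total) >= L / 2 * 0.98:
            return
        prof = analytic_optimum(case, n_points=801)
        assert prof.total_force() == pytest.approx(case.F_total, rel=1e-9)
        assert prof.total_moment() == pytest.approx(M, abs=2e-4 * max(1.0, abs(M)) + 1e-5)
        assert np.all(prof.pressures >= 0.0)


class TestOptimalBiasForce:
    def test_printed_example(self):
        assert optimal_bias_force(10.0, 0.5, L) == pytest.approx(30.0)

    def test_zero_moment_clamps(self):
        assert optimal_bias_force(10.0, 0.0, L) == 0.0

    def test_grid_search_lands_on_formula(self):
        # brute-force sweep of the closed-form peak over the bias force
        F_L, M = 10.0, 0.5
        grid = np.arange(22.0, 60.01, 0.5)
        peaks = [analytic_peak(PlateLoadCase(F_L, M, fb, L)) for fb in grid]
        assert grid[int(np.argmin(peaks))] == pytest.approx(
            optimal_bias_force(F_L, M, L), abs=0.5
        )


class TestDiscreteInterface:
    def test_uniform_springs_no_moment(self):
        n, k = 15, 700.0
        prof = StiffnessProfile(k, k, L, n)
        case = PlateLoadCase(10.0, 0.0, 30.0, L)
        pressure, rel, tilt = simulate_discrete_interface(prof, case)
        assert tilt == pytest.approx(0.0, abs=1e-12)
        assert rel == pytest.approx(case.F_total / (n * k), rel=1e-9)
        assert np.allclose(pressure.pressures, pressure.pressures[0])

    def test_three_spring_moment_couple(self):
        # symmetric 3-point row: outer force difference carries the moment,
        # f_hi - f_lo = 2 M / (2 s) with s the outer lever arm
        prof = StiffnessProfile(500.0, 500.0, L, 3)
        case = PlateLoadCase(0.0, 0.05, 30.0, L)
        pressure, _, _ = simulate_discrete_interface(prof, case)
        s_cell = L / 3
        forces = pressure.pressures * s_cell
        lever = prof.positions()[-1]
        assert forces[-1] - forces[0] == pytest.approx(0.05 / lever, rel=1e-9)

    def test_all_released_is_error(self):
        prof = StiffnessProfile(700.0, 700.0, L, 15)
        with pytest.raises(InfeasibleDesignError):
            simulate_discrete_interface(prof, PlateLoadCase(0.1, 0.5, 0.0, L))

    @given(
        F_b=st.floats(5.0, 60.0),
        M=st.floats(0.0, 0.3),
        g_frac=st.floats(0.0, 0.9),
    )
    def test_force_and_moment_balance(self, F_b, M, g_frac):
        mean_k = 700.0
        prof = StiffnessProfile.from_gradient(mean_k, g_frac * 4 * mean_k / L, L)
        case = PlateLoadCase(10.0, M, F_b, L)
        pressure, _, _ = simulate_discrete_interface(prof, case)
        assert pressure.total_force() == pytest.approx(case.F_total, rel=1e-9)
        assert pressure.total_moment() == pytest.approx(M, rel=1e-9, abs=1e-12)
        assert np.all(pressure.pressures >= 0.0)

    def test_relative_displacement_increases_with_gradient(self):
        case = PlateLoadCase(10.0, 0.2, 30.0, L)
        rels = []
        for g_frac in np.linspace(0.0, 0.95, 8):
            prof = StiffnessProfile.from_gradient(700.0, g_frac * 4 * 700.0 / L, L)
            _, rel, _ = simulate_discrete_interface(prof, case)
            rels.append(rel)
        assert np.all(np.diff(rels) > 0)

    def test_discrete_bias_sweep_minimum_at_eq4(self):
        # simulated peak-vs-bias minimum lands on the analytic bias force
        prof = StiffnessProfile(20000.0, 20000.0, L, 15)
        grid = np.arange(0.0, 60.01, 2.0)
        peaks = [
            simulate_discrete_interface(prof, PlateLoadCase(10.0, 0.5, fb, L))[0].peak
            for fb in grid
        ]
        argmin = grid[int(np.argmin(peaks))]
        assert abs(argmin - optimal_bias_force(10.0, 0.5, L)) <= 2.0


class TestDesignSweep:
    def test_zero_moment_slice_optimal_at_uniform_profile(self):
        # without a moment the plate does not tilt, pressure follows the
        # stiffness profile, and the uniform profile (zero gradient)
        # minimises the peak at the uniform-pressure value F/L
        table = design_sweep(
            [30.0], np.linspace(0.0, 50000.0, 6), PlateLoadCase(10.0, 0.0, 0.0, L),
            mean_stiffness=700.0,
        )
        peaks = table.sort_values("gradient_N_per_m2")[
            "peak_pressure_N_per_m"
        ].to_numpy()
        assert peaks[0] == pytest.approx(40.0 / L)
        assert int(np.argmin(peaks)) == 0
        assert np.all(np.diff(peaks) >= 0)

    def test_interior_minimum_and_moment_ordering(self):
        grads = np.linspace(0.0, 4 * 700.0 / L * 0.95, 20)
        table = design_sweep(
            [30.0], grads, PlateLoadCase(10.0, 0.0, 0.0, L),
            mean_stiffness=700.0, M_L_grid=[0.1, 0.2, 0.3],
        )
        argmins = []
        for M, g in table.groupby("M_L_Nm"):
            peaks = g["peak_pressure_N_per_m"].to_numpy()
            i = int(np.argmin(peaks))
            assert 0 < i < len(peaks) - 1  # interior minimum
            argmins.append(grads[i])
        assert np.all(np.diff(argmins) >= 0)  # optimum gradient grows with M

    def test_peak_grows_with_moment(self):
        table = design_sweep(
            [30.0], [10000.0], PlateLoadCase(10.0, 0.0, 0.0, L),
            mean_stiffness=700.0, M_L_grid=[0.1, 0.2, 0.3],
        )
        peaks = table.sort_values("M_L_Nm")["peak_pressure_N_per_m"].to_numpy()
        assert np.all(np.diff(peaks) > 0)

    def test_balance_columns_small(self):
        table = design_sweep(
            [10.0, 30.0], [0.0, 20000.0], PlateLoadCase(10.0, 0.2, 0.0, L),
            mean_stiffness=700.0,
        )
        assert (table["force_balance_err"].abs() < 1e-9 * 40).all()
        assert (table["moment_balance_err"].abs() < 1e-9).all()


class TestPaddingProfileFromMap:
    def test_pointwise_round_trip(self):
        rng = np.random.default_rng(4)
        from hurosim.design import padding_profile_from_map

        k_d = rng.uniform(0.8, 1.6, 15)
        k_eff = k_d * rng.uniform(0.3, 0.9, 15)
        k_p = padding_profile_from_map(k_eff, k_d)
        for e, d, p in zip(k_eff, k_d, k_p):
            assert series_elastic(p, d) == pytest.approx(e, rel=1e-12)

    def test_mismatched_lengths_rejected(self):
        from hurosim.design import padding_profile_from_map

        with pytest.raises(ValueError, match="equal length"):
            padding_profile_from_map([0.5, 0.6], [1.0])


class TestPaddingStiffness:
    def test_symmetric_series(self):
        assert padding_stiffness(0.5, 1.0) == pytest.approx(1.0)

    def test_rigid_dorsum_limit(self):
        assert padding_stiffness(0.7, 1e9) == pytest.approx(0.7, rel=1e-6)

    def test_infeasible_target(self):
        with pytest.raises(InfeasibleDesignError, match="too soft"):
            padding_stiffness(1.2, 1.0)

    @given(
        k_d=st.floats(0.2, 5.0),
        frac=st.floats(0.01, 0.99),
    )
    def test_round_trip_identity(self, k_d, frac):
        k_eff = frac * k_d
        k_p = padding_stiffness(k_eff, k_d)
        assert series_elastic(k_p, k_d) == pytest.approx(k_eff, rel=1e-12)
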