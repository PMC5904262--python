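"""Muscle unit: calcium conservation, activation, Hill-type mechanics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pymus.analysis import ff_scan, steady_isometric_force
from pymus.engine import SimulationSpec, simulate
from pymus.errors import FeasibilityError
from pymus.muscle import (MuscleModel, VelocityTensionAnchors,
                          activation_derivative, ce_velocity,
                          default_muscle_parameters, effective_activation,
                          fl_factor, hill_massima_force, release_kernel,
                          se_force, solve_hill_massima_coeffs)
from pymus.stimuli import SpikeTrain, length_signal


CA_POOLS = ["Ca_SR", "CaCS", "Ca_SP", "CaB", "CaT"]


def total_calcium(res):
    return sum(res.traces[k] for k in CA_POOLS)


class TestModule1:
    def test_quiescent_rest_is_equilibrium(self, muscle_params):
        model = MuscleModel(muscle_params)
        y = model.initial_state()
        dy = model.rhs(0.0, y, np.empty(0), lambda t: -8.0)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_single_spike_twitch_shape(self, muscle_params):
        spec = SimulationSpec("muscle", t_end=400.0, dt=1.0)
        res = simulate(spec, muscle_params,
                       {"spike_train": SpikeTrain(np.array([50.0])),
                        "X_m": length_signal("isometric", duration=400.0)})
        ca = res.traces["Ca_SP"]
        assert ca.max() > 100 * ca[0] + 1e-9     # transient rises…
        assert ca[-1] < 0.05 * ca.max()          # …and decays back
        assert res.traces["CaT"].max() > res.traces["CaT"][0]
        assert res.traces["F_T"].max() > 0.1     # a twitch produces force

    def test_calcium_conserved_along_trajectory(self, muscle_params):
        """Total calcium over the five pools is conserved to 1e-8 relative on
        a stimulated, moving-length trajectory."""
        spec = SimulationSpec("muscle", t_end=1500.0, dt=1.0)
        from pymus.stimuli import impulse_train
        res = simulate(spec, muscle_params, {
            "spike_train": impulse_train("regular", 15.0, 1500.0),
            "X_m": length_signal("dynamic", duration=1500.0, seed=7)})
        tot = total_calcium(res)
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-8

    def test_release_kernel_shape(self):
        s = np.linspace(0, 30, 500)
        k = release_kernel(s, 1.5, 3.0)
        assert k[0] == 0.0 and np.all(k >= 0)
        assert release_kernel(-1.0, 1.5, 3.0) == 0.0
        assert 0 < np.argmax(k) < s.size - 1      # rises then decays

    def test_troponin_rate_grows_with_length(self, muscle_params):
        m1 = muscle_params.m1
        assert m1.k5_of_length(-4.0) > m1.k5_of_length(-8.0) > \
            m1.k5_of_length(-12.0)


class TestModule2:
    def test_alpha_one_is_identity(self):
        assert effective_activation(0.37, 1.0) == pytest.approx(0.37)

    def test_zero_calcium_floors_sigmoid(self, muscle_params):
        assert muscle_params.m2.a_inf(0.0) <= 0.01

    def test_relaxation_toward_midpoint(self, muscle_params):
        """Holding CaT at the sigmoid midpoint, Ã converges to 0.5 with the
        configured time constant (exponential-fit oracle)."""
        m2 = muscle_params.m2
        cat = m2.cat_half
        sol = solve_ivp(lambda t, y: [activation_derivative(cat, y[0], m2)],
                        (0.0, 600.0), [0.0], dense_output=True,
                        rtol=1e-10, atol=1e-12)
        t = np.linspace(5.0, 100.0, 200)
        a = sol.sol(t)[0]
        assert sol.y[0, -1] == pytest.approx(0.5, abs=1e-6)
        slope = np.polyfit(t, np.log(0.5 - a), 1)[0]
        assert -1.0 / slope == pytest.approx(float(m2.tau(cat)), rel=0.01)


class TestForceLength:
    def test_unity_at_optimum(self):
        assert fl_factor(-8.0) == pytest.approx(1.0)

    def test_unique_argmax_on_grid(self):
        grid = np.arange(-16.0, 0.01, 0.5)
        f = fl_factor(grid)
        assert grid[int(np.argmax(f))] == -8.0
        assert np.sum(f == f.max()) == 1
        assert np.all(f > 0)

    def test_symmetric_about_optimum(self):
        for d in (1.0, 3.0, 5.5):
            assert fl_factor(-8.0 + d) == pytest.approx(fl_factor(-8.0 - d))

    def test_out_of_range_warns_and_clamps(self):
        with pytest.warns(UserWarning):
            v = fl_factor(2.0)
        assert v == fl_factor(0.0)


class TestHillMassima:
    def test_anchors_reproduced_exactly(self):
        a = VelocityTensionAnchors()
        c = solve_hill_massima_coeffs(a, 1.0)
        F0 = a.F0
        assert hill_massima_force(0.0, F0, c) == pytest.approx(F0, abs=1e-9)
        assert hill_massima_force(-a.v_max, F0, c) == pytest.approx(0.0, abs=1e-9)
        # lengthening asymptote
        assert hill_massima_force(1e9, F0, c) == pytest.approx(
            a.ecc_asymptote * F0, rel=1e-6)
        # slope ratio at V = 0
        eps = 1e-8
        s_short = (hill_massima_force(0.0, F0, c)
                   - hill_massima_force(-eps, F0, c)) / eps
        s_len = (hill_massima_force(eps, F0, c)
                 - hill_massima_force(0.0, F0, c)) / eps
        assert s_len / s_short == pytest.approx(a.ecc_slope_ratio, rel=1e-5)

    def test_p0_ratio_scales_force_coefficients_only(self):
        a = VelocityTensionAnchors()
        full = solve_hill_massima_coeffs(a, 1.0)
        half = solve_hill_massima_coeffs(a, 0.5)
        assert half.a0 == pytest.approx(0.5 * full.a0)
        assert half.c0 == pytest.approx(0.5 * full.c0)
        assert half.b0 == pytest.approx(full.b0)

    def test_inconsistent_anchors_rejected(self):
        with pytest.raises(FeasibilityError):
            solve_hill_massima_coeffs(
                VelocityTensionAnchors(ecc_asymptote=0.9), 1.0)


class TestCEVelocity:
    def test_isometric_balance(self, muscle_params):
        m3 = muscle_params.m3
        c = solve_hill_massima_coeffs(m3.anchors, m3.P0_ratio)
        F0 = 1.0 * fl_factor(-8.0) * m3.P0
        assert ce_velocity(1.0, -8.0, F0, c, m3) == pytest.approx(0.0, abs=1e-12)

    def test_unloaded_shortening_at_vmax(self, muscle_params):
        m3 = muscle_params.m3
        c = solve_hill_massima_coeffs(m3.anchors, m3.P0_ratio)
        v = ce_velocity(1.0, -8.0, 0.0, c, m3)
        assert v == pytest.approx(-m3.anchors.v_max, rel=1e-9)

    def test_continuous_across_isometric_point(self, muscle_params):
        m3 = muscle_params.m3
        c = solve_hill_massima_coeffs(m3.anchors, m3.P0_ratio)
        F0 = 0.6 * fl_factor(-8.0) * m3.P0
        for eps in (1e-3, 1e-6, 1e-9):
            v_lo = ce_velocity(0.6, -8.0, F0 - eps, c, m3)
            v_hi = ce_velocity(0.6, -8.0, F0 + eps, c, m3)
            assert v_lo <= 0 <= v_hi
            assert abs(v_hi - v_lo) < 1e3 * eps


class TestSeriesElastic:
    def test_rest_force_zero(self, muscle_params):
        m3 = muscle_params.m3
        assert se_force(m3.Xm_init, m3.XCE_init, m3) == 0.0

    def test_linearity_in_stretch(self, muscle_params):
        m3 = muscle_params.m3
        f1 = se_force(m3.Xm_init + 1.0, m3.XCE_init, m3)
        f2 = se_force(m3.Xm_init + 2.0, m3.XCE_init, m3)
        assert f1 == pytest.approx(m3.k_SE * 1.0)
        assert f2 - f1 == pytest.approx(m3.k_SE * 1.0)

    def test_slack_tendon_cannot_push(self, muscle_params):
        m3 = muscle_params.m3
        assert se_force(m3.Xm_init - 3.0, m3.XCE_init, m3) == 0.0

    def test_quasi_static_force_balance(self, muscle_params):
        """During a sustained isometric tetanus the tendon force settles at
        the contractile element's isometric capacity (V ≈ 0)."""
        F = steady_isometric_force(muscle_params, -8.0, None, t_end=6000.0,
                                   activation_clamp=1.0)
        assert F == pytest.approx(muscle_params.m3.P0, rel=0.02)


class TestSystemBehavior:
    def test_frequency_force_nondecreasing(self, muscle_params):
        out = ff_scan(muscle_params, [5.0, 10.0, 20.0, 40.0], -8.0,
                      t_end=2000.0)
        assert out["nondecreasing"]
        assert out["forces"][-1] > 5 * out["forces"][0]

    def test_short_length_weak_at_physiological_rate(self, muscle_params):
        f_short = steady_isometric_force(muscle_params, -12.0, 20.0, 2000.0)
        f_opt = steady_isometric_force(muscle_params, -8.0, 20.0, 2000.0)
        assert f_short < f_opt

    def test_zero_activation_transmits_no_force(self, muscle_params):
        """With no stimulation, a moving length trajectory leaves the tendon
        essentially slack (small passive-yield residual only)."""
        spec = SimulationSpec("muscle", t_end=3000.0, dt=1.0)
        res = simulate(spec, muscle_params, {
            "X_m": length_signal("dynamic", duration=3000.0, excursion=6.0,
                                 seed=11)})
        assert res.traces["A"].max() == 0.0
        assert res.traces["F_T"].max() < 0.02 * muscle_params.m3.P0

    def test_random_and_regular_trains_differ(self, muscle_params):
        from pymus.stimuli import impulse_train
        xm = length_signal("dynamic", duration=1500.0, seed=3)
        spec = SimulationSpec("muscle", t_end=1500.0, dt=1.0)
        reg = simulate(spec, muscle_params, {
            "spike_train": impulse_train("regular", 20.0, 1500.0), "X_m": xm})
        rnd = simulate(spec, muscle_params, {
            "spike_train": impulse_train("random", 20.0, 1500.0, sd_freq=6.0,
                                         seed=5), "X_m": xm})
        assert abs(reg.traces["F_T"].mean() - rnd.traces["F_T"].mean()) > 1e-3
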