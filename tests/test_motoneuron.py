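"""Motoneuron kinetics, currents, calcium and excitability contracts."""

import numpy as np
import pytest

from pymus.analysis import measure_input_resistance_and_tau
from pymus.engine import SimulationSpec, simulate
from pymus.errors import ConfigurationError, InvalidParameterError
from pymus.motoneuron import (CHANNEL_GATES, CalciumParams, ChannelSet,
                              MotoneuronModel, MotoneuronParameters,
                              calcium_derivative, excitability_knobs,
                              gating_steady_state, gating_time_constant,
                              ionic_current, nernst_ECa)
from pymus.passive import measure_RN, measure_tau
from pymus.presets import validation_motoneuron_parameters
from pymus.stimuli import step_with_pulses


ALL_GATES = [(ch, g.name) for ch, gates in CHANNEL_GATES.items()
             for g in gates]


class TestGating:
    @pytest.mark.parametrize("channel,var", ALL_GATES)
    def test_midpoint_saturation_and_slope(self, channel, var):
        gate = next(g for g in CHANNEL_GATES[channel] if g.name == var)
        assert gating_steady_state(channel, var, gate.theta) == pytest.approx(0.5)
        lo = gating_steady_state(channel, var, gate.theta - 15 * abs(gate.slope))
        hi = gating_steady_state(channel, var, gate.theta + 15 * abs(gate.slope))
        if gate.kind == "act":
            assert lo < 1e-6 and hi > 1 - 1e-6
        else:
            assert lo > 1 - 1e-6 and hi < 1e-6
        # Boltzmann derivative at midpoint is 1/(4k)
        dv = 1e-4
        num = (gating_steady_state(channel, var, gate.theta + dv)
               - gating_steady_state(channel, var, gate.theta - dv)) / (2 * dv)
        assert num == pytest.approx(1.0 / (4.0 * gate.slope), rel=1e-5)
        # strictly monotone where unsaturated, and tau > 0 everywhere
        V = np.linspace(gate.theta - 6 * abs(gate.slope),
                        gate.theta + 6 * abs(gate.slope), 121)
        x = gating_steady_state(channel, var, V)
        assert np.all(np.diff(x) > 0) if gate.kind == "act" \
            else np.all(np.diff(x) < 0)
        Vwide = np.linspace(-120, 60, 181)
        assert np.all(np.asarray(gating_time_constant(channel, var, Vwide)) > 0)

    def test_unknown_channel_or_gate(self):
        with pytest.raises(ConfigurationError):
            gating_steady_state("I_bogus", "m", -50.0)
        with pytest.raises(ConfigurationError):
            gating_time_constant("I_Naf", "q", -50.0)


class TestIonicCurrent:
    def test_reversal_gives_zero(self):
        assert ionic_current("I_CaL", 80.0, {"m": 0.7}, 1.2, 80.0) == 0.0

    def test_zero_conductance(self):
        assert ionic_current("I_Naf", -20.0, {"m": 1.0, "h": 1.0}, 0.0, 55.0) == 0.0

    def test_hand_assembled_density(self):
        # gbar 1, gating product 0.25, driving force −20 mV → −5 µA/cm²
        I = ionic_current("I_CaL", -20.0, {"m": 0.25}, 1.0, 0.0)
        assert I == pytest.approx(-5.0)

    def test_kca_saturates_with_calcium(self):
        kd = 2e-3
        lo = ionic_current("I_KCa", -60.0, {}, 1.0, -80.0, Ca=kd / 10, kca_kd=kd)
        hi = ionic_current("I_KCa", -60.0, {}, 1.0, -80.0, Ca=kd * 100, kca_kd=kd)
        assert abs(hi) > abs(lo)
        assert abs(hi) <= abs(1.0 * (-60.0 + 80.0))


class TestNernst:
    def test_equal_concentrations(self):
        assert nernst_ECa(2.0, 2.0) == 0.0

    def test_unit_log_ratio(self):
        assert nernst_ECa(1.0, np.e, prefactor=13.35) == pytest.approx(13.35)

    def test_body_temperature_value(self):
        # ratio 10^4 at 310 K → ≈ 122.9 mV
        assert nernst_ECa(2e-4, 2.0, prefactor=13.35) == pytest.approx(
            122.9, abs=0.1)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            nernst_ECa(0.0, 2.0)


class TestCalciumDynamics:
    def test_removal_only_decays_to_floor(self):
        cp = CalciumParams()
        assert calcium_derivative(cp.ca_rest * 5, 0.0, cp) < 0
        assert calcium_derivative(cp.ca_rest, 0.0, cp) == 0.0

    def test_fixed_point_under_constant_influx(self):
        """The trajectory converges to the concentration where influx balances
        removal (closed form: rest − alpha·I/k)."""
        cp = CalciumParams()
        I = -50.0  # inward calcium current density
        target = cp.ca_rest - cp.alpha * I / cp.k
        ca, dt = cp.ca_rest, 0.01
        for _ in range(200_000):
            ca += dt * calcium_derivative(ca, I, cp)
        assert ca == pytest.approx(target, rel=1e-6)

    def test_free_fraction_scales_relaxation(self):
        cp_fast = CalciumParams(f=0.1)
        cp_slow = CalciumParams(f=0.05)
        ca = cp_fast.ca_rest * 10
        assert calcium_derivative(ca, 0.0, cp_fast) == pytest.approx(
            2 * calcium_derivative(ca, 0.0, cp_slow))


def passive_only_parameters(cable):
    return MotoneuronParameters(cable=cable, soma=ChannelSet(),
                                dend=ChannelSet())


class TestMembraneDerivatives:
    def test_passive_rest_is_equilibrium(self, cable):
        params = passive_only_parameters(cable)
        model = MotoneuronModel(params)
        y = model.initial_state()
        dy = model.rhs(0.0, y, {})
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_passive_step_reproduces_cable_measurements(self, cable):
        """A small hyperpolarizing step on the passive cell virtually measures
        R_N and τ_m of the cable (cross-module consistency)."""
        params = passive_only_parameters(cable)
        t_on, t_off = 20.0, 220.0
        sig = step_with_pulses(-1.0, t_on, t_off, duration=320.0)
        spec = SimulationSpec("motoneuron", t_end=320.0, dt=0.05,
                              rtol=1e-9, atol=1e-11)
        res = simulate(spec, params, {"I_soma": sig})
        meas = measure_input_resistance_and_tau(res, -1.0, t_on, t_off)
        assert meas["R_N"] == pytest.approx(measure_RN(cable), rel=0.005)
        assert meas["tau_m"] == pytest.approx(measure_tau(cable), rel=0.02)

    def test_suprathreshold_step_fires_repetitively(self):
        params = validation_motoneuron_parameters()
        sig = step_with_pulses(15.0, 100.0, 900.0, duration=1000.0)
        spec = SimulationSpec("motoneuron", t_end=1000.0, dt=0.1)
        res = simulate(spec, params, {"I_soma": sig})
        assert len(res.spikes["soma"]) >= 5
        # state-bounds invariants along the trajectory
        assert res.traces["V_soma"].max() <= 60.0
        assert res.traces["V_soma"].min() >= -120.0
        assert res.traces["Ca_soma"].min() > 0.0
        for name, tr in res.traces.items():
            if name.startswith("gate_"):
                assert tr.min() >= -1e-9 and tr.max() <= 1.0 + 1e-9


def _rheobase(params, lo=0.0, hi=40.0, iters=10):
    """Minimum 50-ms step current evoking a spike (bisection)."""
    def fires(I):
        sig = step_with_pulses(I, 10.0, 60.0, duration=120.0)
        spec = SimulationSpec("motoneuron", t_end=120.0, dt=0.05)
        return len(simulate(spec, params, {"I_soma": sig}).spikes["soma"]) > 0
    assert not fires(lo) and fires(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _ahp_half_decay(params):
    """Half-decay time of the afterhyperpolarization after a single spike."""
    sig = step_with_pulses(30.0, 10.0, 15.0, duration=400.0)
    spec = SimulationSpec("motoneuron", t_end=400.0, dt=0.05)
    res = simulate(spec, params, {"I_soma": sig})
    t, v = res.t, res.traces["V_soma"]
    rest = v[t < 9.0].mean()
    tm, vm = t[t > 15.0], v[t > 15.0]
    imin = int(np.argmin(vm))
    half = rest - 0.5 * (rest - vm[imin])
    after = np.flatnonzero(vm[imin:] > half)
    return tm[imin + after[0]] - tm[imin]


class TestExcitabilityKnobs:
    def test_identity(self):
        params = validation_motoneuron_parameters()
        same = excitability_knobs(params, 1.0, None)
        assert same.soma.gbar == params.soma.gbar
        assert same.ca_soma.f == params.ca_soma.f

    def test_sodium_conductance_moves_rheobase(self):
        base = validation_motoneuron_parameters()
        rheo = [_rheobase(excitability_knobs(base, s)) for s in (0.8, 1.0, 1.2)]
        assert rheo[0] > rheo[1] > rheo[2]

    def test_free_calcium_fraction_moves_ahp(self):
        base = validation_motoneuron_parameters()
        durs = [_ahp_half_decay(excitability_knobs(base, f_S_value=f))
                for f in (0.1, 0.05, 0.025)]
        assert durs[0] < durs[1] < durs[2]

    def test_knobs_are_nearly_independent(self):
        """Turning one knob leaves the other metric within 10% of baseline."""
        base = validation_motoneuron_parameters()
        ahp0 = _ahp_half_decay(base)
        rheo0 = _rheobase(base)
        assert _ahp_half_decay(excitability_knobs(base, 1.2)) == pytest.approx(
            ahp0, rel=0.10)
        assert _rheobase(excitability_knobs(base, f_S_value=0.05)) == \
            pytest.approx(rheo0, rel=0.10)
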