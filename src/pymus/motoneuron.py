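"""Two-compartment conductance-based motoneuron.

The somatic compartment carries the spike-generating machinery (fast Na⁺,
delayed-rectifier K⁺, N-type Ca²⁺, Ca-dependent K⁺, persistent Na⁺, H) and
the dendritic compartment can additionally host the low-voltage-activated
L-type Ca²⁺ current whose slow, regenerative activation produces plateau
potentials, firing bistability and counterclockwise frequency–current
hysteresis.  Any subset of currents may be enabled per compartment — the
validation protocols toggle subsets.

Voltage-gated currents use Hodgkin–Huxley-type first-order gating with
Boltzmann steady states; the Ca-dependent K⁺ current is gated by a saturating
function of intracellular calcium; calcium concentration in each compartment
follows first-order influx/removal dynamics scaled by the free-to-bound
fraction (``f_S`` at the soma, which sets afterhyperpolarization duration);
the calcium reversal potential is either held constant or updated from the
Nernst relation.

Kinetic constants and maximal conductances are this package's own
calibration: they follow the classic two-compartment motoneuron literature in
functional form, with densities scaled to the effective capacitances produced
by the passive-property inversion, and were fixed once against the
qualitative contracts (repetitive firing, separable rheobase/AHP knobs,
CaL-dependent hysteresis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .passive import CableParameters

__all__ = [
    "GatingVariable", "CHANNEL_GATES", "ChannelSet", "CalciumParams",
    "MotoneuronParameters", "MotoneuronModel",
    "gating_steady_state", "gating_time_constant", "ionic_current",
    "nernst_ECa", "calcium_derivative", "excitability_knobs",
    "default_parameters",
]

#: currents implemented for either compartment
ALL_CURRENTS = ("I_Naf", "I_Kdr", "I_CaN", "I_KCa", "I_Nap", "I_H", "I_CaL")
CALCIUM_CURRENTS = ("I_CaN", "I_CaL")

#: nA → µA
_NA_TO_UA = 1e-3


@dataclass(frozen=True)
class GatingVariable:
    """First-order gate: x' = (x_inf(V) − x)/tau(V); x_inf is a Boltzmann."""

    name: str
    power: int
    kind: str            # 'act' (increasing with V) or 'inact' (decreasing)
    theta: float         # half-activation voltage (mV)
    slope: float         # Boltzmann slope k (mV); sign encodes kind
    tau_params: tuple    # ('const', tau) or ('bell', amp, theta, k1, k2)

    def x_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(V - self.theta) / self.slope))

    def tau(self, V):
        kind = self.tau_params[0]
        if kind == "const":
            return np.broadcast_to(self.tau_params[1], np.shape(V)).astype(float) \
                if np.ndim(V) else float(self.tau_params[1])
        amp, th, k1, k2 = self.tau_params[1:]
        return amp / (np.exp((V - th) / k1) + np.exp(-(V - th) / k2))


# Gate tables.  tau 'bell' entries give voltage-dependent time constants with
# a maximum near the half-(in)activation voltage.
CHANNEL_GATES: dict[str, tuple[GatingVariable, ...]] = {
    "I_Naf": (
        GatingVariable("m", 3, "act", -35.0, 7.8, ("const", 0.1)),
        GatingVariable("h", 1, "inact", -55.0, -7.0, ("bell", 30.0, -50.0, 15.0, 16.0)),
    ),
    "I_Kdr": (
        GatingVariable("n", 4, "act", -28.0, 15.0, ("bell", 7.0, -40.0, 40.0, 50.0)),
    ),
    "I_CaN": (
        GatingVariable("m", 2, "act", -30.0, 5.0, ("const", 4.0)),
        GatingVariable("h", 1, "inact", -45.0, -5.0, ("const", 40.0)),
    ),
    "I_CaL": (
        GatingVariable("m", 1, "act", -42.0, 7.0, ("const", 60.0)),
    ),
    "I_Nap": (
        GatingVariable("m", 1, "act", -48.0, 3.0, ("const", 1.0)),
    ),
    "I_H": (
        GatingVariable("m", 1, "inact", -80.0, -6.0, ("const", 100.0)),
    ),
    "I_KCa": (),  # gated by calcium, not voltage
}

#: reversal used for each current family
_CURRENT_REVERSAL = {
    "I_Naf": "E_Na", "I_Nap": "E_Na",
    "I_Kdr": "E_K", "I_KCa": "E_K",
    "I_H": "E_H",
    "I_CaN": "E_Ca", "I_CaL": "E_Ca",
}


def gating_steady_state(channel: str, variable: str, V) -> float:
    """Boltzmann steady state of a gate; monotone in V."""
    return _find_gate(channel, variable).x_inf(V)


def gating_time_constant(channel: str, variable: str, V) -> float:
    """Gate relaxation time constant (ms); strictly positive."""
    return _find_gate(channel, variable).tau(V)


def _find_gate(channel: str, variable: str) -> GatingVariable:
    if channel not in CHANNEL_GATES:
        raise ConfigurationError(f"unknown channel {channel!r}")
    for g in CHANNEL_GATES[channel]:
        if g.name == variable:
            return g
    raise ConfigurationError(f"channel {channel} has no gate {variable!r}")


def nernst_ECa(Ca_in: float, Ca_out: float, prefactor: float = 13.35) -> float:
    """Calcium reversal potential E_Ca = (RT/2F)·ln([Ca]_out/[Ca]_in) in mV.

    ``prefactor`` is RT/2F in mV (13.35 mV at 310 K).
    """
    if Ca_in <= 0 or Ca_out <= 0:
        raise InvalidParameterError("calcium concentrations must be positive")
    return prefactor * math.log(Ca_out / Ca_in)


@dataclass
class ChannelSet:
    """Enabled currents (maximal conductances, mS/cm²) for one compartment."""

    gbar: dict[str, float] = field(default_factory=dict)
    e_ca_mode: str = "constant"       # 'constant' | 'dynamic'
    receptors: tuple[str, ...] = ()   # subset of {'excitatory', 'inhibitory'}

    def __post_init__(self):
        for name, g in self.gbar.items():
            if name not in ALL_CURRENTS:
                raise ConfigurationError(f"unknown current {name!r}")
            if g < 0:
                raise InvalidParameterError(f"conductance {name} must be >= 0")
        if self.e_ca_mode not in ("constant", "dynamic"):
            raise ConfigurationError("e_ca_mode must be 'constant' or 'dynamic'")


@dataclass
class CalciumParams:
    """First-order calcium pool: d[Ca]/dt = f·(−alpha·I_Ca − k·([Ca]−rest))."""

    f: float = 0.01        # free-to-bound fraction (dimensionless)
    alpha: float = 6e-5    # influx scaling (mM·cm²/µA/ms)
    k: float = 2.0         # removal rate (1/ms)
    ca_rest: float = 1e-4  # resting concentration (mM)

    def __post_init__(self):
        if not (0.0 < self.f <= 1.0):
            raise InvalidParameterError("free calcium fraction must be in (0, 1]")
        if self.alpha < 0 or self.k <= 0 or self.ca_rest <= 0:
            raise InvalidParameterError("invalid calcium parameters")


@dataclass
class MotoneuronParameters:
    cable: CableParameters
    soma: ChannelSet
    dend: ChannelSet
    ca_soma: CalciumParams = field(default_factory=CalciumParams)
    ca_dend: CalciumParams = field(default_factory=CalciumParams)
    E_Na: float = 55.0
    E_K: float = -80.0
    E_H: float = -43.0
    E_leak: float = -70.0
    E_esyn: float = 0.0
    E_isyn: float = -75.0
    E_Ca_const: float = 80.0
    ca_out: float = 2.0            # extracellular [Ca] (mM)
    nernst_prefactor: float = 13.35  # RT/2F (mV)
    kca_kd: float = 2e-3           # K(Ca) half-saturation (mM)


def ionic_current(channel: str, V: float, gates: dict[str, float],
                  gbar: float, E: float, Ca: float | None = None,
                  kca_kd: float = 2e-3) -> float:
    """Current density (µA/cm²): I = ḡ·(gating product)·(V − E).

    For I_KCa the gating product is the saturating calcium function
    Ca/(Ca + K_d).
    """
    if channel == "I_KCa":
        if Ca is None:
            raise ConfigurationError("I_KCa requires a calcium concentration")
        prod = Ca / (Ca + kca_kd)
    else:
        prod = 1.0
        for g in CHANNEL_GATES[channel]:
            prod *= gates[g.name] ** g.power
    return gbar * prod * (V - E)


def calcium_derivative(Ca: float, I_Ca_total: float, cp: CalciumParams) -> float:
    """d[Ca]/dt (mM/ms) from total calcium current density (µA/cm²).

    Inward (negative) calcium current raises [Ca]; removal is first-order
    toward the resting concentration; both scaled by the free fraction.
    """
    return cp.f * (-cp.alpha * I_Ca_total - cp.k * (Ca - cp.ca_rest))


def excitability_knobs(params: MotoneuronParameters, G_Naf_scale: float = 1.0,
                       f_S_value: float | None = None) -> MotoneuronParameters:
    """Return parameters with rheobase / AHP knobs turned.

    Scaling the somatic fast-Na conductance moves rheobase (down for larger
    conductance); the somatic free-calcium fraction sets the AHP time scale
    (smaller fraction → slower [Ca] relaxation → longer AHP).  Each knob
    leaves the other metric nearly untouched.
    """
    if G_Naf_scale <= 0:
        raise InvalidParameterError("G_Naf_scale must be positive")
    gbar = dict(params.soma.gbar)
    if "I_Naf" in gbar:
        gbar["I_Naf"] = gbar["I_Naf"] * G_Naf_scale
    soma = replace(params.soma, gbar=gbar)
    ca_soma = params.ca_soma
    if f_S_value is not None:
        ca_soma = replace(ca_soma, f=f_S_value)
    return replace(params, soma=soma, ca_soma=ca_soma)


class MotoneuronModel:
    """State layout, resting initialization and right-hand side.

    State vector: ``[V_S, V_D, Ca_S, Ca_D, gates…]`` with one entry per gate
    of every enabled voltage-gated current, soma first.
    """

    def __init__(self, params: MotoneuronParameters):
        self.p = params
        self.gate_index: list[tuple[str, str, str]] = []  # (comp, channel, gate)
        for comp, cs in (("S", params.soma), ("D", params.dend)):
            for ch in cs.gbar:
                for g in CHANNEL_GATES[ch]:
                    self.gate_index.append((comp, ch, g.name))
        self.n_states = 4 + len(self.gate_index)
        self.names = ["V_S", "V_D", "Ca_S", "Ca_D"] + [
            f"{c}.{ch}.{g}" for c, ch, g in self.gate_index]

    # -- initialization ---------------------------------------------------
    def initial_state(self, V_S: float | None = None, V_D: float | None = None,
                      overrides: dict[str, float] | None = None) -> np.ndarray:
        """Rest: V at the leak reversal, gates at x_inf(V), [Ca] at rest."""
        p = self.p
        y = np.empty(self.n_states)
        y[0] = p.E_leak if V_S is None else V_S
        y[1] = p.E_leak if V_D is None else V_D
        y[2] = p.ca_soma.ca_rest
        y[3] = p.ca_dend.ca_rest
        for i, (comp, ch, gname) in enumerate(self.gate_index):
            V = y[0] if comp == "S" else y[1]
            y[4 + i] = _find_gate(ch, gname).x_inf(V)
        if overrides:
            for name, val in overrides.items():
                if name not in self.names:
                    raise ConfigurationError(f"unknown state {name!r}")
                y[self.names.index(name)] = val
        return y

    # -- dynamics ---------------------------------------------------------
    def _compartment_currents(self, comp: str, V: float, Ca: float,
                              gates: np.ndarray) -> tuple[float, float]:
        """(total ionic current density, total calcium current density)."""
        p = self.p
        cs = p.soma if comp == "S" else p.dend
        total = 0.0
        i_ca = 0.0
        for ch, gbar in cs.gbar.items():
            if gbar == 0.0:
                continue
            rev = _CURRENT_REVERSAL[ch]
            if rev == "E_Ca":
                if cs.e_ca_mode == "dynamic":
                    E = nernst_ECa(Ca, p.ca_out, p.nernst_prefactor)
                else:
                    E = p.E_Ca_const
            else:
                E = getattr(p, rev)
            gdict = {}
            for i, (c2, ch2, gname) in enumerate(self.gate_index):
                if c2 == comp and ch2 == ch:
                    gdict[gname] = gates[i]
            I = ionic_current(ch, V, gdict, gbar, E, Ca=Ca, kca_kd=p.kca_kd)
            total += I
            if ch in CALCIUM_CURRENTS:
                i_ca += I
        return total, i_ca

    def rhs(self, t: float, y: np.ndarray, inputs) -> np.ndarray:
        """Full derivative vector.

        ``inputs`` provides callables (or None): ``I_soma(t)`` in nA and
        synaptic conductances ``G_esyn_S/G_isyn_S/G_esyn_D/G_isyn_D`` in
        mS/cm² of the target compartment.
        """
        p = self.p
        cab = p.cable
        V_S, V_D, Ca_S, Ca_D = y[0], y[1], y[2], y[3]
        gates = y[4:]

        I_ion_S, I_ca_S = self._compartment_currents("S", V_S, Ca_S, gates)
        I_ion_D, I_ca_D = self._compartment_currents("D", V_D, Ca_D, gates)

        # leak and synapses (densities, µA/cm²)
        I_leak_S = cab.G_mS * (V_S - p.E_leak)
        I_leak_D = cab.G_mD * (V_D - p.E_leak)
        I_syn_S = 0.0
        I_syn_D = 0.0
        g = inputs.get("G_esyn_S")
        if g is not None:
            I_syn_S += g(t) * (V_S - p.E_esyn)
        g = inputs.get("G_isyn_S")
        if g is not None:
            I_syn_S += g(t) * (V_S - p.E_isyn)
        g = inputs.get("G_esyn_D")
        if g is not None:
            I_syn_D += g(t) * (V_D - p.E_esyn)
        g = inputs.get("G_isyn_D")
        if g is not None:
            I_syn_D += g(t) * (V_D - p.E_isyn)

        I_inj = inputs.get("I_soma")
        I_inj_dens = (I_inj(t) * _NA_TO_UA / cab.A_S) if I_inj is not None else 0.0

        gc = cab.g_C
        couple_S = gc * (V_D - V_S) / cab.A_S
        couple_D = gc * (V_S - V_D) / cab.A_D

        dy = np.empty_like(y)
        dy[0] = (-I_ion_S - I_leak_S - I_syn_S + I_inj_dens + couple_S) / cab.C_mS
        dy[1] = (-I_ion_D - I_leak_D - I_syn_D + couple_D) / cab.C_mD
        dy[2] = calcium_derivative(Ca_S, I_ca_S, p.ca_soma)
        dy[3] = calcium_derivative(Ca_D, I_ca_D, p.ca_dend)
        for i, (comp, ch, gname) in enumerate(self.gate_index):
            V = V_S if comp == "S" else V_D
            gate = _find_gate(ch, gname)
            dy[4 + i] = (gate.x_inf(V) - gates[i]) / gate.tau(V)
        return dy


# -- default validation parameter set -------------------------------------

#: calibrated somatic densities (mS/cm²); scaled to the effective somatic
#: capacitance of the inverted cat-motoneuron cable (C_mS ≈ 28 µF/cm²)
SOMA_GBAR = {
    "I_Naf": 1500.0,
    "I_Kdr": 1300.0,
    "I_CaN": 150.0,
    "I_KCa": 40.0,
    "I_Nap": 3.0,
}

#: calibrated dendritic densities (mS/cm²); C_mD ≈ 4.1 µF/cm²
DEND_GBAR = {
    "I_CaL": 0.9,
}


def default_parameters(cable: CableParameters,
                       soma_currents: dict[str, float] | None = None,
                       dend_currents: dict[str, float] | None = None,
                       **kwargs) -> MotoneuronParameters:
    """Validation parameter set: spiking soma, plateau-generating dendrite."""
    soma = ChannelSet(gbar=dict(SOMA_GBAR if soma_currents is None
                                else soma_currents), e_ca_mode="dynamic")
    dend = ChannelSet(gbar=dict(DEND_GBAR if dend_currents is None
                                else dend_currents), e_ca_mode="constant")
    return MotoneuronParameters(cable=cable, soma=soma, dend=dend, **kwargs)
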