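"""Protocol presets for the validation virtual experiments.

Each preset bundles a :class:`SimulationSpec`, a parameter set and input
signals reproducing one of the step-by-step validation protocols:

* ``fig6a`` — motoneuron, symmetric triangular current ramp at the soma,
  spiking soma + L-type-Ca dendrite → counterclockwise f–I hysteresis.
* ``fig6b`` — motoneuron, zero somatic current, triangular excitatory
  synaptic-conductance ramp on the dendrite (Gp 0.12, duration 10 s,
  20 s simulated).
* ``fig7a``/``fig7b`` — muscle unit, 20 Hz regular / random impulse train
  during locomotor-like movement.
* ``fig8`` — motor unit, somatic step current with alternating excitatory
  and inhibitory 300 ms pulses at the optimal length.
* ``fig9`` — motor unit, same pulse protocol applied to the dendritic
  excitatory synaptic conductance.
* ``fig10_pushpull`` / ``fig10_proportional`` — motor unit with noisy
  triangular inhibition at the soma and excitation at the dendrite, the
  inhibition either counter-varying (push–pull) or co-varying
  (proportional) with excitation.

Presets are deterministic given their bundled seeds; any field can be
overridden (notably ``t_scale`` to shorten a protocol proportionally).
"""

from __future__ import annotations

import numpy as np

from .engine import MotorUnitParameters, SimulationSpec
from .errors import ConfigurationError
from .motoneuron import (ChannelSet, MotoneuronParameters, default_parameters)
from .muscle import default_muscle_parameters
from .passive import SystemProperties, invert_passive
from .stimuli import (impulse_train, length_signal, step_with_pulses,
                      synaptic_conductance, triangular_ramp)

__all__ = ["PRESET_NAMES", "cat_system_properties", "cat_cable",
           "validation_motoneuron_parameters", "get_preset"]

#: the cat-motoneuron target property set used throughout validation
CAT_PROPERTIES = dict(R_N=1.29, tau_m=7.2, VA_SD_DC=0.76, VA_DS_DC=0.75,
                      VA_SD_AC=0.27)

PRESET_SEED = 20180411

#: somatic ramp peak (nA) for the f–I protocol; ≈1.8× the rheobase of the
#: validation cell so both hysteresis limbs are well sampled
FIG6A_PEAK_NA = 22.0
FIG8_STEP_NA = 8.5
FIG8_PULSE_NA = 12.0
FIG9_STEP_G = 0.08
FIG9_PULSE_G = 0.06


def cat_system_properties(**overrides) -> SystemProperties:
    return SystemProperties(**{**CAT_PROPERTIES, **overrides})


def cat_cable(**overrides):
    return invert_passive(cat_system_properties(**overrides))


def validation_motoneuron_parameters(extended: bool = False
                                     ) -> MotoneuronParameters:
    """Channel layout of the validation protocols.

    Base layout: soma {I_Naf, I_Nap, I_Kdr, I_KCa, I_CaN} with
    calcium-dependent E_Ca, dendrite {I_CaL} with constant E_Ca.  The
    extended layout adds I_H to the soma (constant E_Ca) and the full somatic
    repertoire plus I_H to the dendrite.
    """
    cable = cat_cable()
    params = default_parameters(cable)
    if extended:
        soma = dict(params.soma.gbar)
        soma["I_H"] = 6.0
        params.soma = ChannelSet(gbar=soma, e_ca_mode="constant",
                                 receptors=("inhibitory",))
        dend = dict(params.dend.gbar)
        dend.update({"I_Naf": 4.0, "I_Kdr": 3.0, "I_CaN": 0.4,
                     "I_KCa": 0.4, "I_Nap": 0.06, "I_H": 0.8})
        params.dend = ChannelSet(gbar=dend, e_ca_mode="constant",
                                 receptors=("excitatory",))
    else:
        params.dend = ChannelSet(gbar=dict(params.dend.gbar),
                                 e_ca_mode="constant",
                                 receptors=("excitatory",))
    return params


def get_preset(name: str, t_scale: float = 1.0, seed: int | None = None,
               rtol: float = 1e-6, atol: float = 1e-8, dt: float = 0.1):
    """Return (spec, params, inputs) for a named protocol preset.

    ``t_scale`` shrinks every duration proportionally (for quick runs);
    ``seed`` overrides the bundled seed of stochastic presets.
    """
    seed = PRESET_SEED if seed is None else seed
    s = t_scale
    if name == "fig6a":
        params = validation_motoneuron_parameters()
        dur = 10000.0 * s
        ramp = triangular_ramp(FIG6A_PEAK_NA, dur, 0.0, units="nA")
        spec = SimulationSpec("motoneuron", t_end=dur, dt=dt,
                              rtol=rtol, atol=atol, seed=seed)
        return spec, params, {"I_soma": ramp}
    if name == "fig6b":
        params = validation_motoneuron_parameters()
        dur = 10000.0 * s
        g = synaptic_conductance("ramp", G0=0.0, Gp=0.12, duration=dur,
                                 total=2 * dur, noise=False)
        spec = SimulationSpec("motoneuron", t_end=2 * dur, dt=dt,
                              rtol=rtol, atol=atol, seed=seed)
        return spec, params, {"G_esyn_D": g}
    if name in ("fig7a", "fig7b"):
        params = default_muscle_parameters(P0_ratio=1.0)
        dur = 2000.0 * max(s, 1.0)  # needs ≥ 2 s of movement
        xm = length_signal("dynamic", duration=dur, excursion=6.0, seed=seed)
        if name == "fig7a":
            train = impulse_train("regular", 20.0, dur)
        else:
            train = impulse_train("random", 20.0, dur, sd_freq=6.0, seed=seed)
        spec = SimulationSpec("muscle", t_end=dur, dt=1.0,
                              rtol=rtol, atol=atol, seed=seed)
        return spec, params, {"spike_train": train, "X_m": xm}
    if name == "fig8":
        params = MotorUnitParameters(validation_motoneuron_parameters(),
                                     default_muscle_parameters(1.0))
        t_end = 6000.0 * s
        step = step_with_pulses(FIG8_STEP_NA, 500.0 * s, 5500.0 * s,
                                pulse_amp=FIG8_PULSE_NA, pulse_dur=300.0,
                                pulse_times=[1500.0 * s, 3500.0 * s],
                                duration=t_end)
        xm = length_signal("isometric", duration=t_end, level=-8.0)
        spec = SimulationSpec("motorunit", t_end=t_end, dt=dt,
                              rtol=rtol, atol=atol, seed=seed)
        return spec, params, {"I_soma": step, "X_m": xm}
    if name == "fig9":
        params = MotorUnitParameters(validation_motoneuron_parameters(),
                                     default_muscle_parameters(1.0))
        t_end = 6000.0 * s
        g = synaptic_conductance(
            "step", Gp=FIG9_STEP_G, t_start=500.0 * s, duration=5000.0 * s,
            pulse_amp=FIG9_PULSE_G, pulse_dur=300.0,
            pulse_times=[1500.0 * s, 3500.0 * s], total=t_end, noise=False)
        xm = length_signal("isometric", duration=t_end, level=-8.0)
        spec = SimulationSpec("motorunit", t_end=t_end, dt=dt,
                              rtol=rtol, atol=atol, seed=seed)
        return spec, params, {"G_esyn_D": g, "X_m": xm}
    if name in ("fig10_pushpull", "fig10_proportional"):
        params = MotorUnitParameters(
            validation_motoneuron_parameters(extended=True),
            default_muscle_parameters(1.0))
        dur = 10000.0 * s
        t_end = 20000.0 * s
        g_e = synaptic_conductance("ramp", G0=0.0, Gp=0.12, duration=dur,
                                   total=t_end, noise=True, seed=seed)
        if name == "fig10_pushpull":
            g_i = synaptic_conductance("ramp", G0=0.13, Gp=0.03, duration=dur,
                                       total=t_end, noise=True, seed=seed + 1)
        else:
            g_i = synaptic_conductance("ramp", G0=0.03, Gp=0.13, duration=dur,
                                       total=t_end, noise=True, seed=seed + 1)
        xm = length_signal("isometric", duration=t_end, level=-8.0)
        spec = SimulationSpec("motorunit", t_end=t_end, dt=dt,
                              rtol=rtol, atol=atol, seed=seed)
        return spec, params, {"G_esyn_D": g_e, "G_isyn_S": g_i, "X_m": xm}
    raise ConfigurationError(
        f"unknown preset {name!r}; options: {', '.join(PRESET_NAMES)}")


PRESET_NAMES = ("fig6a", "fig6b", "fig7a", "fig7b", "fig8", "fig9",
                "fig10_pushpull", "fig10_proportional")
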