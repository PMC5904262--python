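"""YAML configuration loading.

A single structured file supplies every parameter.  Schema (all sections
optional; omitted keys fall back to the validation defaults)::

    motoneuron:
      passive:            # the five measurable targets + geometry
        R_N: 1.29         # MΩ
        tau_m: 7.2        # ms
        VA_SD_DC: 0.76
        VA_DS_DC: 0.75
        VA_SD_AC: 0.27
        p: 0.1            # somatic/dendritic area ratio
        A_total: 1.0e-3   # cm²
        f_AC: 200.0       # Hz (AC probe frequency defining VA_SD_AC)
      soma:               # maximal conductances, mS/cm²
        I_Naf: 1500.0
        ...
      soma_e_ca: dynamic  # 'constant' | 'dynamic'
      dend: {...}
      dend_e_ca: constant
    muscle:
      P_0: 1.0            # muscle-unit / whole-muscle peak-force ratio
      m1: {...}           # module-1 rate constants
      m2: {...}
      m3: {...}
    axon:
      delay_ms: 2.0
    engine:
      t_end: 1000.0
      dt: 0.1
      solver: stiff-BDF
      rtol: 1.0e-6
      atol: 1.0e-8

Note: the coupling conductance G_C in the derived cable is specific per
*total* membrane area; absolute values are exposed as properties.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .engine import MotorUnitParameters, SimulationSpec
from .motoneuron import ChannelSet, MotoneuronParameters, default_parameters
from .muscle import MuscleParameters, default_muscle_parameters
from .passive import SystemProperties, invert_passive

__all__ = ["load_config", "system_properties_from_config",
           "motoneuron_from_config", "muscle_from_config", "spec_from_config"]

DEFAULT_PASSIVE = dict(R_N=1.29, tau_m=7.2, VA_SD_DC=0.76, VA_DS_DC=0.75,
                       VA_SD_AC=0.27, p=0.1, A_total=1e-3, f_AC=200.0)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def system_properties_from_config(cfg: dict) -> SystemProperties:
    passive = {**DEFAULT_PASSIVE,
               **(cfg.get("motoneuron", {}).get("passive", {}) or {})}
    return SystemProperties(**passive)


def motoneuron_from_config(cfg: dict) -> MotoneuronParameters:
    cable = invert_passive(system_properties_from_config(cfg))
    mn = cfg.get("motoneuron", {}) or {}
    params = default_parameters(cable,
                                soma_currents=mn.get("soma"),
                                dend_currents=mn.get("dend"))
    if "soma_e_ca" in mn:
        params.soma = replace(params.soma, e_ca_mode=mn["soma_e_ca"])
    if "dend_e_ca" in mn:
        params.dend = replace(params.dend, e_ca_mode=mn["dend_e_ca"])
    return params


def muscle_from_config(cfg: dict) -> MuscleParameters:
    mc = cfg.get("muscle", {}) or {}
    params = default_muscle_parameters(P0_ratio=float(mc.get("P_0", 1.0)))
    for section in ("m1", "m2", "m3"):
        for key, val in (mc.get(section, {}) or {}).items():
            sub = getattr(params, section)
            if not hasattr(sub, key):
                raise KeyError(f"unknown muscle.{section} key {key!r}")
            setattr(sub, key, float(val))
    return params


def spec_from_config(cfg: dict, model: str) -> SimulationSpec:
    eng = cfg.get("engine", {}) or {}
    return SimulationSpec(
        model=model,
        t_end=float(eng.get("t_end", 1000.0)),
        dt=float(eng.get("dt", 0.1)),
        solver=eng.get("solver"),
        rtol=float(eng.get("rtol", 1e-6)),
        atol=float(eng.get("atol", 1e-8)),
        seed=eng.get("seed"),
    )


def motorunit_from_config(cfg: dict) -> MotorUnitParameters:
    delay = float((cfg.get("axon", {}) or {}).get("delay_ms", 2.0))
    return MotorUnitParameters(neuron=motoneuron_from_config(cfg),
                               muscle=muscle_from_config(cfg),
                               axon_delay=delay)
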