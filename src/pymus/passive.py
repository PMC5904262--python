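"""Passive two-compartment cable: forward "virtual measurements" and inversion.

The reduced motoneuron collapses soma (plus hillock/initial segment) and the
whole dendritic tree into two isopotential compartments joined by a coupling
conductance.  Its passive behavior is fully described by five cable constants
(two specific membrane conductances, two specific capacitances, one coupling
conductance).  Rather than assigning those constants directly, they are
constrained *simultaneously* from five quantities an electrophysiologist can
measure on the real cell:

* ``R_N``      somatic input resistance (MΩ),
* ``tau_m``    slowest membrane time constant (ms),
* ``VA_SD_DC`` soma→dendrite voltage attenuation for DC input at the soma,
* ``VA_DS_DC`` dendrite→soma voltage attenuation for DC input at the dendrite,
* ``VA_SD_AC`` soma→dendrite attenuation magnitude for a sinusoidal input at
  probe frequency ``f_AC``.

This module defines the forward measurements exactly on the circuit and the
closed-form inversion against them.  Unit convention (repo-wide): mV, ms, nA,
MΩ, mS/cm², µF/cm², cm².  Internally absolute conductances are in mS and
capacitances in µF, so that R = 1/g is in kΩ and τ = c/g in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import FeasibilityError, InvalidParameterError

__all__ = [
    "SystemProperties",
    "CableParameters",
    "measure_RN",
    "measure_tau",
    "measure_VAs",
    "invert_passive",
]

#: kΩ → MΩ
_KOHM_TO_MOHM = 1e-3


@dataclass(frozen=True)
class SystemProperties:
    """Measurable passive targets of the reduced motoneuron.

    ``p`` is the somatic-to-dendritic surface-area ratio, ``A_total`` the total
    membrane area (cm²) and ``f_AC`` the probe frequency (Hz) at which the AC
    attenuation is defined.
    """

    R_N: float            # MΩ
    tau_m: float          # ms
    VA_SD_DC: float
    VA_DS_DC: float
    VA_SD_AC: float
    p: float = 0.1
    A_total: float = 1e-3  # cm²
    f_AC: float = 200.0    # Hz

    def __post_init__(self):
        if self.R_N <= 0 or self.tau_m <= 0:
            raise InvalidParameterError("R_N and tau_m must be positive")
        for name in ("VA_SD_DC", "VA_DS_DC", "VA_SD_AC"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise InvalidParameterError(f"{name} must lie in (0, 1]")
        if self.VA_SD_AC > self.VA_SD_DC:
            raise InvalidParameterError(
                "VA_SD_AC must not exceed VA_SD_DC (AC attenuates more than DC)")
        if self.p <= 0 or self.A_total <= 0:
            raise InvalidParameterError("p and A_total must be positive")
        if self.f_AC < 0:
            raise InvalidParameterError("f_AC must be non-negative")


@dataclass(frozen=True)
class CableParameters:
    """The five cable constants plus compartment areas.

    Specific quantities (per cm² of the owning compartment); the coupling
    conductance ``G_C`` is specific per *total* membrane area.  Properties
    ``g_S``/``g_D``/``g_C``/``c_S``/``c_D`` expose the absolute values (mS, µF)
    used by every circuit formula.
    """

    G_mS: float   # mS/cm²
    G_mD: float   # mS/cm²
    G_C: float    # mS/cm² of A_total
    C_mS: float   # µF/cm²
    C_mD: float   # µF/cm²
    A_S: float    # cm²
    A_D: float    # cm²

    def __post_init__(self):
        for name in ("G_mS", "G_mD", "G_C", "C_mS", "C_mD", "A_S", "A_D"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def p(self) -> float:
        return self.A_S / self.A_D

    @property
    def A_total(self) -> float:
        return self.A_S + self.A_D

    @property
    def g_S(self) -> float:
        return self.G_mS * self.A_S

    @property
    def g_D(self) -> float:
        return self.G_mD * self.A_D

    @property
    def g_C(self) -> float:
        return self.G_C * self.A_total

    @property
    def c_S(self) -> float:
        return self.C_mS * self.A_S

    @property
    def c_D(self) -> float:
        return self.C_mD * self.A_D

    def system_matrix(self) -> np.ndarray:
        """Relaxation-rate matrix A of dV/dt = -A·V (1/ms)."""
        gS, gD, gC, cS, cD = self.g_S, self.g_D, self.g_C, self.c_S, self.c_D
        return np.array([[(gS + gC) / cS, -gC / cS],
                         [-gC / cD, (gD + gC) / cD]])


def measure_RN(cable: CableParameters) -> float:
    """Somatic input resistance (MΩ): steady-state V_S/I for DC current at the soma."""
    gS, gD, gC = cable.g_S, cable.g_D, cable.g_C
    r_kohm = (gD + gC) / (gS * gD + gS * gC + gD * gC)
    return r_kohm * _KOHM_TO_MOHM


def measure_tau(cable: CableParameters) -> float:
    """Slowest relaxation time constant (ms) of the passive circuit."""
    lam = np.linalg.eigvals(cable.system_matrix())
    lam_min = float(np.min(lam.real))
    return 1.0 / lam_min


def measure_VAs(cable: CableParameters, f_AC: float) -> tuple[float, float, float]:
    """Voltage-attenuation factors (VA_SD_DC, VA_DS_DC, VA_SD_AC).

    VA is the ratio of voltage at the measurement site to voltage at the
    stimulation site; the AC factor is the amplitude ratio at sinusoidal
    steady state for probe frequency ``f_AC`` (Hz).
    """
    if f_AC < 0:
        raise InvalidParameterError("f_AC must be non-negative")
    gS, gD, gC, cD = cable.g_S, cable.g_D, cable.g_C, cable.c_D
    va_sd_dc = gC / (gC + gD)
    va_ds_dc = gC / (gC + gS)
    omega = 2.0 * math.pi * f_AC * 1e-3  # rad/ms
    va_sd_ac = abs(gC / (gC + gD + 1j * omega * cD))
    return va_sd_dc, va_ds_dc, va_sd_ac


def invert_passive(props: SystemProperties) -> CableParameters:
    """Constrain all five cable parameters from the five system properties.

    Closed form: with a = VA_SD_DC, b = VA_DS_DC,

    * g_C = b / (R_N · (1 − a·b)),  g_D = g_C (1−a)/a,  g_S = g_C (1−b)/b,
    * c_D from the AC attenuation magnitude at ω = 2π f_AC,
    * c_S from requiring 1/τ_m to be the smaller eigenvalue of the system
      matrix.

    Raises :class:`FeasibilityError` (naming the violated constraint, with
    residual diagnostics) when no positive-parameter solution exists — e.g.
    when the probe frequency is too low for the requested AC attenuation to
    coexist with the requested time constant.
    """
    a, b, c = props.VA_SD_DC, props.VA_DS_DC, props.VA_SD_AC
    R = props.R_N / _KOHM_TO_MOHM  # kΩ

    g_C = b / (R * (1.0 - a * b))
    g_D = g_C * (1.0 - a) / a
    g_S = g_C * (1.0 - b) / b

    if c >= a:
        raise FeasibilityError(
            "VA_SD_AC must be strictly below VA_SD_DC for a finite dendritic "
            "capacitance", constraint="VA_SD_AC < VA_SD_DC",
            residuals={"VA_SD_AC": c, "VA_SD_DC": a})
    omega = 2.0 * math.pi * props.f_AC * 1e-3
    if omega <= 0:
        raise FeasibilityError(
            "f_AC must be positive to constrain C_mD from the AC attenuation",
            constraint="f_AC > 0", residuals={"f_AC": props.f_AC})
    c_D = (g_C / omega) * math.sqrt(1.0 / c**2 - 1.0 / a**2)

    lam = 1.0 / props.tau_m
    delta = (g_D + g_C) / c_D
    disc = (g_S + g_C) * (g_D + g_C) - g_C**2
    num = (g_S + g_C) * lam - disc / c_D
    den = lam * (lam - delta)
    if den == 0 or num / den <= 0:
        raise FeasibilityError(
            "target (tau_m, VA_SD_AC, f_AC) combination admits no positive "
            "somatic capacitance; raise f_AC or tau_m",
            constraint="C_mS > 0",
            residuals={"c_S_candidate": num / den if den else math.inf,
                       "c_D": c_D, "lambda": lam, "delta": delta})
    c_S = num / den

    A_D = props.A_total / (1.0 + props.p)
    A_S = props.A_total - A_D
    cable = CableParameters(
        G_mS=g_S / A_S, G_mD=g_D / A_D, G_C=g_C / props.A_total,
        C_mS=c_S / A_S, C_mD=c_D / A_D, A_S=A_S, A_D=A_D)

    # 1/tau must be the *slowest* mode of the constructed circuit.
    tau_back = measure_tau(cable)
    if not math.isclose(tau_back, props.tau_m, rel_tol=1e-9):
        raise FeasibilityError(
            "requested tau_m is not the slowest mode of any positive-parameter "
            "circuit satisfying the other four targets",
            constraint="tau_m = slowest mode",
            residuals={"tau_requested": props.tau_m, "tau_realized": tau_back})
    return cable


def forward_measurements(cable: CableParameters, f_AC: float) -> SystemProperties:
    """Convenience: full virtual-measurement quintuple of a cable."""
    va_sd_dc, va_ds_dc, va_sd_ac = measure_VAs(cable, f_AC)
    return SystemProperties(
        R_N=measure_RN(cable), tau_m=measure_tau(cable),
        VA_SD_DC=va_sd_dc, VA_DS_DC=va_ds_dc, VA_SD_AC=va_sd_ac,
        p=cable.p, A_total=cable.A_total, f_AC=f_AC)
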