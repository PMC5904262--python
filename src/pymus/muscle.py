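"""Spike-driven muscle unit: calcium kinetics, activation, Hill-type mechanics.

The muscle unit (all fibers innervated by one motoneuron, modeled as one
averaged fiber plus a series elastic tendon) transforms the arriving spike
train into force through three modules:

* **Module 1** — sarcoplasmic calcium.  Each spike triggers a release flux
  from the sarcoplasmic-reticulum (SR) free-calcium pool through a
  double-exponential kernel (rise τ₁, decay τ₂); a single rate constant K
  pumps sarcoplasmic calcium back into the SR.  Inside the SR calcium
  exchanges with calsequestrin; in the sarcoplasm it exchanges with a generic
  buffer and with troponin.  The troponin on-rate (K5) increases with muscle
  length, which makes short muscle disproportionately weak at physiological
  (sub-tetanic) stimulation rates.  Total calcium over the five pools is
  conserved.

* **Module 2** — activation.  The calcium–troponin concentration drives an
  intermediate activation Ã through first-order relaxation toward a
  sigmoidal steady state (cross-bridge cooperativity), with a
  concentration-dependent time constant in the Morris–Lecar style; the
  effective activation is A = Ã^α.

* **Module 3** — mechanics.  Tendon force is the series-elastic stiffness
  times the difference between the muscle-length and contractile-element
  deviations from their initial lengths, floored at 0 (a tendon cannot
  push).  The contractile-element velocity inverts a Hill-type
  force–velocity relation with distinct shortening and lengthening branches
  (coefficients a0–d0), scaled by activation and by the bell-shaped
  force–length factor.  a0 and c0 scale with the muscle-unit-to-whole-muscle
  peak-force ratio P0_ratio.

Length convention: X_m = 0 mm is the physiological maximum, −16 mm the
minimum, −8 mm the optimum; positive contractile-element velocity means
lengthening.  All module constants are this package's own calibration of the
cat-soleus model family (twitch/unfused/fused behavior over 1–40 Hz),
recorded with the defaults below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FeasibilityError, InvalidParameterError
from .stimuli import XM_OPTIMAL, XM_RANGE, SpikeTrain

__all__ = [
    "CalciumParams1", "ActivationParams", "MechanicsParams",
    "HillMassimaCoefficients", "VelocityTensionAnchors", "MuscleParameters",
    "MuscleModel", "fl_factor", "solve_hill_massima_coeffs", "ce_velocity",
    "activation_derivative", "effective_activation", "hill_massima_force",
    "se_force", "release_kernel", "default_muscle_parameters",
]

# ---------------------------------------------------------------------------
# parameters

@dataclass
class CalciumParams1:
    """Module 1 constants (concentrations in relative units, rates 1/ms)."""

    ca_total: float = 1.0       # conserved total calcium over all pools
    cs_total: float = 0.6       # calsequestrin capacity (SR)
    b_total: float = 0.4        # sarcoplasmic buffer capacity
    t_total: float = 0.1        # troponin capacity
    k1: float = 0.2             # Ca_SR + CS association (1/(conc·ms))
    k2: float = 0.05            # CaCS dissociation (1/ms)
    k3: float = 0.3             # Ca_SP + B association
    k4: float = 0.01            # CaB dissociation
    k5: float = 0.4             # Ca_SP + T association at optimal length
    k6: float = 0.04            # CaT dissociation
    k5_length_gain: float = 0.12  # 1/mm; K5(X_m) = k5·exp(gain·(X_m − X_opt))
    tau1: float = 1.5           # release rise time constant (ms)
    tau2: float = 3.0           # release decay time constant (ms)
    r_max: float = 2.5          # release rate scale (1/ms, × Ca_SR × kernel)
    k_uptake: float = 0.25      # reuptake rate K (1/ms)

    def k5_of_length(self, X_m: float) -> float:
        return self.k5 * float(np.exp(self.k5_length_gain * (X_m - XM_OPTIMAL)))


@dataclass
class ActivationParams:
    """Module 2 constants."""

    cat_half: float = 0.04      # sigmoid midpoint (CaT units)
    n_hill: float = 4.0         # cooperativity
    tau_act: float = 25.0       # baseline relaxation time (ms)
    tau_floor: float = 8.0      # minimum relaxation time (ms)
    alpha: float = 2.0          # A = Ã^α

    def a_inf(self, CaT):
        CaT = np.maximum(CaT, 0.0)
        h = CaT ** self.n_hill
        return h / (h + self.cat_half ** self.n_hill)

    def tau(self, CaT):
        # Morris–Lecar-style: fastest near the sigmoid midpoint
        z = (CaT - self.cat_half) / (2.0 * self.cat_half)
        return self.tau_floor + (self.tau_act - self.tau_floor) / np.cosh(z)


@dataclass(frozen=True)
class HillMassimaCoefficients:
    """Force–velocity coefficients: shortening (a0, b0), lengthening (c0, d0).

    Shortening (Hill): (F + a0)(b0 − V) = (F0 + a0)·b0 for V ≤ 0.
    Lengthening:       F = c0 − (c0 − F0)·d0/(d0 + V) for V ≥ 0,
    where F0 is the instantaneous isometric capacity and c0 the eccentric
    force asymptote at full activation.  a0, c0 in N; b0, d0 in mm/ms.
    """

    a0: float
    b0: float
    c0: float
    d0: float


@dataclass(frozen=True)
class VelocityTensionAnchors:
    """Experimental anchors of the full-activation velocity–tension curve."""

    F0: float = 20.0            # whole-muscle isometric peak force (N)
    curvature: float = 0.25     # Hill a/F0
    v_max: float = 0.04         # unloaded shortening speed (mm/ms)
    ecc_asymptote: float = 1.5  # lengthening force asymptote / F0
    ecc_slope_ratio: float = 2.0  # lengthening/shortening slope ratio at V=0


@dataclass
class MechanicsParams:
    """Module 3 constants."""

    anchors: VelocityTensionAnchors = field(default_factory=VelocityTensionAnchors)
    P0_ratio: float = 1.0       # muscle-unit peak force / whole-muscle peak
    k_SE: float = 5.0           # series-elastic stiffness (N/mm)
    fl_width: float = 6.0       # force–length bell width (mm)
    X_opt: float = XM_OPTIMAL   # optimal length (mm)
    Xm_init: float = XM_OPTIMAL
    XCE_init: float = XM_OPTIMAL
    v_bound: float = 0.1        # |dX_CE/dt| saturation (mm/ms)
    capacity_reg: float = 0.01  # low-activation regularization fraction

    @property
    def P0(self) -> float:
        """Muscle-unit peak isometric force (N)."""
        return self.anchors.F0 * self.P0_ratio


@dataclass
class MuscleParameters:
    m1: CalciumParams1 = field(default_factory=CalciumParams1)
    m2: ActivationParams = field(default_factory=ActivationParams)
    m3: MechanicsParams = field(default_factory=MechanicsParams)


def default_muscle_parameters(P0_ratio: float = 1.0) -> MuscleParameters:
    p = MuscleParameters()
    p.m3 = replace(p.m3, P0_ratio=P0_ratio)
    return p


# ---------------------------------------------------------------------------
# module 3 primitives

def fl_factor(X_m: float, width: float = 6.0,
              X_opt: float = XM_OPTIMAL):
    """Bell-shaped force–length factor in (0, 1]; 1 at the optimal length.

    Lengths outside the physiological range raise a warning and are clamped.
    """
    x = np.asarray(X_m, dtype=float)
    lo, hi = XM_RANGE
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn("muscle length outside physiological range; clamping",
                      stacklevel=2)
        x = np.clip(x, lo, hi)
    out = np.exp(-((x - X_opt) / width) ** 2)
    return out if out.ndim else float(out)


def solve_hill_massima_coeffs(anchors: VelocityTensionAnchors,
                              P0_ratio: float = 1.0) -> HillMassimaCoefficients:
    """Coefficients from velocity–tension anchors; a0, c0 scale with P0_ratio.

    The anchors are reproduced exactly: F(V=0) = F0, F(−v_max) = 0, the
    lengthening asymptote is ecc_asymptote·F0 and the lengthening branch is
    ecc_slope_ratio times steeper than the shortening branch at V = 0.
    """
    a = anchors
    if a.F0 <= 0 or a.v_max <= 0:
        raise FeasibilityError("isometric force and v_max must be positive",
                               constraint="F0, v_max > 0")
    if a.ecc_asymptote <= 1.0:
        raise FeasibilityError(
            "lengthening asymptote must exceed isometric force",
            constraint="ecc_asymptote > 1")
    if not (0.0 < P0_ratio <= 1.0):
        raise InvalidParameterError("P0_ratio must lie in (0, 1]")
    F0 = a.F0 * P0_ratio
    a0 = a.curvature * F0
    # V(F=0) = −b0·F0/a0  =>  b0 = v_max·curvature
    b0 = a.v_max * a.curvature
    c0 = a.ecc_asymptote * F0
    s_short = (F0 + a0) / b0
    d0 = (c0 - F0) / (a.ecc_slope_ratio * s_short)
    return HillMassimaCoefficients(a0=a0, b0=b0, c0=c0, d0=d0)


def hill_massima_force(V: float, F0_inst: float,
                       coeffs: HillMassimaCoefficients) -> float:
    """Forward force–velocity relation at isometric capacity ``F0_inst``."""
    c = coeffs
    if V <= 0:
        return max((F0_inst + c.a0) * c.b0 / (c.b0 - V) - c.a0, 0.0)
    return c.c0 - (c.c0 - F0_inst) * c.d0 / (c.d0 + V)


def ce_velocity(A: float, X_m: float, F_CE: float,
                coeffs: HillMassimaCoefficients, mech: MechanicsParams) -> float:
    """Contractile-element velocity (mm/ms) by inverting the F–V relation.

    Negative = shortening.  Zero when the load equals the instantaneous
    isometric capacity A·fl(X_m)·P0; below it the element shortens (down to
    the unloaded-velocity asymptote), above it it lengthens.  The lengthening
    asymptote and the Hill constant scale with the instantaneous capacity
    (exactly c0 and a0 at full activation), so a nearly passive element
    yields under load; a small capacity floor (``capacity_reg``·P0, vanishing
    at full activation) keeps the inverse relation's slope bounded as the
    capacity goes to zero.  Velocities saturate at ±``mech.v_bound``.
    """
    A = min(max(A, 0.0), 1.0)
    F0i = A * fl_factor(X_m, mech.fl_width, mech.X_opt) * mech.P0
    vb = mech.v_bound
    P0 = mech.P0
    reg = mech.capacity_reg * (P0 - F0i)  # 0 at full activation
    if F_CE <= F0i:
        # shortening branch: V = b0 (F − F0)/(F + a) ≤ 0
        a_i = coeffs.a0 * (F0i + reg) / P0
        v = coeffs.b0 * (F_CE - F0i) / (F_CE + a_i)
        return max(v, -vb)
    c_inst = (coeffs.c0 / P0) * F0i + reg
    if F_CE >= c_inst:
        return vb
    v = coeffs.d0 * (F_CE - F0i) / (c_inst - F_CE)
    return min(v, vb)


def se_force(X_m: float, X_CE: float, mech: MechanicsParams) -> float:
    """Tendon force (N): k_SE·[(X_m − X_m,init) − (X_CE − X_CE,init)], ≥ 0."""
    stretch = (X_m - mech.Xm_init) - (X_CE - mech.XCE_init)
    return max(mech.k_SE * stretch, 0.0)


# ---------------------------------------------------------------------------
# module 2 primitives

def activation_derivative(CaT: float, atilde: float,
                          m2: ActivationParams) -> float:
    """dÃ/dt: first-order relaxation toward the sigmoidal steady state with a
    calcium–troponin-dependent time constant."""
    if CaT < 0:
        raise InvalidParameterError("CaT must be non-negative")
    return (float(m2.a_inf(CaT)) - atilde) / float(m2.tau(CaT))


def effective_activation(atilde: float, alpha: float) -> float:
    """A = Ã^α, clipped to [0, 1]."""
    return min(max(atilde, 0.0), 1.0) ** alpha


# ---------------------------------------------------------------------------
# module 1 primitives

def release_kernel(s, tau1: float, tau2: float):
    """Per-spike SR release kernel (1 − e^{−s/τ1})·e^{−s/τ2} for s ≥ 0."""
    s = np.asarray(s, dtype=float)
    out = np.where(s >= 0.0, (1.0 - np.exp(-s / tau1)) * np.exp(-s / tau2), 0.0)
    return out if out.ndim else float(out)


class MuscleModel:
    """State layout and right-hand side of the three coupled modules.

    State: ``[Ca_SR, CaCS, Ca_SP, CaB, CaT, Atilde, X_CE]``.  The right-hand
    side is a pure function of (t, state, spike list, X_m signal); spikes
    older than the bounded kernel window contribute nothing.
    """

    names = ["Ca_SR", "CaCS", "Ca_SP", "CaB", "CaT", "Atilde", "X_CE"]
    n_states = 7

    def __init__(self, params: MuscleParameters):
        self.p = params
        self.coeffs = solve_hill_massima_coeffs(params.m3.anchors,
                                                params.m3.P0_ratio)
        m1 = params.m1
        self.kernel_window = 5.0 * max(m1.tau1, m1.tau2)

    def initial_state(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        """Quiescent rest: all free calcium in the SR in equilibrium with
        calsequestrin; sarcoplasmic pools at trace levels; CE at its initial
        length."""
        m1 = self.p.m1
        # Solve CaSR + CaCS = ca_total with k1·CaSR·(CS_tot − CaCS) = k2·CaCS
        # => quadratic in CaCS
        k = m1.k1 / m1.k2
        # CaCS = k·CaSR·CS_tot/(1 + k·CaSR), CaSR = ca_total − CaCS
        ca_sr = m1.ca_total
        for _ in range(200):
            cacs = k * ca_sr * m1.cs_total / (1.0 + k * ca_sr)
            ca_sr_new = m1.ca_total - cacs
            if abs(ca_sr_new - ca_sr) < 1e-15:
                ca_sr = ca_sr_new
                break
            ca_sr = ca_sr_new
        y = np.array([ca_sr, m1.ca_total - ca_sr, 0.0, 0.0, 0.0, 0.0,
                      self.p.m3.XCE_init])
        if overrides:
            for name, val in overrides.items():
                y[self.names.index(name)] = val
        return y

    def release_drive(self, t: float, spikes: np.ndarray) -> float:
        """Superposed spike kernels within the bounded history window."""
        if spikes.size == 0:
            return 0.0
        m1 = self.p.m1
        s = t - spikes
        mask = (s >= 0.0) & (s <= self.kernel_window)
        if not mask.any():
            return 0.0
        return float(np.sum(release_kernel(s[mask], m1.tau1, m1.tau2)))

    def force(self, y: np.ndarray, X_m: float) -> float:
        return se_force(X_m, y[6], self.p.m3)

    def activation(self, y: np.ndarray) -> float:
        return effective_activation(y[5], self.p.m2.alpha)

    def rhs(self, t: float, y: np.ndarray, spikes: np.ndarray,
            X_m_func) -> np.ndarray:
        m1, m2, m3 = self.p.m1, self.p.m2, self.p.m3
        ca_sr, cacs, ca_sp, cab, cat, atil, x_ce = y
        X_m = float(X_m_func(t))

        R = m1.r_max * self.release_drive(t, spikes) * max(ca_sr, 0.0)
        U = m1.k_uptake * max(ca_sp, 0.0)
        cs_free = max(m1.cs_total - cacs, 0.0)
        b_free = max(m1.b_total - cab, 0.0)
        t_free = max(m1.t_total - cat, 0.0)
        k5 = m1.k5_of_length(X_m)

        j_cs = m1.k1 * ca_sr * cs_free - m1.k2 * cacs
        j_b = m1.k3 * ca_sp * b_free - m1.k4 * cab
        j_t = k5 * ca_sp * t_free - m1.k6 * cat

        d_ca_sr = -R + U - j_cs
        d_cacs = j_cs
        d_ca_sp = R - U - j_b - j_t
        d_cab = j_b
        d_cat = j_t

        d_atil = activation_derivative(max(cat, 0.0), atil, m2)

        A = self.activation(y)
        F_T = se_force(X_m, x_ce, m3)
        d_xce = ce_velocity(A, X_m, F_T, self.coeffs, m3)

        return np.array([d_ca_sr, d_cacs, d_ca_sp, d_cab, d_cat,
                         d_atil, d_xce])
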