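"""Post-processing: firing rate, hysteresis, F–L / frequency–force scans,
spectral bandwidth and virtual whole-cell measurements."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .engine import SimulationResult, SimulationSpec, simulate
from .errors import InvalidParameterError
from .muscle import MuscleParameters
from .stimuli import Signal, SpikeTrain, impulse_train, length_signal, step_with_pulses

__all__ = [
    "instantaneous_firing_rate", "hysteresis_metrics", "fl_scan", "ff_scan",
    "psd_bandwidth", "measure_input_resistance_and_tau",
    "steady_isometric_force",
]


def instantaneous_firing_rate(train: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Rate 1000/ISI (Hz) assigned at the time of the later spike of each
    interval.  Returns (times, rates); empty for fewer than two spikes."""
    t = train.times
    if t.size < 2:
        return np.empty(0), np.empty(0)
    isi = np.diff(t)
    return t[1:], 1000.0 / isi


def hysteresis_metrics(train: SpikeTrain, drive: Signal) -> dict:
    """Onset/offset drive of firing on a symmetric triangular ramp.

    ``onset_drive`` is the drive at the first spike (ascending limb),
    ``offset_drive`` the drive at the last spike (descending limb);
    ``delta = onset − offset`` is positive for counterclockwise hysteresis
    (firing persists below the current that started it — the signature of
    dendritic persistent-inward-current activation).
    """
    if len(train) == 0:
        raise InvalidParameterError("no spikes: hysteresis undefined")
    onset = float(drive(train.times[0]))
    offset = float(drive(train.times[-1]))
    delta = onset - offset
    return {"onset_drive": onset, "offset_drive": offset, "delta": delta,
            "orientation": "counterclockwise" if delta > 0 else "clockwise"}


def _steady_window_mean(t, f, frac=0.2, drift_tol=0.01):
    n = max(int(t.size * frac), 2)
    tail = f[-n:]
    mean = float(tail.mean())
    drift = abs(tail[-1] - tail[0]) / max(abs(mean), 1e-12)
    return mean, drift


def steady_isometric_force(params: MuscleParameters, length_mm: float,
                           freq_hz: float | None, t_end: float = 3000.0,
                           activation_clamp: float | None = None,
                           rtol: float = 1e-6, atol: float = 1e-9) -> float:
    """Mean force over the last 20% of an isometric run.

    Either stimulate at ``freq_hz`` (regular train) or clamp the intermediate
    activation at ``activation_clamp`` (bypassing modules 1–2) to probe the
    mechanics in isolation.
    """
    xm = length_signal("isometric", duration=t_end, level=length_mm, dt=1.0)
    inputs: dict = {"X_m": xm}
    initial = {}
    if activation_clamp is not None:
        # clamp the *effective* activation A by pinning Ã = A^(1/α)
        a_t = float(activation_clamp) ** (1.0 / params.m2.alpha)
        initial = {"Atilde": a_t}
        params = _with_frozen_activation(params)
    else:
        inputs["spike_train"] = impulse_train("regular", freq_hz, t_end)
    spec = SimulationSpec(model="muscle", t_end=t_end, dt=1.0,
                          rtol=rtol, atol=atol, initial=initial)
    res = simulate(spec, params, inputs)
    mean, _ = _steady_window_mean(res.t, res.traces["F_T"])
    return mean


def _with_frozen_activation(params: MuscleParameters) -> MuscleParameters:
    """Copy of the parameters whose activation dynamics are frozen (dÃ/dt=0)."""
    import copy
    p = copy.deepcopy(params)
    p.m2.tau_act = 1e12   # dÃ/dt ≈ 0: Ã stays at its initial value
    p.m2.tau_floor = 1e12
    return p


def fl_scan(params: MuscleParameters, lengths: np.ndarray,
            activation: float = 1.0, t_end: float = 1500.0) -> dict:
    """Steady isometric force over a length grid at clamped activation.

    Returns the curve and the argmax length (the embedded optimum)."""
    lengths = np.asarray(lengths, dtype=float)
    forces = np.array([
        steady_isometric_force(params, L, None, t_end,
                               activation_clamp=activation)
        for L in lengths])
    return {"lengths": lengths, "forces": forces,
            "argmax_length": float(lengths[int(np.argmax(forces))])}


def ff_scan(params: MuscleParameters, freqs, length_mm: float = -8.0,
            t_end: float = 3000.0) -> dict:
    """Steady isometric force versus stimulation frequency at one length."""
    freqs = np.asarray(freqs, dtype=float)
    forces = np.array([steady_isometric_force(params, length_mm, f, t_end)
                       for f in freqs])
    return {"frequencies": freqs, "forces": forces,
            "nondecreasing": bool(np.all(np.diff(forces) >= -1e-9))}


def psd_bandwidth(sig: Signal, power_fraction: float = 0.99) -> float:
    """Smallest frequency (Hz) below which ``power_fraction`` of the total
    (detrended) spectral power lies; segment-averaged periodogram (Welch)."""
    if not (0.0 < power_fraction <= 1.0):
        raise InvalidParameterError("power_fraction must be in (0, 1]")
    fs = 1000.0 / sig.dt  # Hz
    v = sps.detrend(sig.values)
    nper = min(v.size, max(int(round(10.0 * fs)), 256))  # ≥0.1 Hz resolution
    f, p = sps.welch(v, fs=fs, nperseg=nper)
    cum = np.cumsum(p)
    cum /= cum[-1]
    idx = int(np.searchsorted(cum, power_fraction))
    return float(f[min(idx, f.size - 1)])


def measure_input_resistance_and_tau(res: SimulationResult, I_step_nA: float,
                                     t_on: float, t_off: float) -> dict:
    """Virtual whole-cell measurement from a small somatic current step.

    R_N from the steady-state somatic deflection divided by the current;
    τ_m from a late-phase exponential fit of the relaxation after step
    offset.
    """
    t, v = res.t, res.traces["V_soma"]
    v_rest = float(np.mean(v[t < t_on])) if np.any(t < t_on) else float(v[0])
    pre_off = (t > t_on + 0.8 * (t_off - t_on)) & (t <= t_off)
    v_ss = float(np.mean(v[pre_off]))
    R_N = (v_ss - v_rest) / I_step_nA  # mV/nA = MΩ
    # relaxation after offset: fit late phase (one slow exponential)
    mask = t > t_off
    tr, vr = t[mask], v[mask]
    dv = vr - v_rest
    amp0 = dv[0]
    # late phase: after the fast mode has decayed, between 60% and 5% of amp
    sel = (np.abs(dv) < 0.6 * abs(amp0)) & (np.abs(dv) > 0.05 * abs(amp0))
    if sel.sum() < 4:
        raise InvalidParameterError("decay window too short for a tau fit")
    slope, _ = np.polyfit(tr[sel], np.log(np.abs(dv[sel])), 1)
    tau = -1.0 / slope
    return {"R_N": R_N, "tau_m": tau, "V_rest": v_rest, "V_step": v_ss}
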