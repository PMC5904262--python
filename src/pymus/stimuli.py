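"""Input-signal generators for the virtual-experiment protocols.

Covers every input family the protocols use: somatic current steps with
alternating excitatory/inhibitory pulses, symmetric triangular current ramps,
synaptic-conductance profiles with optional intensity-proportional noise,
regular and Gaussian-random impulse trains for direct axonal stimulation, and
muscle-length trajectories (isometric, isokinetic and band-limited
locomotor-like movement).  Every stochastic generator is a pure function of
its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, SignalParseError

__all__ = [
    "Signal",
    "step_with_pulses",
    "triangular_ramp",
    "synaptic_conductance",
    "impulse_train",
    "length_signal",
    "import_signal",
    "export_signal",
]

#: physiological muscle-length range (mm): 0 = maximum, −16 = minimum
XM_RANGE = (-16.0, 0.0)
XM_OPTIMAL = -8.0


@dataclass
class Signal:
    """Uniformly sampled time series (ms grid).

    ``interp`` selects how the engine evaluates between samples: ``"linear"``
    for smooth signals, ``"hold"`` (zero-order) for piecewise-constant
    protocols whose edges must be exact.  ``breakpoints`` lists times of
    genuine discontinuities/corners so the integrator can restart there.
    """

    t0: float
    dt: float
    values: np.ndarray
    units: str
    interp: str = "linear"
    seed: int | None = None
    breakpoints: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("signal contains non-finite values")
        if not self.units:
            raise InvalidParameterError("units label is required")
        if self.interp not in ("linear", "hold"):
            raise InvalidParameterError("interp must be 'linear' or 'hold'")
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    def __call__(self, t):
        """Evaluate at time(s) t; constant extrapolation outside the support."""
        t = np.asarray(t, dtype=float)
        if self.interp == "hold":
            idx = np.clip(
                np.floor((t - self.t0) / self.dt + 1e-9).astype(int),
                0, self.values.size - 1)
            out = self.values[idx]
        else:
            out = np.interp(t, self.t, self.values)
        return out if out.ndim else float(out)

    def resample(self, t0: float, dt: float, n: int) -> "Signal":
        grid = t0 + dt * np.arange(n)
        return Signal(t0, dt, self(grid), self.units, "linear",
                      self.seed, self.breakpoints)


def _grid(duration: float, dt: float) -> np.ndarray:
    return np.arange(0.0, duration + dt / 2, dt)


def step_with_pulses(I0: float, t_on: float, t_off: float, *,
                     pulse_amp: float = 0.0, pulse_dur: float = 0.0,
                     pulse_times: list[float] | None = None,
                     first_pulse_excitatory: bool = True,
                     duration: float | None = None, dt: float = 0.1,
                     units: str = "nA") -> Signal:
    """Long-lasting step with alternating excitatory/inhibitory pulses.

    Baseline 0 outside [t_on, t_off]; ``I0`` during the step; rectangular
    pulses of ``pulse_amp``/``pulse_dur`` superposed at ``pulse_times`` with
    alternating sign (first sign set by ``first_pulse_excitatory``).
    """
    pulse_times = list(pulse_times or [])
    if any(pt < t_on or pt + pulse_dur > t_off for pt in pulse_times):
        raise InvalidParameterError("pulse epochs must lie within [t_on, t_off]")
    if sorted(pulse_times) != pulse_times:
        raise InvalidParameterError("pulse_times must be ordered")
    duration = duration if duration is not None else t_off + (t_off - t_on) * 0.0
    duration = max(duration, t_off)
    t = _grid(duration, dt)
    v = np.zeros_like(t)
    v[(t >= t_on) & (t < t_off)] = I0
    bps = [t_on, t_off]
    sign = 1.0 if first_pulse_excitatory else -1.0
    for pt in pulse_times:
        v[(t >= pt) & (t < pt + pulse_dur)] += sign * pulse_amp
        bps += [pt, pt + pulse_dur]
        sign = -sign
    return Signal(0.0, dt, v, units, "hold", breakpoints=np.unique(bps))


def triangular_ramp(peak: float, duration: float, t_start: float = 0.0, *,
                    dt: float = 0.1, baseline: float = 0.0,
                    total: float | None = None, units: str = "nA") -> Signal:
    """Symmetric triangular ramp: linear rise to ``peak`` at the midpoint,
    linear fall back to ``baseline`` at ``t_start + duration``."""
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    total = total if total is not None else t_start + duration
    t = _grid(max(total, t_start + duration), dt)
    half = duration / 2.0
    frac = np.clip(1.0 - np.abs((t - t_start - half) / half), 0.0, 1.0)
    v = baseline + (peak - baseline) * frac
    v[(t < t_start) | (t > t_start + duration)] = baseline
    bps = np.array([t_start, t_start + half, t_start + duration])
    return Signal(0.0, dt, v, units, "linear", breakpoints=bps)


def _ou_noise(n: int, dt: float, sd: float, tau_c: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path with SD ``sd`` and correlation time
    ``tau_c`` (ms), sampled exactly at the grid spacing."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    rho = np.exp(-dt / tau_c)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def synaptic_conductance(profile: str, *, G0: float = 0.0, Gp: float = 0.0,
                         duration: float = 10000.0, t_start: float = 0.0,
                         total: float | None = None,
                         pulse_amp: float = 0.0, pulse_dur: float = 0.0,
                         pulse_times: list[float] | None = None,
                         noise: bool = False, noise_fraction: float = 0.05,
                         noise_tau: float = 10.0,
                         seed: int | None = None, dt: float = 0.5,
                         units: str = "mS/cm^2") -> Signal:
    """Synaptic-conductance profile (normalized specific conductance).

    ``profile`` is ``"ramp"`` (triangle from G0 up to Gp and back) or
    ``"step"`` (step of amplitude Gp between t_start and t_start+duration,
    optionally with alternating pulses).  With ``noise`` on, a zero-mean
    first-order (Ornstein–Uhlenbeck) Gaussian process is added whose standard
    deviation is ``noise_fraction`` times the profile's maximum conductance —
    the noise amplitude grows in proportion to the input intensity.  The
    result is floored at 0 (conductances cannot be negative).
    """
    if G0 < 0 or Gp < 0:
        raise InvalidParameterError("conductances must be non-negative")
    if profile == "ramp":
        base = triangular_ramp(Gp, duration, t_start, dt=dt, baseline=G0,
                               total=total, units=units)
    elif profile == "step":
        base = step_with_pulses(Gp, t_start, t_start + duration,
                                pulse_amp=pulse_amp, pulse_dur=pulse_dur,
                                pulse_times=pulse_times,
                                duration=total, dt=dt, units=units)
    else:
        raise InvalidParameterError(f"unknown synaptic profile {profile!r}")
    v = base.values.copy()
    if noise:
        rng = np.random.default_rng(seed)
        gmax = float(np.max(np.abs(v))) or Gp or G0
        v = v + _ou_noise(v.size, dt, noise_fraction * gmax, noise_tau, rng)
    v = np.maximum(v, 0.0)
    return Signal(0.0, dt, v, units, "linear" if noise else base.interp,
                  seed=seed if noise else None, breakpoints=base.breakpoints)


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing event times (ms)."""

    times: np.ndarray
    source: str = "external"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise InvalidParameterError(
                "spike times must be strictly increasing and non-negative")

    def __len__(self):
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def impulse_train(mode: str, mean_freq: float, duration: float, *,
                  sd_freq: float = 0.0, t_start: float = 0.0,
                  seed: int | None = None,
                  min_freq: float = 0.1) -> SpikeTrain:
    """Axonal impulse train at a regular or Gaussian-random rate.

    ``regular``: exact ISI of 1000/mean_freq ms.  ``random``: each event's
    instantaneous frequency is drawn from N(mean, sd) truncated below at
    ``min_freq`` Hz (prevents infinite intervals); the next ISI is 1000/f.
    Events lie in [t_start, t_start + duration).
    """
    if mean_freq <= 0:
        raise InvalidParameterError("mean_freq must be positive")
    if mode not in ("regular", "random"):
        raise InvalidParameterError("mode must be 'regular' or 'random'")
    times = []
    t = t_start
    rng = np.random.default_rng(seed)
    while t < t_start + duration - 1e-9:
        times.append(t)
        if mode == "regular" or sd_freq == 0.0:
            f = mean_freq
        else:
            f = max(rng.normal(mean_freq, sd_freq), min_freq)
        t += 1000.0 / f
    return SpikeTrain(np.array(times), source="external")


def length_signal(mode: str, *, duration: float = 2000.0, dt: float = 0.1,
                  level: float = XM_OPTIMAL, start: float | None = None,
                  end: float | None = None, excursion: float = 6.0,
                  center: float = XM_OPTIMAL, cutoff_hz: float = 3.0,
                  numtaps: int = 14001, seed: int | None = None) -> Signal:
    """Muscle-length trajectory X_m (mm; 0 = physiological maximum).

    ``isometric``: constant ``level``.  ``isokinetic``: constant-velocity ramp
    from ``start`` to ``end`` over ``duration``.  ``dynamic``: locomotor-like
    movement — white uniform noise at 10 kHz low-pass filtered with a
    Blackman-window FIR (unity DC gain), rescaled to ``excursion`` mm
    peak-to-peak, centered on the −8 mm operating point and clipped to the
    physiological range.  The filter is specified so essentially all signal
    power lies below 5 Hz, matching soleus length changes during unrestrained
    locomotion.
    """
    lo, hi = XM_RANGE
    if mode == "isometric":
        if not lo <= level <= hi:
            raise InvalidParameterError("isometric level outside [-16, 0] mm")
        t = _grid(duration, dt)
        return Signal(0.0, dt, np.full(t.size, level), "mm", "hold")
    if mode == "isokinetic":
        if start is None or end is None:
            raise InvalidParameterError("isokinetic mode needs start and end")
        if not (lo <= start <= hi and lo <= end <= hi):
            raise InvalidParameterError("isokinetic endpoints outside [-16, 0] mm")
        t = _grid(duration, dt)
        v = start + (end - start) * t / duration
        return Signal(0.0, dt, v, "mm", "linear",
                      breakpoints=np.array([0.0, duration]))
    if mode == "dynamic":
        fs = 10_000.0  # Hz generation rate
        dt_gen = 1000.0 / fs  # 0.1 ms
        n = int(round(duration / dt_gen)) + 1
        rng = np.random.default_rng(seed)
        white = rng.uniform(-1.0, 1.0, size=n + numtaps)
        taps = sps.firwin(numtaps, cutoff_hz, window="blackman", fs=fs)
        filt = sps.fftconvolve(white, taps, mode="valid")[:n]
        filt = filt - filt.mean()
        ptp = np.ptp(filt)
        if ptp > 0:
            filt = filt * (excursion / ptp)
        v = np.clip(center + filt, lo, hi)
        sig = Signal(0.0, dt_gen, v, "mm", "linear", seed=seed)
        if abs(dt - dt_gen) > 1e-12:
            sig = sig.resample(0.0, dt, int(round(duration / dt)) + 1)
        return sig
    raise InvalidParameterError(f"unknown length mode {mode!r}")


def import_signal(path, units: str, interpolation: str = "linear") -> Signal:
    """Load a two-column (time_ms, value) CSV, with or without a header row.

    The series is stored on a uniform grid at the file's median sampling
    interval; non-monotonic times, missing columns and non-numeric cells raise
    :class:`SignalParseError` with the offending row number.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise SignalParseError("empty signal file", row=0)
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
        if len(parts) < 2:
            raise SignalParseError(f"row {i + 1}: expected two columns", row=i + 1)
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if i == 0:
                continue  # header row
            raise SignalParseError(f"row {i + 1}: non-numeric value", row=i + 1)
    if len(rows) < 2:
        raise SignalParseError("need at least two numeric samples", row=len(lines))
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise SignalParseError(f"row {bad}: time not strictly increasing", row=bad)
    dt = float(np.median(np.diff(t)))
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    vals = np.interp(grid, t, v)
    return Signal(float(t[0]), dt, vals, units, interpolation)


def export_signal(sig: Signal, path) -> None:
    """Write a Signal as two-column CSV with a header."""
    arr = np.column_stack([sig.t, sig.values])
    np.savetxt(path, arr, delimiter=",", header=f"time_ms,value_{sig.units}",
               comments="")
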