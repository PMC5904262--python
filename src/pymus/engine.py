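"""Time integration of the motoneuron, muscle unit and coupled motor unit.

Stiff-capable adaptive integration (BDF by default for the spiking models,
auto-switching LSODA for the muscle unit), with three robustness policies:

* **breakpoint restarts** — integration is restarted at every input
  discontinuity (step/pulse edges, ramp corners, spike deliveries) so short
  pulses are never stepped over;
* **online spike detection** — during coupled motor-unit runs an integration
  event fires at each upward somatic threshold crossing, using the same
  crossing rule as offline detection, and the spike is enqueued for delivery
  to the muscle after the axonal conduction delay;
* **dense output** — every span is sampled onto the uniform output grid, so
  traces are solver-step independent.
"""

from __future__ import annotations

import bisect
import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import axon as axon_mod
from .errors import ConfigurationError, IntegrationError
from .motoneuron import MotoneuronModel, MotoneuronParameters
from .muscle import MuscleModel, MuscleParameters
from .stimuli import Signal, SpikeTrain

__all__ = ["SimulationSpec", "SimulationResult", "MotorUnitParameters",
           "simulate", "discontinuity_schedule"]

_SOLVER_ALIASES = {
    "stiff-BDF": "BDF", "BDF": "BDF", "vode": "BDF",
    "Adams": "LSODA", "auto-switching": "LSODA", "LSODA": "LSODA",
    "RK45": "RK45",
}


@dataclass
class SimulationSpec:
    model: str                      # 'motoneuron' | 'muscle' | 'motorunit'
    t_end: float
    dt: float = 0.1                 # output grid spacing (ms)
    solver: str | None = None       # None → model default
    rtol: float = 1e-6
    atol: float = 1e-8
    initial: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    max_step: float = 10.0          # cap on solver step (ms) so slowly
                                    # forced states cannot skip input motion
    spike_threshold: float = axon_mod.DEFAULT_THRESHOLD_MV
    refractory: float = axon_mod.DEFAULT_REFRACTORY_MS

    def __post_init__(self):
        if self.model not in ("motoneuron", "muscle", "motorunit"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.t_end <= 0 or self.dt <= 0:
            raise ConfigurationError("t_end and dt must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigurationError("tolerances must be positive")

    def method(self) -> str:
        if self.solver is None:
            return "LSODA" if self.model == "muscle" else "BDF"
        if self.solver not in _SOLVER_ALIASES:
            raise ConfigurationError(f"unknown solver {self.solver!r}")
        return _SOLVER_ALIASES[self.solver]


@dataclass
class MotorUnitParameters:
    neuron: MotoneuronParameters
    muscle: MuscleParameters
    axon_delay: float = axon_mod.DEFAULT_DELAY_MS


@dataclass
class SimulationResult:
    """Time-aligned traces on a uniform grid, spike trains and metadata."""

    t: np.ndarray
    traces: dict[str, np.ndarray]
    spikes: dict[str, SpikeTrain]
    metadata: dict

    def trace_signal(self, name: str, units: str = "") -> Signal:
        dt = float(self.t[1] - self.t[0])
        return Signal(float(self.t[0]), dt, self.traces[name], units or name)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_ms": self.t, **self.traces})

    def save(self, outdir) -> None:
        import json
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "traces.csv", index=False)
        for name, train in self.spikes.items():
            np.savetxt(outdir / f"spikes_{name}.csv", train.times,
                       header="time_ms", comments="")
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def discontinuity_schedule(inputs: dict, t_end: float) -> np.ndarray:
    """All input breakpoints in [0, t_end]: signal edges and spike times.

    Always contains 0 and t_end; integration restarts at every entry so no
    pulse of finite duration can be silently skipped.
    """
    pts = [0.0, float(t_end)]
    for val in inputs.values():
        if val is None:
            continue
        if isinstance(val, Signal):
            pts.extend(float(b) for b in val.breakpoints)
        elif isinstance(val, SpikeTrain):
            pts.extend(float(s) for s in val.times)
    pts = [p for p in pts if 0.0 <= p <= t_end]
    return np.unique(np.round(np.asarray(pts), 9))


def _param_digest(obj) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def _as_func(sig):
    return sig if sig is not None else None


def _integrate_spans(rhs, y0, breakpoints, grid, method, rtol, atol,
                     stats: dict, max_step=np.inf) -> np.ndarray:
    """Integrate across fixed spans, sampling dense output onto ``grid``."""
    ys = np.empty((y0.size, grid.size))
    ys[:, 0] = y0
    y = np.array(y0, dtype=float)
    bps = list(breakpoints)
    for t0, t1 in zip(bps[:-1], bps[1:]):
        if t1 - t0 <= 1e-12:
            continue
        sol = solve_ivp(rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
                        dense_output=True, max_step=max_step)
        stats["nfev"] = stats.get("nfev", 0) + sol.nfev
        stats["spans"] = stats.get("spans", 0) + 1
        if not sol.success:
            raise IntegrationError(f"solver failed at t={sol.t[-1]:.3f} ms: "
                                   f"{sol.message}",
                                   t_last=sol.t[-1], y_last=sol.y[:, -1])
        mask = (grid > t0 + 1e-12) & (grid <= t1 + 1e-12)
        if mask.any():
            ys[:, mask] = sol.sol(np.clip(grid[mask], t0, t1))
        y = sol.y[:, -1]
    return ys


def simulate(spec: SimulationSpec, params, inputs: dict | None = None
             ) -> SimulationResult:
    """Run one virtual experiment and return its full recording.

    ``inputs`` maps input names to :class:`Signal` / :class:`SpikeTrain`
    objects (all optional): ``I_soma`` (nA), ``G_esyn_S``, ``G_isyn_S``,
    ``G_esyn_D``, ``G_isyn_D`` (mS/cm²), ``spike_train`` (axonal impulse
    train) and ``X_m`` (mm).
    """
    inputs = dict(inputs or {})
    grid = np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt)
    stats: dict = {}
    if spec.model == "motoneuron":
        result = _simulate_motoneuron(spec, params, inputs, grid, stats)
    elif spec.model == "muscle":
        result = _simulate_muscle(spec, params, inputs, grid, stats)
    else:
        result = _simulate_motorunit(spec, params, inputs, grid, stats)
    result.metadata.update({
        "model": spec.model, "t_end": spec.t_end, "dt": spec.dt,
        "solver": spec.method(), "rtol": spec.rtol, "atol": spec.atol,
        "seed": spec.seed, "parameter_digest": _param_digest(params),
        "solver_stats": stats,
    })
    return result


def _record_inputs(traces: dict, inputs: dict, grid: np.ndarray) -> None:
    for name, val in inputs.items():
        if isinstance(val, Signal):
            traces[name] = val(grid)


def _check_bounds(model: MotoneuronModel, ys: np.ndarray) -> None:
    V = ys[:2]
    if np.any(~np.isfinite(ys)):
        raise IntegrationError("non-finite state encountered")
    if V.min() < -150.0 or V.max() > 100.0:
        raise IntegrationError("membrane voltage escaped physiological bounds")


def _simulate_motoneuron(spec, params: MotoneuronParameters, inputs, grid,
                         stats) -> SimulationResult:
    model = MotoneuronModel(params)
    y0 = model.initial_state(overrides=spec.initial or None)
    funcs = {k: _as_func(inputs.get(k)) for k in
             ("I_soma", "G_esyn_S", "G_isyn_S", "G_esyn_D", "G_isyn_D")}
    bps = discontinuity_schedule(inputs, spec.t_end)
    ys = _integrate_spans(lambda t, y: model.rhs(t, y, funcs), y0, bps, grid,
                          spec.method(), spec.rtol, spec.atol, stats,
                          max_step=spec.max_step)
    _check_bounds(model, ys)
    traces = {"V_soma": ys[0], "V_dend": ys[1], "Ca_soma": ys[2],
              "Ca_dend": ys[3]}
    for i, (comp, ch, g) in enumerate(model.gate_index):
        traces[f"gate_{comp}_{ch}_{g}"] = ys[4 + i]
    _record_inputs(traces, inputs, grid)
    vsig = Signal(0.0, spec.dt, ys[0], "mV")
    spikes = axon_mod.detect_spikes(vsig, spec.spike_threshold, spec.refractory)
    return SimulationResult(grid, traces, {"soma": spikes}, {})


def _muscle_traces(model: MuscleModel, ys, grid, xm_func) -> dict:
    xm = np.asarray(xm_func(grid), dtype=float)
    a_tilde = np.clip(ys[5], 0.0, 1.0)
    A = a_tilde ** model.p.m2.alpha
    F = np.array([model.force(ys[:, i], xm[i]) for i in range(grid.size)])
    return {"Ca_SR": ys[0], "CaCS": ys[1], "Ca_SP": ys[2], "CaB": ys[3],
            "CaT": ys[4], "Atilde": a_tilde, "A": A, "X_CE": ys[6],
            "X_m": xm, "F_T": F}


def _rereference_rest_length(params: MuscleParameters,
                             xm0: float) -> MuscleParameters:
    """Anchor the series-elastic rest offsets at the trajectory's starting
    length so the preparation begins slack (rest force 0)."""
    import copy
    from dataclasses import replace as _replace
    p = copy.deepcopy(params)
    p.m3 = _replace(p.m3, Xm_init=xm0, XCE_init=xm0)
    return p


def _simulate_muscle(spec, params: MuscleParameters, inputs, grid,
                     stats) -> SimulationResult:
    train = inputs.get("spike_train") or SpikeTrain(np.empty(0))
    xm_sig = inputs.get("X_m")
    if xm_sig is None:
        xm_func = lambda t: np.full_like(np.asarray(t, dtype=float),
                                         params.m3.Xm_init)
    else:
        xm_func = xm_sig
        params = _rereference_rest_length(params, float(xm_sig(0.0)))
    model = MuscleModel(params)
    y0 = model.initial_state(overrides=spec.initial or None)
    bps = discontinuity_schedule(inputs, spec.t_end)
    spike_arr = train.times
    ys = _integrate_spans(lambda t, y: model.rhs(t, y, spike_arr, xm_func),
                          y0, bps, grid, spec.method(), spec.rtol, spec.atol,
                          stats, max_step=spec.max_step)
    traces = _muscle_traces(model, ys, grid, xm_func)
    if isinstance(xm_sig, Signal):
        traces["X_m"] = xm_sig(grid)
    return SimulationResult(grid, traces, {"delivered": train}, {})


def _simulate_motorunit(spec, params: MotorUnitParameters, inputs, grid,
                        stats) -> SimulationResult:
    """Coupled run: somatic spikes detected online feed the muscle after the
    conduction delay; each detection and each delivery restarts integration."""
    nm = MotoneuronModel(params.neuron)
    n_n = nm.n_states

    xm_sig = inputs.get("X_m")
    muscle_params = params.muscle
    if xm_sig is not None:
        xm_func = xm_sig
        muscle_params = _rereference_rest_length(muscle_params,
                                                 float(xm_sig(0.0)))
    else:
        xm_func = (lambda t: np.full_like(np.asarray(t, dtype=float),
                                          params.muscle.m3.Xm_init))
    mm = MuscleModel(muscle_params)

    init = dict(spec.initial or {})
    n_init = {k: v for k, v in init.items() if k in nm.names}
    m_init = {k: v for k, v in init.items() if k in mm.names}
    y0 = np.concatenate([nm.initial_state(overrides=n_init or None),
                         mm.initial_state(overrides=m_init or None)])

    funcs = {k: _as_func(inputs.get(k)) for k in
             ("I_soma", "G_esyn_S", "G_isyn_S", "G_esyn_D", "G_isyn_D")}
    delay = params.axon_delay

    deliveries: list[float] = []   # sorted delivery times (spike + delay)
    ext = inputs.get("spike_train")
    if isinstance(ext, SpikeTrain):
        deliveries = sorted(float(s) + delay for s in ext.times
                            if s + delay <= spec.t_end)
    delivered = np.array(deliveries)

    def rhs(t, y):
        dy = np.empty_like(y)
        dy[:n_n] = nm.rhs(t, y[:n_n], funcs)
        dy[n_n:] = mm.rhs(t, y[n_n:], delivered, xm_func)
        return dy

    thr = spec.spike_threshold

    def crossing(t, y):
        return y[0] - thr

    crossing.terminal = True
    crossing.direction = 1

    bps = list(discontinuity_schedule(inputs, spec.t_end))
    for d in deliveries:
        bisect.insort(bps, d)

    ys = np.empty((y0.size, grid.size))
    ys[:, 0] = y0
    y = y0.copy()
    t = 0.0
    method = spec.method()
    spike_times: list[float] = []
    last_spike = -np.inf
    guard = 0
    max_events = int(spec.t_end * 2) + 10_000  # > 2 kHz sustained → runaway
    while t < spec.t_end - 1e-9:
        i = bisect.bisect_right(bps, t + 1e-12)
        t1 = bps[i] if i < len(bps) else spec.t_end
        t1 = min(t1, spec.t_end)
        # honor the detection refractory: no event search until it expires
        use_events = t >= last_spike + spec.refractory
        if not use_events:
            t1 = min(t1, last_spike + spec.refractory)
        sol = solve_ivp(rhs, (t, t1), y, method=method, rtol=spec.rtol,
                        atol=spec.atol, dense_output=True,
                        max_step=spec.max_step,
                        events=[crossing] if use_events else None)
        stats["nfev"] = stats.get("nfev", 0) + sol.nfev
        stats["spans"] = stats.get("spans", 0) + 1
        if not sol.success:
            raise IntegrationError(f"solver failed at t={sol.t[-1]:.3f} ms: "
                                   f"{sol.message}",
                                   t_last=sol.t[-1], y_last=sol.y[:, -1])
        t_reached = sol.t[-1]
        mask = (grid > t + 1e-12) & (grid <= t_reached + 1e-12)
        if mask.any():
            ys[:, mask] = sol.sol(np.clip(grid[mask], t, t_reached))
        y = sol.y[:, -1]
        if use_events and sol.t_events and sol.t_events[0].size:
            ts = float(sol.t_events[0][0])
            spike_times.append(ts)
            last_spike = ts
            td = ts + delay
            if td <= spec.t_end:
                bisect.insort(bps, td)
                delivered = np.append(delivered, td)
                delivered.sort()
            guard += 1
            if guard > max_events:
                raise IntegrationError("runaway spiking: event budget exceeded",
                                       t_last=ts, y_last=y)
        t = t_reached

    _check_bounds(nm, ys[:n_n])
    traces = {"V_soma": ys[0], "V_dend": ys[1], "Ca_soma": ys[2],
              "Ca_dend": ys[3]}
    traces.update(_muscle_traces(mm, ys[n_n:], grid, xm_func))
    _record_inputs(traces, inputs, grid)
    soma = SpikeTrain(np.array(spike_times), source="motoneuron")
    deliv = SpikeTrain(np.array(sorted(delivered)), source="motoneuron")
    return SimulationResult(grid, traces, {"soma": soma, "delivered": deliv}, {})
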