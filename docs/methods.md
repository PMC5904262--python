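# Methods

## Passive two-compartment cable

The reduced motoneuron lumps the soma (with hillock and initial segment)
and the entire dendritic tree into two isopotential compartments joined by
a coupling conductance.  With absolute conductances g_S = G_m,S·A_S,
g_D = G_m,D·A_D, g_C and capacitances c_S, c_D, the forward "virtual
measurements" are defined exactly on the circuit:

* R_N = (g_D + g_C) / (g_S g_D + g_S g_C + g_D g_C);
* τ_m = 1/λ_min of the relaxation matrix
  [[(g_S+g_C)/c_S, −g_C/c_S], [−g_C/c_D, (g_D+g_C)/c_D]];
* VA_SD^DC = g_C/(g_C+g_D); VA_DS^DC = g_C/(g_C+g_S);
* VA_SD^AC = |g_C / (g_C + g_D + iωc_D)| at ω = 2π f_AC.

The inversion is closed form: g_C = b/(R_N(1−ab)) with a = VA_SD^DC,
b = VA_DS^DC, then g_D and g_S from the attenuation ratios, c_D from the AC
magnitude, and c_S from requiring 1/τ_m to be a root (verified a posteriori
to be the *smaller* root) of the characteristic polynomial.  Compartment
areas follow from the somatic/dendritic area ratio p (default 0.1) and the
total area A_total (default 1e-3 cm²; only ratios affect the dimensionless
behavior, the absolute area scales injected current into density).
Acceptance is defined by the round-trip property — measurements of the
inverted circuit reproduce the targets to 1e-6 relative — not by the
formulas themselves; a property-based test samples random positive cables.

**AC probe frequency.**  The attenuation VA_SD^AC depends on the probe
frequency f_AC, which is a required, config-exposed parameter.  The
validation target set (R_N 1.29 MΩ, τ_m 7.2 ms, VA 0.76/0.75/0.27) is only
jointly realizable for f_AC ≳ 136 Hz: below that, the dendritic capacitance
implied by the AC constraint is too large to leave a positive somatic
capacitance at τ_m = 7.2 ms.  The default is therefore **200 Hz**; the
inversion raises a feasibility error naming the violated constraint
(`C_mS > 0`) and reporting residuals when the combination is impossible.

## Active motoneuron

Voltage-gated currents use first-order Hodgkin–Huxley gating with Boltzmann
steady states x∞(V) = 1/(1+exp(−(V−θ)/k)) and either constant or
bell-shaped τ(V).  The calcium-dependent K⁺ current is gated by
Ca/(Ca+K_d); per-compartment calcium follows
d[Ca]/dt = f·(−α·I_Ca − k_Ca·([Ca]−[Ca]_rest)), so the free-to-bound
fraction f sets the relaxation time scale 1/(f·k_Ca) — the soma's f_S is the
afterhyperpolarization-duration knob, while the fast-Na conductance G_Na,f
is the rheobase knob (both contracts are enforced by monotonicity tests).
E_Ca is either fixed (80 mV) or updated as (RT/2F)·ln([Ca]_out/[Ca]_in)
with RT/2F = 13.35 mV at 310 K.

Kinetic constants and maximal conductances are this package's own
calibration, in the functional forms of the classic two-compartment
motoneuron literature.  Because the inverted cable's effective specific
capacitances are large (C_m,S ≈ 28 µF/cm² for the validation cell — an
artifact of collapsing a tree into one compartment, not a membrane
property), channel densities were scaled up accordingly so that spike
upstroke and repolarization rates stay physiological.  The calibration was
fixed once against four qualitative contracts: a stable rest near the leak
reversal (−70 mV), repetitive firing above a rheobase of ≈10 nA with rates
in the 5–45 Hz range, monotone rheobase/AHP knobs, and dendritic-CaL
plateau behavior — a stable rest *without* self-activation, but latching
after ≈300 ms of suprathreshold firing, giving counterclockwise f–I
hysteresis on triangular ramps (half-activation −42 mV, τ 60 ms,
0.9 mS/cm²).  The validation channel sets are: soma {Na,f; Na,p; K,dr;
K(Ca); Ca,N} with calcium-dependent E_Ca, dendrite {Ca,L} with constant
E_Ca; an extended set adds I_H and the full somatic repertoire to the
dendrite for the noisy-synaptic-drive protocols.

Spike threshold for all detection (offline and online) is an upward 0 mV
crossing with a 2 ms refractory, sub-sample interpolated.

## Muscle unit

**Module 1 (calcium).**  Five pools: SR free calcium, calsequestrin-bound,
sarcoplasmic free, buffer-bound and troponin-bound.  Each spike triggers a
release flux r_max·(1−e^{−s/τ₁})·e^{−s/τ₂}·[Ca]_SR (τ₁ = 1.5 ms,
τ₂ = 3 ms); reuptake is linear, K·[Ca]_SP.  Binding follows mass action;
the troponin on-rate K5(X_m) = K5·exp(0.12·(X_m+8)) grows with length,
which (together with the force–length factor) reproduces the
disproportionate weakness of short muscle at sub-tetanic rates.  Total
calcium is conserved by construction and asserted to 1e-8 relative on every
trajectory.  Spike kernels are summed over a bounded 5·max(τ₁,τ₂) history
window, so the right-hand side is a pure function of (t, state, spike
list).

**Module 2 (activation).**  dÃ/dt = (Ã∞(CaT) − Ã)/τ(CaT) with a Hill
sigmoid Ã∞ (midpoint 0.04, cooperativity 4) and a Morris–Lecar-style time
constant (8–25 ms, fastest at the midpoint); A = Ã².

**Module 3 (mechanics).**  F_T = k_SE·[(X_m−X_m,init) − (X_CE−X_CE,init)],
floored at 0 (a tendon cannot push); the series-elastic rest offsets are
re-anchored to the trajectory's starting length so every run begins slack.
The contractile-element velocity inverts the force–velocity relation:
shortening branch (F+a)(b₀−V) = (F₀+a)b₀, lengthening branch
F = c − (c−F₀)d₀/(d₀+V), where F₀ = A·fl(X_m)·P0 is the instantaneous
isometric capacity.  The coefficients are solved in closed form from
velocity–tension anchors (isometric force 20 N, Hill curvature a/F₀ = 0.25,
V_max = 40 mm/s, eccentric asymptote 1.5·F₀, eccentric/concentric slope
ratio 2 at V = 0 — representative of slow cat muscle in the model's length
units); a₀ and c₀ scale with the motor-unit force fraction P_0.  The Hill
constant and the eccentric asymptote scale with the instantaneous capacity
(exactly a₀ and c₀ at full activation), so unloaded shortening speed is
V_max at any activation and a passive element yields under load.

*Numerical regularization.*  As activation → 0 the exact inverse relation's
slope diverges (an infinitely fast yield), which chatters adaptive stiff
solvers.  A small capacity floor, `capacity_reg`·(P0−F₀) with
capacity_reg = 0.01, bounds the slope; it vanishes at full activation, so
every anchor is reproduced exactly.  The residual passive force under
movement is below 2% of P0 (tested).  Velocities saturate at ±0.1 mm/ms.

**Force–length.**  fl(X_m) = exp(−((X_m+8)/6)²) on [−16, 0] mm: optimum
exactly −8 mm, positive everywhere, ≈0.17 at the range ends.  The factor is
a function of the muscle-tendon length command X_m (not X_CE): the embedded
whole-muscle relation was characterized against controlled muscle-tendon
length, and this choice keeps the isometric optimum at −8 mm independent of
tendon stretch.  K5 uses X_m for the same reason.

Module-1/2 constants are this package's calibration of the model family,
fixed once against: a single-spike twitch of ≈1.6 N (8% of P0) peaking
≈46 ms after the spike, unfused tetanus at 20 Hz (≈2.8 N), near-fused at
40 Hz (≈11 N), monotone frequency–force over 5–40 Hz, and F(−12 mm) <
F(−8 mm) at 20 Hz.

## Stimuli

All generators are pure functions of (parameters, seed).  Synaptic-noise is
a stationary first-order (Ornstein–Uhlenbeck) Gaussian process, correlation
time 10 ms, with standard deviation equal to a configurable fraction
(default 0.05) of the profile's maximum conductance — noise amplitude grows
with input intensity; the result is floored at 0.  Gaussian-random impulse
trains draw each event's instantaneous frequency from N(mean, sd) truncated
at 0.1 Hz (prevents unbounded intervals); the truncation makes 1/mean(ISI)
slightly below the nominal rate (Jensen), while the mean instantaneous
frequency matches it.  The locomotor-like length signal is uniform white
noise at 10 kHz filtered by a Blackman-window FIR low-pass (default 14001
taps, cutoff 3 Hz, unity DC gain), rescaled to the requested peak-to-peak
excursion (default 6 mm), centered at −8 mm and clipped to [−16, 0] mm; the
contract is spectral (≥99% of power below 5 Hz, matching soleus length
changes during unrestrained locomotion), not a particular filter order.

## Numerical integration

`solve_ivp` BDF for motoneuron and coupled motor-unit runs, LSODA for the
muscle alone (config-overridable), rtol 1e-6 / atol 1e-8, output grid
0.1 ms.  Three robustness policies:

* integration restarts at every input breakpoint (step/pulse edges, ramp
  corners, spike deliveries), so 300 ms pulse epochs are never stepped over;
* during coupled runs a terminal integration event fires at each somatic
  threshold crossing — the same rule as offline detection — and the spike is
  enqueued for delivery to the muscle at t + delay (the axon is a pure
  transport delay, so restart-at-delivery replaces delay-differential
  solving);
* the solver step is capped (default 10 ms) because a state resting in a
  zero-derivative region (e.g. a slack tendon) would otherwise let the
  stiff solvers step across subsequent input motion.

Halving both tolerances moves spike times by < 0.1 ms and peak force by
< 0.5% on all validation protocols (tested).  A runaway-spiking guard
aborts coupled runs exceeding a 2 kHz sustained event budget.

## Protocol presets and problem sizes

The preset battery mirrors the validation experiments: somatic triangular
ramp (peak 22 nA ≈ 2.2× rheobase, 10 s), dendritic excitatory conductance
ramp (G_p 0.12, 10 s ramp in a 20 s run), muscle under 20 Hz regular/random
drive during locomotor-like movement (2 s), motor-unit step protocols with
alternating 300 ms excitatory/inhibitory pulses (somatic current 8.5 nA
step ± 12 nA pulses; dendritic conductance 0.08 ± 0.06), and noisy push–pull
vs proportional synaptic organization (inhibition 0.13→0.03 against
excitation 0→0.12, or 0.03→0.13 co-varying).  Step and pulse amplitudes are
the package's calibration (chosen so the step lies in the bistable range
and a single pulse latches/tests the plateau); conductance values follow
the validation protocol settings.  Every preset accepts a `t_scale` that
shrinks all durations proportionally; the test suite runs scaled-down
versions (0.1–0.3) that retain every asserted qualitative feature, and the
acceptance script uses full-size problems for the quantities it reports
(320 ms passive measurements, 30 s length signal, 33-point F–L scan with
1.5 s settles).

## Known limitations

* The motoneuron and muscle constants are calibrated to qualitative
  contracts, not fitted to a specific cell's recordings; quantitative
  waveforms (exact firing rates, twitch ratios) should be treated as
  representative, not predictive.
* Single muscle-unit type (slow): no sag, potentiation or fatigue; no
  parallel elastic element, so passive force at long lengths is near zero.
* The synthetic protocols exercise ideal inputs; real intracellular
  recordings contain electrode artifacts and drift that the virtual
  measurements do not emulate, so passing tests demonstrate internal
  consistency of the model, not agreement with any particular experiment.
* Two compartments cannot represent location-dependent dendritic PIC
  recruitment; the attenuation factors stand in for channel position.
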