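"""Delay-only axon: spike detection and perfect delayed transmission.

Transduction of action potentials from motoneuron to muscle unit is assumed
perfect; the axon contributes a single conduction-delay parameter.  The same
threshold-crossing rule used here offline is used by the engine for online
detection during coupled integration.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .stimuli import Signal, SpikeTrain

__all__ = ["SpikeTrain", "detect_spikes", "transmit",
           "DEFAULT_DELAY_MS", "DEFAULT_THRESHOLD_MV", "DEFAULT_REFRACTORY_MS"]

#: conduction delay placeholder (ms); config key ``axon.delay_ms``
DEFAULT_DELAY_MS = 2.0
DEFAULT_THRESHOLD_MV = 0.0
DEFAULT_REFRACTORY_MS = 2.0


def detect_spikes(trace: Signal, threshold: float = DEFAULT_THRESHOLD_MV,
                  refractory: float = DEFAULT_REFRACTORY_MS) -> SpikeTrain:
    """Upward threshold crossings of a uniformly sampled voltage trace.

    Crossing times are refined by linear interpolation between the bracketing
    samples; crossings closer than ``refractory`` ms to the previous accepted
    event are discarded (suppresses double counting on multi-peaked
    waveforms).
    """
    v = trace.values
    if v.size < 2:
        return SpikeTrain(np.empty(0), source="motoneuron")
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    t = trace.t
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * trace.dt
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(np.array(times), source="motoneuron")


def transmit(train: SpikeTrain, delay: float) -> SpikeTrain:
    """Shift every event by the conduction delay; count and ISIs preserved."""
    if delay < 0:
        raise InvalidParameterError("conduction delay must be non-negative")
    return SpikeTrain(train.times + delay, source=train.source)
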