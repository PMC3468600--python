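"""Periodic waveform shapes shared by the simulator and the model-library matcher.

Every shape is a function of the cycle fraction ``u = ((t - phase) / period) mod 1``
with range [-1, 1] and its peak at ``u = 0``, so that a planted series
``baseline + (half_amplitude) * w(u)`` peaks at ``t = phase`` and the matcher's
grid argmax recovers the planted phase directly.
"""

from __future__ import annotations

import numpy as np

#: Half-width of the box waveform's high state, as a fraction of the period
#: (6 h of a 24-h cycle).
BOX_HALF_WIDTH = 0.125

#: Gaussian sigma of the spike waveform, as a fraction of the period
#: (1.5 h of a 24-h cycle).
SPIKE_SIGMA = 0.0625


def _cycle_fraction(t, phase, period):
    return np.mod((np.asarray(t, dtype=float) - phase) / period, 1.0)


def _circular_frac_distance(u):
    """Distance of cycle fraction u from the peak at 0, in [0, 0.5]."""
    u = np.mod(u, 1.0)
    return np.minimum(u, 1.0 - u)


def cosine(t, phase, period):
    return np.cos(2.0 * np.pi * _cycle_fraction(t, phase, period))


def spike(t, phase, period):
    d = _circular_frac_distance(_cycle_fraction(t, phase, period))
    return 2.0 * np.exp(-0.5 * (d / SPIKE_SIGMA) ** 2) - 1.0


def box(t, phase, period):
    d = _circular_frac_distance(_cycle_fraction(t, phase, period))
    return np.where(d < BOX_HALF_WIDTH, 1.0, -1.0)


def sawtooth(t, phase, period):
    """Peak at the phase, then a linear decline to the trough over one cycle."""
    u = _cycle_fraction(t, phase, period)
    return 1.0 - 2.0 * u


WAVEFORMS = {
    "cosine": cosine,
    "spike": spike,
    "box": box,
    "sawtooth": sawtooth,
}

DEFAULT_LIBRARY = ("cosine", "spike", "box", "sawtooth")


def evaluate(name: str, t, phase: float, period: float) -> np.ndarray:
    try:
        fn = WAVEFORMS[name]
    except KeyError:
        raise ValueError(f"unknown waveform {name!r}; known: {sorted(WAVEFORMS)}")
    return fn(t, phase, period)
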