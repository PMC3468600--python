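"""Small shared numerics: circular phase arithmetic and p-value formatting."""

from __future__ import annotations

import math

import numpy as np

P_VALUE_FLOOR = 2.2e-16


def circular_phase_distance(a: float, b: float, cycle: float = 24.0) -> float:
    """Shortest distance between two phases on a cycle; always <= cycle/2."""
    d = abs(a - b) % cycle
    return min(d, cycle - d)


def circular_mean(phases, cycle: float = 24.0) -> float:
    """Circular mean of phases in hours, returned in [0, cycle)."""
    phases = np.asarray(list(phases), dtype=float)
    if phases.size == 0:
        raise ValueError("cannot take the circular mean of no phases")
    ang = 2.0 * np.pi * phases / cycle
    mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return (mean * cycle / (2.0 * np.pi)) % cycle


def format_pvalue(p: float) -> str:
    """Report tiny p-values as the conventional '<2.2e-16' floor."""
    if p < P_VALUE_FLOOR:
        return "<2.2e-16"
    return format(p, ".3g")
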