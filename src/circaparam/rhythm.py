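"""Rhythm detection in temporal expression matrices.

Two detectors, combined the way the analysis pipeline uses them:

* a JTK-style nonparametric scan (:func:`jtk_scan`): each row is compared by
  the Kendall S statistic (concordant minus discordant pairs) against reference
  cosines over a (period x phase) grid, with an *exact* permutation null for S.
  Reference cosines sampled on an even time grid carry heavy ties (e.g. the two
  cycles of a 48-point / 24-h reference repeat the same 24 values), so the null
  is computed for the reference's tie pattern via the q-multinomial generating
  function -- the product of Gaussian binomial coefficients, evaluated by
  polynomial convolution in exact integer arithmetic.

* a model-library matcher (:func:`model_match_scan`): Pearson correlation of a
  row against discretized template waveforms (cosine, spike, box, sawtooth)
  over a (model x period x phase) grid, aimed at non-cosine rhythmic rows the
  rank scan misses.

Per-row p-values are Bonferroni-corrected over the number of distinct grid
alternatives; q-values are Benjamini-Hochberg across rows; the combiner keeps
the rank-scan call wherever it passes and falls back to the matcher otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import waveforms

__all__ = [
    "TimeCourseMatrix",
    "RhythmCall",
    "NullDistribution",
    "exact_kendall_null",
    "kendall_null_for_groups",
    "jtk_scan",
    "model_match_scan",
    "benjamini_hochberg",
    "combine_rhythm_calls",
]

DEFAULT_PERIODS = tuple(range(20, 29))  # hours; +-4 h around 24

_EXACT_NULL_MAX_N = 60


# ---------------------------------------------------------------------------
# containers


@dataclass
class TimeCourseMatrix:
    """Rows of log10 expression over an evenly spaced time grid."""

    row_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 4:
            raise ValueError("need at least 4 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0]):
            raise ValueError("times must be evenly spaced")
        if self.values.shape != (len(self.row_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {self.times.size} timepoints"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.times.size)

    def subset(self, row_ids: Sequence[str]) -> "TimeCourseMatrix":
        index = {r: i for i, r in enumerate(self.row_ids)}
        rows = [index[r] for r in row_ids]
        return TimeCourseMatrix(list(row_ids), self.times, self.values[rows])


@dataclass
class RhythmCall:
    row_id: str
    period: float
    phase: float
    statistic: float
    p_value: float
    q_value: float = math.nan
    detector: str = "jtk"
    waveform: str | None = None


@dataclass
class NullDistribution:
    """Exact null of Kendall S for a reference with tied groups.

    ``group_sizes`` are the sizes of the reference's tied-value groups (the
    untied case is all ones).  ``support`` holds the attainable S values in
    ascending order and ``probabilities`` their null probabilities.
    """

    group_sizes: tuple[int, ...]
    support: np.ndarray
    probabilities: np.ndarray

    @property
    def n(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def max_s(self) -> int:
        return int(self.support[-1])

    def two_sided_p(self, s: float) -> float:
        return float(self.two_sided_tail(np.array([s]))[0])

    def two_sided_tail(self, s: np.ndarray) -> np.ndarray:
        """P(|S| >= |s|) under the null (distribution is symmetric)."""
        a = np.abs(np.asarray(s, dtype=float))
        # tail sums from the top, indexed via searchsorted on the support
        rev_cum = np.concatenate([np.cumsum(self.probabilities[::-1])[::-1], [0.0]])
        idx = np.searchsorted(self.support, a - 1e-9, side="left")
        upper = rev_cum[idx]
        p = np.where(a <= 1e-9, 1.0, np.minimum(1.0, 2.0 * upper))
        return p


# ---------------------------------------------------------------------------
# exact null via Gaussian-binomial convolution


def _mul_one_minus_qe(poly: list[int], e: int) -> list[int]:
    out = poly + [0] * e
    for j, v in enumerate(poly):
        out[j + e] -= v
    return out


def _div_one_minus_qe(poly: list[int], e: int) -> list[int]:
    out = list(poly)
    for j in range(e, len(out)):
        out[j] += out[j - e]
    while len(out) > 1 and out[-1] == 0:
        out.pop()
    return out


@lru_cache(maxsize=4096)
def _q_binomial(m: int, r: int) -> tuple[int, ...]:
    """Integer coefficients of the Gaussian binomial [m choose r]_q.

    Coefficient j counts the r-subsets of {1..m} whose rank-sum excess
    ("inversions" contributed when merging a block of r into m-r items) is j.
    Built as prod_{i=1..r} (1-q^{m-r+i})/(1-q^i); every prefix of the product
    is itself a Gaussian binomial, so the intermediate stays integral.
    """
    if not 0 <= r <= m:
        raise ValueError("need 0 <= r <= m")
    poly = [1]
    for i in range(1, r + 1):
        poly = _mul_one_minus_qe(poly, m - r + i)
        poly = _div_one_minus_qe(poly, i)
    return tuple(poly)


def _convolve_int(a: Sequence[int], b: Sequence[int]) -> list[int]:
    out = [0] * (len(a) + len(b) - 1)
    for i, x in enumerate(a):
        if x:
            for j, y in enumerate(b):
                if y:
                    out[i + j] += x * y
    return out


@lru_cache(maxsize=512)
def kendall_null_for_groups(group_sizes: tuple[int, ...]) -> NullDistribution:
    """Exact null of Kendall S against a reference with the given tie pattern.

    Under the null the data ranks are an exchangeable permutation; only pairs
    in distinct reference groups contribute, so S = 2*C - M where C is the
    number of concordant untied pairs and M = sum_{i<j} n_i n_j.  The count
    generating function of C is the q-multinomial coefficient
    prod_k [N_k choose n_k]_q with N_k the cumulative group size.
    """
    sizes = tuple(int(s) for s in group_sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("group sizes must be positive")
    n = sum(sizes)
    if n > _EXACT_NULL_MAX_N:
        raise ValueError(
            f"exact null supported up to n={_EXACT_NULL_MAX_N}; got {n} "
            "(use a normal approximation beyond that)"
        )
    poly = [1]
    cum = 0
    for s in sizes:
        cum += s
        poly = _convolve_int(poly, _q_binomial(cum, s))
    total = float(sum(poly))
    m = (n * n - sum(s * s for s in sizes)) // 2
    assert len(poly) == m + 1
    support = np.arange(-m, m + 1, 2, dtype=int)
    probabilities = np.array([c / total for c in poly])
    return NullDistribution(sizes, support, probabilities)


def exact_kendall_null(n: int) -> NullDistribution:
    """Exact distribution of Kendall S over all n! orderings (untied case)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return kendall_null_for_groups((1,) * int(n))


# ---------------------------------------------------------------------------
# JTK-style scan


def _pair_signs(x: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return np.sign(x[..., iu[0]] - x[..., iu[1]])


def _reference_grid(
    times: np.ndarray, periods: Sequence[float], phase_step: float
) -> tuple[list[dict], int]:
    """Build cosine references and count distinct two-sided grid alternatives.

    A reference at phase ``phi + period/2`` is the sign flip of the one at
    ``phi``; under the symmetric two-sided tail the two are the same test, so
    when the antiphase mate lies on the phase grid each pair counts once.
    """
    refs = []
    n_alternatives = 0
    for period in periods:
        phases = np.arange(0.0, period - 1e-9, phase_step)
        half_on_grid = abs((period / 2.0) / phase_step - round((period / 2.0) / phase_step)) < 1e-9
        n_alternatives += (len(phases) + 1) // 2 if half_on_grid else len(phases)
        for phi in phases:
            ref = np.cos(2.0 * np.pi * (times - phi) / period)
            refs.append({"period": float(period), "phase": float(phi), "values": ref})
    return refs, n_alternatives


def jtk_scan(
    matrix: TimeCourseMatrix,
    periods: Sequence[float] = DEFAULT_PERIODS,
    phase_step: float | None = None,
) -> list[RhythmCall]:
    """Kendall-S scan of every row against reference cosines on a grid.

    Per row: the tie-adjusted S against each reference, the exact two-sided
    tail probability under the reference's tied null, the minimum over the
    grid Bonferroni-multiplied by the number of distinct alternatives (capped
    at 1), and the best-scoring (period, phase, S).  Constant rows score S=0,
    p=1.  q-values are Benjamini-Hochberg across rows.
    """
    if phase_step is None:
        phase_step = matrix.sampling_interval
    times = matrix.times
    n_t = times.size
    refs, n_alternatives = _reference_grid(times, periods, phase_step)
    iu = np.triu_indices(n_t, k=1)

    ref_signs = np.empty((len(refs), iu[0].size), dtype=np.float64)
    nulls = []
    for i, ref in enumerate(refs):
        rounded = np.round(ref["values"], 9)
        ref_signs[i] = _pair_signs(rounded, iu)
        _, counts = np.unique(rounded, return_counts=True)
        key = tuple(sorted(int(c) for c in counts))
        nulls.append(kendall_null_for_groups(key))

    calls: list[RhythmCall] = []
    chunk = max(1, 2_000_000 // max(1, iu[0].size))
    n_rows = len(matrix.row_ids)
    best_period = np.empty(n_rows)
    best_phase = np.empty(n_rows)
    best_s = np.empty(n_rows)
    p_out = np.empty(n_rows)
    for lo in range(0, n_rows, chunk):
        hi = min(n_rows, lo + chunk)
        d = _pair_signs(matrix.values[lo:hi], iu)
        s_grid = d @ ref_signs.T  # (rows, refs)
        p_grid = np.empty_like(s_grid)
        for j, null in enumerate(nulls):
            p_grid[:, j] = null.two_sided_tail(s_grid[:, j])
        p_min = p_grid.min(axis=1, keepdims=True)
        # among minimal-p references prefer positive S (the antiphase mate of a
        # negative-S best always ties in p when it is on the grid)
        cand = np.where(p_grid <= p_min + 1e-300, s_grid, -np.inf)
        best = cand.argmax(axis=1)
        for r, j in enumerate(best):
            period = refs[j]["period"]
            phase = refs[j]["phase"]
            s = s_grid[r, j]
            if s < 0:
                phase = (phase + period / 2.0) % period
            best_period[lo + r] = period
            best_phase[lo + r] = phase
            best_s[lo + r] = s
        p_out[lo:hi] = np.minimum(1.0, p_min[:, 0] * n_alternatives)

    q = benjamini_hochberg(p_out)
    for i, row_id in enumerate(matrix.row_ids):
        calls.append(
            RhythmCall(
                row_id=row_id,
                period=float(best_period[i]),
                phase=float(best_phase[i]),
                statistic=float(best_s[i]),
                p_value=float(p_out[i]),
                q_value=float(q[i]),
                detector="jtk",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# model-library matcher


def model_match_scan(
    matrix: TimeCourseMatrix,
    library: Sequence[str] = waveforms.DEFAULT_LIBRARY,
    periods: Sequence[float] = DEFAULT_PERIODS,
    phase_step: float | None = None,
) -> list[RhythmCall]:
    """Best Pearson correlation of each row against discretized templates.

    p is the two-sided t-transform of the best r with T-2 degrees of freedom,
    Bonferroni-corrected over the grid of (model, period, phase) templates.
    Zero-variance templates are skipped; an all-skipped or zero-variance row
    reports p = 1.
    """
    if not library:
        raise ValueError("waveform library must be non-empty")
    if phase_step is None:
        phase_step = matrix.sampling_interval
    times = matrix.times
    n_t = times.size

    templates = []
    meta = []
    for name in library:
        for period in periods:
            for phi in np.arange(0.0, period - 1e-9, phase_step):
                y = waveforms.evaluate(name, times, float(phi), float(period))
                sd = y.std()
                if sd < 1e-12:
                    continue
                templates.append((y - y.mean()) / sd)
                meta.append((name, float(period), float(phi)))
    if not templates:
        raise ValueError("all templates degenerate on this sampling grid")
    tmat = np.asarray(templates)
    n_grid = len(templates)

    x = matrix.values
    xm = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    ok = sd > 1e-12
    xz = np.zeros_like(xm)
    xz[ok] = xm[ok] / sd[ok, None]
    r = (xz @ tmat.T) / n_t
    best = r.argmax(axis=1)
    best_r = np.clip(r[np.arange(len(best)), best], -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = best_r * np.sqrt((n_t - 2) / np.maximum(1e-300, 1.0 - best_r**2))
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t_stat), df=n_t - 2) * n_grid)
    p[~ok] = 1.0
    q = benjamini_hochberg(p)

    calls = []
    for i, row_id in enumerate(matrix.row_ids):
        name, period, phi = meta[best[i]]
        calls.append(
            RhythmCall(
                row_id=row_id,
                period=period,
                phase=phi,
                statistic=float(best_r[i]) if ok[i] else 0.0,
                p_value=float(p[i]),
                q_value=float(q[i]),
                detector="model_match",
                waveform=name if ok[i] else None,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# FDR and combination


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def combine_rhythm_calls(
    jtk: Sequence[RhythmCall],
    mm: Sequence[RhythmCall],
    q_threshold: float,
) -> list[RhythmCall]:
    """Merge the two detectors' calls over a shared row universe.

    Rows passing the rank scan (q < threshold) keep their rank-scan call; of
    the remaining rows, those passing the matcher are added with its call.
    """

    def _index(calls: Sequence[RhythmCall], name: str) -> dict[str, RhythmCall]:
        out: dict[str, RhythmCall] = {}
        for c in calls:
            if c.row_id in out:
                raise ValueError(f"duplicate row_id {c.row_id!r} in {name} calls")
            out[c.row_id] = c
        return out

    jtk_by_id = _index(jtk, "jtk")
    mm_by_id = _index(mm, "model_match")
    combined = []
    for row_id, call in jtk_by_id.items():
        if call.q_value < q_threshold:
            combined.append(call)
        else:
            alt = mm_by_id.get(row_id)
            if alt is not None and alt.q_value < q_threshold:
                combined.append(alt)
    for row_id, call in mm_by_id.items():
        if row_id not in jtk_by_id and call.q_value < q_threshold:
            combined.append(call)
    return combined
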