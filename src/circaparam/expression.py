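"""Expression-level features and group comparisons.

Peak-to-trough amplitude on the linear intensity scale, ranked expression
bins (300 genes per bin, remainder merged into the top bin), per-gene
temporal / cross-tissue mean and standard deviation, tissue expression
breadth with the fixed 11-bin histogram, mRNA half-life filtering, and
one-sided Wilcoxon rank-sum comparisons with the conventional '<2.2e-16'
reporting floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .utils import format_pvalue

__all__ = [
    "TissueMatrix",
    "HalfLifeRecord",
    "ExpressionBin",
    "amplitude",
    "expression_bins",
    "bin_group_percentages",
    "temporal_stats",
    "expression_breadth",
    "breadth_bins",
    "breadth_histogram",
    "filter_halflife",
    "ranksum_onesided",
    "format_pvalue",
]


@dataclass
class TissueMatrix:
    """Genes x tissues log10 expression."""

    gene_ids: list[str]
    tissue_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValueError("values shape does not match gene/tissue ids")

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)


@dataclass
class HalfLifeRecord:
    gene_id: str
    halflife_es: float
    halflife_diff: float
    diff_p: float | None

    def __post_init__(self) -> None:
        if self.halflife_es <= 0 or self.halflife_diff <= 0:
            raise ValueError(f"{self.gene_id}: half-lives must be positive")


@dataclass
class ExpressionBin:
    bin_index: int
    gene_ids: list[str]
    mean_expression: float


def amplitude(series: Sequence[float], scale: str = "log10") -> float:
    """Peak-to-trough ratio: 95th / 5th percentile on the linear scale.

    Stored values are log10 intensities by default and are antilogged before
    taking percentiles; pass ``scale='linear'`` for raw intensities.
    Percentiles use the interpolated order statistic at position 1+(n-1)p.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if scale == "log10":
        x = 10.0**x
    elif scale != "linear":
        raise ValueError("scale must be 'log10' or 'linear'")
    hi = np.percentile(x, 95)
    lo = np.percentile(x, 5)
    if lo <= 0:
        raise ValueError("5th percentile must be positive for a ratio amplitude")
    return float(hi / lo)


def expression_bins(
    mean_expression: Mapping[str, float], bin_size: int = 300
) -> list[ExpressionBin]:
    """Rank genes by mean expression and fill fixed-size bins bottom-up.

    The remainder (fewer than ``bin_size`` genes) merges into the highest
    bin, so the top bin holds between ``bin_size`` and ``2*bin_size - 1``
    genes.  Ties at bin boundaries break by gene id for reproducibility.
    """
    items = sorted(mean_expression.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if n < bin_size:
        warnings.warn(f"only {n} genes: returning a single bin")
        sizes = [n]
    else:
        n_bins = n // bin_size
        sizes = [bin_size] * (n_bins - 1) + [bin_size + n % bin_size]
    bins = []
    pos = 0
    for i, size in enumerate(sizes):
        chunk = items[pos : pos + size]
        pos += size
        bins.append(
            ExpressionBin(
                bin_index=i,
                gene_ids=[g for g, _ in chunk],
                mean_expression=float(np.mean([v for _, v in chunk])),
            )
        )
    return bins


def bin_group_percentages(
    bins: Sequence[ExpressionBin], groups: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Share of each bin's genes belonging to each group, in percent."""
    rows = []
    for b in bins:
        members = set(b.gene_ids)
        rows.append(
            {name: 100.0 * len(members & set(g)) / len(members) for name, g in groups.items()}
        )
    out = pd.DataFrame(rows)
    out.insert(0, "mean_expression", [b.mean_expression for b in bins])
    return out


def temporal_stats(values: np.ndarray, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Per-gene mean and sample standard deviation across columns."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 columns for a standard deviation")
    return pd.DataFrame(
        {"mean": values.mean(axis=1), "std": values.std(axis=1, ddof=1)},
        index=list(gene_ids),
    )


def breadth_bins(n_tissues: int = 46) -> list[tuple[int, int]]:
    """The fixed breadth histogram bins.

    For 46 tissues: {0-1}, nine 5-wide bins 2-41, {42-45}, {46}.  Other
    tissue counts use the analogous scheme: a {0,1} bin, 5-wide bins, a
    truncated penultimate bin up to n-1, and {n} alone.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues for the breadth bins")
    bins = [(0, 1)]
    lo = 2
    while lo + 4 <= n_tissues - 1:
        bins.append((lo, lo + 4))
        lo += 5
    if lo <= n_tissues - 1:
        bins.append((lo, n_tissues - 1))
    bins.append((n_tissues, n_tissues))
    return bins


def expression_breadth(matrix: TissueMatrix, cutoff: float) -> pd.Series:
    """Number of tissues where each gene exceeds the expression cutoff."""
    counts = (matrix.values > cutoff).sum(axis=1)
    return pd.Series(counts, index=matrix.gene_ids, name="breadth")


def breadth_histogram(
    breadths: Mapping[str, int] | pd.Series,
    n_tissues: int = 46,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Counts (and per-group percentages) of genes per breadth bin.

    Group percentages are shares of the group's genes falling in each bin and
    sum to 100 over bins.
    """
    series = pd.Series(dict(breadths)) if not isinstance(breadths, pd.Series) else breadths
    bins = breadth_bins(n_tissues)
    labels = [f"{lo}-{hi}" if lo != hi else str(lo) for lo, hi in bins]
    out = pd.DataFrame(index=labels)
    assign = np.full(len(series), -1)
    for i, (lo, hi) in enumerate(bins):
        assign[((series.values >= lo) & (series.values <= hi))] = i
    if (assign < 0).any():
        raise ValueError("breadth outside [0, n_tissues]")
    out["count"] = [int((assign == i).sum()) for i in range(len(bins))]
    if groups:
        for name, members in groups.items():
            mask = series.index.isin(set(members))
            total = mask.sum()
            out[f"pct_{name}"] = [
                100.0 * ((assign == i) & mask).sum() / total if total else 0.0
                for i in range(len(bins))
            ]
    return out


def filter_halflife(
    records: Sequence[HalfLifeRecord], p_threshold: float = 0.1
) -> list[HalfLifeRecord]:
    """Drop records whose ES vs differentiated difference is significant.

    Records with diff_p <= threshold (boundary inclusive) are excluded;
    records lacking a p-value are retained with a warning.
    """
    retained = []
    n_missing = 0
    for r in records:
        if r.diff_p is None or np.isnan(r.diff_p):
            n_missing += 1
            retained.append(r)
        elif r.diff_p > p_threshold:
            retained.append(r)
    if n_missing:
        warnings.warn(f"{n_missing} half-life records lack a difference p-value; retained")
    return retained


def ranksum_onesided(
    x: Sequence[float], y: Sequence[float], alternative: str = "less"
) -> float:
    """One-sided two-sample Wilcoxon rank-sum p-value.

    Exact by enumeration when min(n, m) <= 8 with no ties, otherwise the
    tie-corrected normal approximation with continuity correction.  Identical
    constant samples give p = 1 by convention.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; p = 1 by convention")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)
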