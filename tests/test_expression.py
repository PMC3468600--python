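"""Amplitude, expression bins, temporal stats, breadth, half-life, rank-sum."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaparam.expression import (
    HalfLifeRecord,
    TissueMatrix,
    amplitude,
    breadth_bins,
    breadth_histogram,
    expression_bins,
    expression_breadth,
    filter_halflife,
    format_pvalue,
    ranksum_onesided,
    temporal_stats,
)


def percentile_oracle(values, p):
    """Interpolated order statistic at 1-based position 1 + (n-1)p."""
    x = sorted(values)
    pos = 1 + (len(x) - 1) * p
    lo = int(np.floor(pos)) - 1
    frac = pos - np.floor(pos)
    if lo + 1 >= len(x):
        return x[-1]
    return x[lo] + frac * (x[lo + 1] - x[lo])


class TestAmplitude:
    def test_constant_series_is_one(self):
        assert amplitude([2.0] * 10) == pytest.approx(1.0)

    def test_linear_values_oracle(self):
        values = list(range(1, 101))
        expected = percentile_oracle(values, 0.95) / percentile_oracle(values, 0.05)
        assert amplitude(values, scale="linear") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(95.05 / 5.95)

    def test_log10_series_antilogged(self):
        series = np.log10([1, 10, 100, 1000])
        assert amplitude(series) == pytest.approx(
            percentile_oracle([1, 10, 100, 1000], 0.95)
            / percentile_oracle([1, 10, 100, 1000], 0.05),
            rel=1e-12,
        )

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 4.0), min_size=2, max_size=60))
    def test_at_least_one_on_positive_values(self, series):
        assert amplitude(series) >= 1.0 - 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            amplitude([1.0])


class TestExpressionBins:
    def test_even_split(self):
        means = {f"g{i:04d}": i / 1000 for i in range(600)}
        bins = expression_bins(means)
        assert [len(b.gene_ids) for b in bins] == [300, 300]

    def test_remainder_merges_into_top_bin(self):
        means = {f"g{i:05d}": float(i) for i in range(8_429)}
        bins = expression_bins(means)
        sizes = [len(b.gene_ids) for b in bins]
        assert len(bins) == 28
        assert sizes == [300] * 27 + [329]
        assert sum(sizes) == 8_429

    def test_bottom_bin_holds_lowest_values(self):
        means = {f"g{i}": float(i) for i in range(600)}
        bins = expression_bins(means)
        assert bins[0].mean_expression < bins[1].mean_expression

    def test_input_order_invariance(self):
        rng = np.random.default_rng(0)
        means = {f"g{i}": float(v) for i, v in enumerate(rng.normal(2, 0.5, 700))}
        shuffled = dict(sorted(means.items(), key=lambda kv: kv[1]))
        a = expression_bins(means)
        b = expression_bins(shuffled)
        assert [set(x.gene_ids) for x in a] == [set(x.gene_ids) for x in b]

    def test_small_input_single_bin_with_warning(self):
        with pytest.warns(UserWarning, match="single bin"):
            bins = expression_bins({"a": 1.0, "b": 2.0})
        assert len(bins) == 1


class TestTemporalStats:
    def test_hand_arithmetic(self):
        df = temporal_stats(np.array([[1.0, 2.0, 3.0]]), ["g"])
        assert df.loc["g", "mean"] == 2.0
        assert df.loc["g", "std"] == 1.0

    def test_constant_row_zero_std(self):
        df = temporal_stats(np.full((1, 5), 3.3), ["g"])
        assert df.loc["g", "std"] == 0.0

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            temporal_stats(np.ones((2, 1)), ["a", "b"])


class TestBreadth:
    def test_bin_scheme_for_46_tissues(self):
        bins = breadth_bins(46)
        assert bins[0] == (0, 1)
        assert bins[-2:] == [(42, 45), (46, 46)]
        assert len(bins) == 11
        covered = sorted(b for lo, hi in bins for b in range(lo, hi + 1))
        assert covered == list(range(47))

    def test_extreme_breadths(self):
        m = TissueMatrix(["all", "none"], [f"t{i}" for i in range(46)],
                         np.vstack([np.full(46, 2.0), np.full(46, 1.0)]))
        b = expression_breadth(m, 1.45)
        assert b["all"] == 46 and b["none"] == 0
        hist = breadth_histogram(b, 46)
        assert hist.loc["46", "count"] == 1
        assert hist.loc["0-1", "count"] == 1

    def test_breadth_43_falls_in_42_45(self):
        hist = breadth_histogram({"g": 43}, 46)
        assert hist.loc["42-45", "count"] == 1

    def test_group_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        breadths = {f"g{i}": int(rng.integers(0, 47)) for i in range(200)}
        hist = breadth_histogram(breadths, 46, {"G": list(breadths)})
        assert hist["pct_G"].sum() == pytest.approx(100.0, abs=1e-9)


class TestHalfLife:
    def rec(self, p):
        return HalfLifeRecord("g", 8.0, 8.1, p)

    def test_threshold_boundary_inclusive(self):
        assert filter_halflife([self.rec(0.05)]) == []
        assert filter_halflife([self.rec(0.1)]) == []
        assert len(filter_halflife([self.rec(0.2)])) == 1

    def test_missing_p_retained_with_warning(self):
        with pytest.warns(UserWarning, match="lack"):
            kept = filter_halflife([self.rec(None)])
        assert len(kept) == 1

    def test_nonpositive_halflife_rejected(self):
        with pytest.raises(ValueError):
            HalfLifeRecord("g", 0.0, 1.0, 0.5)


def ranksum_enumeration_oracle(x, y, alternative):
    """Exact one-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    total = 0
    hits = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        total += 1
        w = sum(combo)
        if (alternative == "less" and w <= w_obs) or (
            alternative == "greater" and w >= w_obs
        ):
            hits += 1
    return hits / total


class TestRankSum:
    def test_fully_separated_small_samples(self):
        assert ranksum_onesided([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_identical_samples_not_significant(self):
        assert ranksum_onesided([1, 2, 3], [1, 2, 3], "less") >= 0.5

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for n, m in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            for alt in ("less", "greater"):
                assert ranksum_onesided(x, y, alt) == pytest.approx(
                    ranksum_enumeration_oracle(list(x), list(y), alt), abs=1e-12
                )

    def test_all_identical_values_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            assert ranksum_onesided([1.0, 1.0], [1.0], "less") == 1.0

    def test_reporting_floor(self):
        assert format_pvalue(1e-20) == "<2.2e-16"
        assert format_pvalue(0.034) == "0.034"
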