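"""Rhythm detection: exact nulls, rank scan, model matcher, FDR, combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaparam.rhythm import (
    RhythmCall,
    TimeCourseMatrix,
    benjamini_hochberg,
    combine_rhythm_calls,
    exact_kendall_null,
    jtk_scan,
    kendall_null_for_groups,
    model_match_scan,
)
from conftest import enumerate_kendall_null


def cosine_row(t, phase, period=24.0, baseline=2.0, half_amp=0.3):
    return baseline + half_amp * np.cos(2 * np.pi * (t - phase) / period)


class TestExactNull:
    def test_n1_degenerate(self):
        null = exact_kendall_null(1)
        assert null.support.tolist() == [0]
        assert null.probabilities.tolist() == [1.0]
        assert null.two_sided_p(0) == 1.0

    def test_n2_two_orderings(self):
        null = exact_kendall_null(2)
        assert null.support.tolist() == [-1, 1]
        np.testing.assert_allclose(null.probabilities, [0.5, 0.5])

    def test_n3_enumerated_probabilities(self):
        null = exact_kendall_null(3)
        got = dict(zip(null.support.tolist(), null.probabilities))
        np.testing.assert_allclose(
            [got[-3], got[-1], got[1], got[3]], [1 / 6, 2 / 6, 2 / 6, 1 / 6]
        )

    @pytest.mark.parametrize("groups", [(2, 1), (2, 2), (3, 2), (2, 2, 1), (1, 1, 2, 2)])
    def test_tied_reference_matches_enumeration(self, groups):
        null = kendall_null_for_groups(groups)
        expected = enumerate_kendall_null(groups)
        got = dict(zip(null.support.tolist(), null.probabilities))
        for s, p in expected.items():
            assert got[s] == pytest.approx(p, abs=1e-12)
        assert sum(p for p in got.values()) == pytest.approx(1.0, abs=1e-12)

    def test_support_symmetric_probabilities_normalized(self):
        null = exact_kendall_null(12)
        assert null.support.sum() == 0
        np.testing.assert_allclose(null.probabilities, null.probabilities[::-1])
        assert null.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            exact_kendall_null(0)
        with pytest.raises(ValueError):
            exact_kendall_null(61)


class TestJtkScan:
    def test_recovers_noiseless_cosine(self):
        t = np.arange(48.0)
        m = TimeCourseMatrix(["a"], t, cosine_row(t, 8.0)[None, :])
        call = jtk_scan(m, periods=range(20, 29))[0]
        assert call.period == 24.0
        assert call.phase == 8.0
        assert call.p_value < 1e-20
        # S attains the maximum allowed by the reference's tie pattern
        assert call.statistic == 1060.0

    def test_constant_row_scores_null(self):
        t = np.arange(48.0)
        call = jtk_scan(TimeCourseMatrix(["c"], t, np.full((1, 48), 2.0)))[0]
        assert call.p_value == 1.0
        assert call.statistic == 0.0

    def test_sign_flip_reports_antiphase(self):
        t = np.arange(48.0)
        flipped = 2.0 - 0.3 * np.cos(2 * np.pi * (t - 8.0) / 24.0)
        call = jtk_scan(TimeCourseMatrix(["f"], t, flipped[None, :]))[0]
        assert call.period == 24.0
        assert call.phase == 20.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        t = np.arange(24.0)
        x = cosine_row(t, 3.0) + rng.normal(0, 0.1, 24)
        m = TimeCourseMatrix(["x", "y"], t, np.vstack([x, np.exp(2.0 * x)]))
        a, b = jtk_scan(m)
        assert (a.period, a.phase, a.statistic, a.p_value) == (
            b.period, b.phase, b.statistic, b.p_value,
        )

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="4 timepoints"):
            TimeCourseMatrix(["a"], [0, 1, 2], np.zeros((1, 3)))
        with pytest.raises(ValueError, match="missing"):
            TimeCourseMatrix(["a"], np.arange(4.0), np.array([[0.0, 1.0, np.nan, 2.0]]))


class TestModelMatch:
    def test_exact_template_self_match(self):
        from circaparam.waveforms import spike

        t = np.arange(48.0)
        row = 2.0 + 0.2 * spike(t, 6.0, 24.0)
        call = model_match_scan(TimeCourseMatrix(["s"], t, row[None, :]))[0]
        assert call.waveform == "spike"
        assert call.statistic == pytest.approx(1.0, abs=1e-9)
        assert call.period == 24.0 and call.phase == 6.0

    def test_white_noise_scores_low(self):
        rng = np.random.default_rng(17)
        t = np.arange(48.0)
        rows = rng.normal(2.0, 0.1, size=(200, 48))
        calls = model_match_scan(TimeCourseMatrix([f"n{i}" for i in range(200)], t, rows))
        assert np.median([c.statistic for c in calls]) < 0.5

    def test_cosine_phase_recovered_with_cosine_library(self):
        t = np.arange(48.0)
        row = cosine_row(t, 8.0)
        call = model_match_scan(
            TimeCourseMatrix(["c"], t, row[None, :]), library=("cosine",)
        )[0]
        assert call.phase == 8.0 and call.period == 24.0

    def test_zero_variance_row(self):
        t = np.arange(48.0)
        call = model_match_scan(TimeCourseMatrix(["z"], t, np.full((1, 48), 1.5)))[0]
        assert call.p_value == 1.0 and call.waveform is None


class TestBenjaminiHochberg:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_constant(self):
        assert benjamini_hochberg([0.2]).tolist() == [0.2]
        np.testing.assert_allclose(benjamini_hochberg([0.4, 0.4, 0.4]), [0.4] * 3)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p(self, ps):
        q = benjamini_hochberg(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCombine:
    @staticmethod
    def call(rid, q, detector):
        return RhythmCall(rid, 24.0, 0.0, 1.0, q, q_value=q, detector=detector)

    def test_row_passing_both_keeps_jtk(self):
        jtk = [self.call("a", 1e-5, "jtk")]
        mm = [self.call("a", 1e-6, "model_match")]
        (merged,) = combine_rhythm_calls(jtk, mm, 0.001)
        assert merged.detector == "jtk"

    def test_row_passing_neither_absent(self):
        jtk = [self.call("a", 0.5, "jtk")]
        mm = [self.call("a", 0.5, "model_match")]
        assert combine_rhythm_calls(jtk, mm, 0.001) == []

    def test_union_count(self):
        jtk = [self.call(f"j{i}", 1e-5, "jtk") for i in range(5)]
        jtk += [self.call(f"m{i}", 0.9, "jtk") for i in range(3)]
        mm = [self.call(f"j{i}", 0.9, "model_match") for i in range(5)]
        mm += [self.call(f"m{i}", 1e-5, "model_match") for i in range(3)]
        assert len(combine_rhythm_calls(jtk, mm, 0.001)) == 8

    def test_duplicate_rows_rejected(self):
        jtk = [self.call("a", 0.5, "jtk"), self.call("a", 0.5, "jtk")]
        with pytest.raises(ValueError, match="duplicate"):
            combine_rhythm_calls(jtk, [], 0.001)
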