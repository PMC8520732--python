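"""Ratio computation, histograms, and clearance fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggrephagy.ratiometry import (
    RatioRecord,
    classify_acidified,
    clearance_summary,
    mkeima_ratio,
    ratio_histogram,
)


class TestRatio:
    @pytest.mark.parametrize("i445,i561,expected", [
        (100.0, 100.0, 0.5),
        (80.0, 20.0, 0.8),
        (0.0, 50.0, 0.0),
    ])
    def test_values(self, i445, i561, expected):
        assert mkeima_ratio(i445, i561) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            mkeima_ratio(0.0, 0.0)

    @given(
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, i445, i561, c):
        assert mkeima_ratio(c * i445, c * i561) == pytest.approx(
            mkeima_ratio(i445, i561), rel=1e-9
        )


class TestClassification:
    def test_strict_threshold(self):
        assert classify_acidified(0.34) is True
        assert classify_acidified(0.35) is False
        assert classify_acidified(0.80) is False


class TestHistogram:
    def test_single_value_lands_in_its_bin(self):
        edges, freqs = ratio_histogram([0.5], bin_width=0.05)
        k = int(np.argmax(freqs))
        assert edges[k] == pytest.approx(0.50) and freqs[k] == 1.0

    def test_normalization(self):
        rng = np.random.default_rng(0)
        _, freqs = ratio_histogram(rng.uniform(0, 1, 1000))
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_fills_bins_evenly(self):
        rng = np.random.default_rng(1)
        n = 10**6
        _, freqs = ratio_histogram(rng.uniform(0, 1, n), bin_width=0.05)
        se = np.sqrt(0.05 * 0.95 / n)
        assert np.all(np.abs(freqs - 0.05) < 3 * se + 1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ratio_histogram([])


def _records(ratios, rep="r1"):
    return [
        RatioRecord(i, 0, r, r < 0.35, rep, "control") for i, r in enumerate(ratios)
    ]


class TestClearance:
    def test_single_replicate_count(self):
        summary = clearance_summary({"r1": _records([0.1, 0.2, 0.9, 0.8])})
        assert summary.fractions == (0.5,)

    def test_mean_is_unweighted_across_replicates(self):
        # replicate sizes differ: the mean must ignore particle counts
        reps = {
            "r1": _records([0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9]),  # 0.4
            "r2": _records([0.1, 0.9]),                                           # 0.5
            "r3": _records([0.1, 0.1, 0.1, 0.9, 0.9]),                            # 0.6
        }
        assert clearance_summary(reps).mean == pytest.approx(0.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        recs = {"r1": _records(rng.uniform(0, 1, 500))}
        fracs = [clearance_summary(recs, threshold=t).mean for t in (0.1, 0.35, 0.6, 0.9)]
        assert fracs == sorted(fracs)

    def test_histogram_variant_close_to_count(self):
        rng = np.random.default_rng(3)
        recs = {"r1": _records(rng.uniform(0, 1, 2000))}
        direct = clearance_summary(recs, method="count").mean
        binned = clearance_summary(recs, method="histogram").mean
        assert binned == pytest.approx(direct, abs=0.02)

    def test_empty_replicate_excluded_with_warning(self):
        reps = {"r1": _records([0.1, 0.9]), "r2": []}
        with pytest.warns(UserWarning):
            summary = clearance_summary(reps)
        assert summary.fractions == (0.5,)
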