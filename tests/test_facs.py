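"""FACS population simulation and gating."""

import numpy as np
import pytest

from aggrephagy.facs import Gate, gate_positive, roi_fraction
from aggrephagy.sim import simulate_facs_population


def test_fraction_zero_and_one_are_pure():
    lo = simulate_facs_population(500, 0.0, seed=1)
    hi = simulate_facs_population(500, 1.0, seed=1)
    assert not any(e.shifted for e in lo)
    assert all(e.shifted for e in hi)


def test_shifted_component_elevates_low_channel():
    events = simulate_facs_population(4000, 0.5, seed=2)
    r_shift = np.mean([e.i_low / e.i_neutral for e in events if e.shifted])
    r_base = np.mean([e.i_low / e.i_neutral for e in events if not e.shifted])
    assert r_shift > 10 * r_base


def test_binomial_mean_of_shifted_count():
    n, f, n_seeds = 20000, 0.2, 100
    counts = np.array([
        sum(e.shifted for e in simulate_facs_population(n, f, seed=s))
        for s in range(n_seeds)
    ], dtype=float)
    sem = counts.std(ddof=1) / np.sqrt(n_seeds)
    assert abs(counts.mean() - n * f) < 3 * sem + 1e-9


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        simulate_facs_population(0, 0.5)
    with pytest.raises(ValueError):
        simulate_facs_population(10, 1.5)


class TestGating:
    def test_zero_threshold_is_identity(self):
        events = simulate_facs_population(200, 0.2, seed=3)
        assert gate_positive(events, 0.0) == events

    def test_all_below_threshold_empty(self):
        events = simulate_facs_population(200, 0.2, seed=3)
        assert gate_positive(events, 1e12) == []

    def test_whole_plane_and_empty_gate(self):
        events = simulate_facs_population(300, 0.2, seed=4)
        everything = Gate("all", "polygon", {"vertices": [(-5, -5), (15, -5), (15, 15), (-5, 15)]})
        nothing = Gate("none", "polygon", {"vertices": [(-9, -9), (-8, -9), (-8, -8)]})
        assert roi_fraction(events, everything) == 100.0
        assert roi_fraction(events, nothing) == 0.0

    def test_partition_sums_to_100(self):
        events = simulate_facs_population(1000, 0.3, seed=5)
        split = 2.6
        lower = Gate("lo", "threshold", {"log_i_low": (None, split)})
        upper = Gate("hi", "threshold", {"log_i_low": (split, None)})
        on_boundary = sum(np.log10(e.i_low) == split for e in events)
        assert on_boundary == 0  # continuous draws: partition is exact
        assert roi_fraction(events, lower) + roi_fraction(events, upper) == pytest.approx(100.0)

    def test_monotone_transform_invariance(self):
        # squaring intensities doubles log coordinates; transforming the
        # gate vertices identically must leave the fraction unchanged
        from aggrephagy.sim.facs import FACSEvent

        events = simulate_facs_population(2000, 0.2, seed=6)
        gate = Gate("roi", "polygon", {"vertices": [(0, 2.6), (6, 2.6), (6, 8), (0, 8)]})
        frac1 = roi_fraction(events, gate)
        squared = [
            FACSEvent(e.cell_id, e.i_neutral**2, e.i_low**2, e.shifted) for e in events
        ]
        gate2 = Gate("roi2", "polygon", {
            "vertices": [(2 * x, 2 * y) for x, y in gate.params["vertices"]]
        })
        assert roi_fraction(squared, gate2) == pytest.approx(frac1)

    def test_boundary_point_counts_inside(self):
        from aggrephagy.sim.facs import FACSEvent

        gate = Gate("roi", "polygon", {"vertices": [(0, 0), (2, 0), (2, 2), (0, 2)]})
        on_edge = FACSEvent(0, 10.0, 1.0, False)  # log10 -> (1, 0): on the edge
        assert gate.contains(on_edge)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            Gate("bad", "polygon", {"vertices": [(0, 0), (1, 1)]})
        with pytest.raises(ValueError):
            Gate("bad", "weird", {})

    def test_empty_subset_rejected(self):
        gate = Gate("roi", "threshold", {"log_i_low": (0, None)})
        with pytest.raises(ValueError):
            roi_fraction([], gate)


def test_scripted_fraction_recovered_through_gate():
    events = simulate_facs_population(20000, 0.2, seed=7)
    gate = Gate("roi1", "polygon", {"vertices": [(0, 2.6), (6, 2.6), (6, 8), (0, 8)]})
    frac = roi_fraction(gate_positive(events, 10.0), gate)
    truth = 100.0 * np.mean([e.shifted for e in events])
    assert frac == pytest.approx(truth, abs=0.5)
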