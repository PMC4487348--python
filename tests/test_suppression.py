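import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakfill import WindowSchedule, suppress, suppress_sweep, window_schedule

from _oracles import naive_suppress


class TestWindowSchedule:
    def test_fig3_style_settings_end_at_one(self):
        """Starting at ±15 over 20 iterations the window shrinks to ±1."""
        s = window_schedule(15, 20)
        assert len(s) == 20
        assert s.halfwidths[-1] == 1
        assert s.halfwidths[0] <= 15

    def test_unit_halfwidth_stays_unit(self):
        assert window_schedule(1, 7).halfwidths == (1,) * 7

    def test_log_spaced_decades(self):
        assert window_schedule(100, 3).halfwidths == (100, 10, 1)

    def test_single_iteration_keeps_initial_width(self):
        assert window_schedule(9, 1).halfwidths == (9,)

    @given(hwi=st.integers(1, 200), it=st.integers(1, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_schedule_invariants(self, hwi, it):
        """Non-increasing, bounded by hwi, and ending at 1 when iterated."""
        hw = window_schedule(hwi, it).halfwidths
        assert len(hw) == it
        assert hw[0] <= hwi
        assert all(a >= b for a, b in zip(hw, hw[1:]))
        if it >= 2:
            assert hw[-1] == 1

    @pytest.mark.parametrize("hwi,it", [(0, 5), (5, 0), (-1, 3), (3, -1)])
    def test_nonpositive_inputs_rejected(self, hwi, it):
        with pytest.raises(ValueError):
            window_schedule(hwi, it)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            WindowSchedule((2, 3, 1))  # increasing step
        with pytest.raises(ValueError):
            WindowSchedule((3, 2))  # does not end at 1
        with pytest.raises(ValueError):
            WindowSchedule(())


class TestSuppressSweep:
    def test_isolated_spike_left_to_right(self):
        out = suppress_sweep([0, 0, 10, 0, 0], 1, "ltr")
        np.testing.assert_array_equal(out, [0, 0, 10 / 3, 0, 0])

    def test_isolated_spike_then_right_to_left(self):
        mid = suppress_sweep([0, 0, 10, 0, 0], 1, "ltr")
        out = suppress_sweep(mid, 1, "rtl")
        np.testing.assert_array_equal(out, [0, 0, 10 / 9, 0, 0])

    def test_constant_vector_unchanged(self):
        # exactly representable sums: the window mean reproduces c exactly
        v = np.full(20, 3.5)
        for direction in ("ltr", "rtl"):
            np.testing.assert_array_equal(suppress_sweep(v, 4, direction), v)
        # for general constants the mean can round one ulp low, never more
        w = np.full(20, 3.7)
        out = suppress_sweep(w, 4, "ltr")
        np.testing.assert_allclose(out, w, rtol=5e-16)

    def test_input_not_modified(self):
        v = np.array([0.0, 5.0, 0.0])
        suppress_sweep(v, 1, "ltr")
        np.testing.assert_array_equal(v, [0.0, 5.0, 0.0])

    @pytest.mark.parametrize(
        "v,hw,direction",
        [([], 1, "ltr"), ([1.0], 0, "ltr"), ([1.0], 1, "up")],
    )
    def test_invalid_arguments_rejected(self, v, hw, direction):
        with pytest.raises(ValueError):
            suppress_sweep(v, hw, direction)


class TestSuppress:
    def test_spike_double_sweep(self):
        out = suppress([0, 0, 10, 0, 0], WindowSchedule((1,)))
        np.testing.assert_array_equal(out, [0, 0, 10 / 9, 0, 0])

    def test_constant_unchanged_for_any_schedule(self):
        v = np.full(30, -2.5)
        out = suppress(v, window_schedule(8, 6))
        np.testing.assert_array_equal(out, v)

    @pytest.mark.parametrize("seed", range(20))
    def test_pointwise_non_increasing_through_every_sweep(self, seed):
        """No element ever rises, sweep after sweep."""
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 5, rng.integers(5, 200))
        current = v.copy()
        for hw in window_schedule(int(rng.integers(1, 15)), 8):
            for direction in ("ltr", "rtl"):
                nxt = suppress_sweep(current, hw, direction)
                assert np.all(nxt <= current)
                current = nxt

    def test_plateau_interior_pulled_down_monotonically(self):
        """A wide plateau sinks strictly below its height, and keeps
        sinking as iterations accumulate."""
        v = np.zeros(41)
        v[10:31] = 5.0  # plateau wider than 2*hwi+1
        interior = slice(12, 29)
        prev = v.copy()
        prev_level = 5.0
        for hw in window_schedule(4, 12):
            nxt = suppress_sweep(suppress_sweep(prev, hw, "ltr"), hw, "rtl")
            assert np.all(nxt <= prev)
            level = nxt[interior].max()
            assert level <= prev_level
            prev, prev_level = nxt, level
        assert prev[interior].max() < 5.0

    @pytest.mark.parametrize("seed", range(15))
    def test_bitwise_agreement_with_naive_loop(self, seed):
        """Production and naive loop oracle agree exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 500))
        v = rng.normal(0, 10, n)
        schedule = window_schedule(int(rng.integers(1, 21)), int(rng.integers(1, 11)))
        expected = naive_suppress(v, schedule.halfwidths)
        np.testing.assert_array_equal(suppress(v, schedule), expected)
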