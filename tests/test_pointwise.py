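import itertools

import numpy as np
import pytest

from hgmod.epoching import ROITimeCourse
from hgmod.pointwise import (duration_filter, fdr_adjust,
                             permutation_mean_test, slope_estimate)


def make_tc(values, times=None):
    values = np.atleast_2d(values)
    if times is None:
        times = np.arange(values.shape[1]) * 10.0
    return ROITimeCourse(
        roi="posterior_MFG", hemisphere="left", sentence_type="both",
        anchor="p1_onset", times=times, mean=values.mean(axis=0),
        se=values.std(axis=0) / np.sqrt(len(values)),
        n_electrodes=len(values), n_patients=1, electrode_values=values)


class TestPermutationTest:
    def test_all_zero_gives_p_one(self):
        p = permutation_mean_test(np.zeros((5, 4)), 1000, rng_seed=0)
        assert np.all(p == 1.0)

    def test_strong_effect_smallest_attainable_p(self):
        """30 electrodes all at +1: p is the smallest attainable value
        1/1001 unless a permutation reproduces the all-plus pattern."""
        x = np.ones((30, 1))
        p = permutation_mean_test(x, 1000, rng_seed=0)
        assert p[0] <= 2 / 1001 + 1e-12

    def test_matches_exact_enumeration(self):
        """For 8 electrodes the permutation p converges to the exact
        sign-flip enumeration over all 2^8 patterns."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 3)) + 0.6
        obs = np.abs(x.mean(axis=0))
        exact = np.zeros(3)
        for signs in itertools.product([-1, 1], repeat=8):
            null = np.abs(np.array(signs) @ x) / 8
            exact += null >= obs - 1e-12
        exact /= 2 ** 8
        p = permutation_mean_test(x, 20000, rng_seed=0)
        np.testing.assert_allclose(p, exact, atol=0.01)

    def test_single_electrode_rejected(self):
        with pytest.raises(ValueError, match="2 electrodes"):
            permutation_mean_test(np.ones((1, 5)), 100)

    def test_add_one_convention_lower_bound(self):
        p = permutation_mean_test(np.random.default_rng(0).standard_normal((6, 2)) + 10,
                                  500, rng_seed=1)
        assert np.all(p >= 1 / 501)


class TestFdrAdjust:
    def test_closed_form_three_values(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_equal_values_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.full(7, 0.2)), np.full(7, 0.2))

    def test_matches_bruteforce_stepup(self):
        """Agrees exactly with an independent brute-force BH step-up."""
        rng = np.random.default_rng(0)
        p = rng.random(101)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(fdr_adjust(p), adj)

    def test_never_decreases(self):
        p = np.random.default_rng(1).random(50)
        assert np.all(fdr_adjust(p) >= p)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))


class TestDurationFilter:
    times = np.arange(0, 400, 10.0)

    def mask(self, *runs):
        m = np.zeros(self.times.size, dtype=bool)
        for start, stop in runs:
            m[start:stop] = True
        return m

    def test_five_bins_dropped(self):
        assert duration_filter(self.mask((3, 8)), self.times, 60) == []

    def test_six_bins_retained(self):
        eps = duration_filter(self.mask((3, 9)), self.times, 60)
        assert len(eps) == 1
        assert eps[0].duration_ms == 60.0

    def test_seven_bins_single_epoch(self):
        eps = duration_filter(self.mask((3, 10)), self.times, 60)
        assert len(eps) == 1 and eps[0].n_bins == 7

    def test_alternating_bins_no_epochs(self):
        m = np.zeros(self.times.size, dtype=bool)
        m[::2] = True
        assert duration_filter(m, self.times, 60) == []

    def test_padding_invariance(self):
        m = self.mask((5, 15))
        base = duration_filter(m, self.times, 60)
        padded = np.concatenate([np.zeros(10, bool), m])
        tp = np.arange(-100, 400, 10.0)
        shifted = duration_filter(padded, tp, 60)
        assert [(e.start_ms, e.end_ms) for e in base] == \
               [(e.start_ms, e.end_ms) for e in shifted]

    def test_sign_split_and_labels(self):
        m = self.mask((0, 14))
        mean = np.where(self.times < 70, 1.0, -1.0)
        eps = duration_filter(m, self.times, 60, mean=mean)
        assert [e.sign for e in eps] == ["augmentation", "suppression"]


class TestSlopeEstimate:
    def test_linear_ramp_recovered(self):
        """A 10%/s ramp yields slope 10%/s at every valid center."""
        times = np.arange(0, 2000, 10.0)
        vals = np.tile(times / 1000.0 * 10.0, (5, 1))
        sl = slope_estimate(make_tc(vals, times), 600.0, n_boot=20, rng_seed=0)
        np.testing.assert_allclose(sl.slope, 10.0, rtol=1e-9)
        assert sl.argmax_time == sl.times[0]  # earliest on ties

    def test_constant_trace_zero_slope(self):
        vals = np.full((4, 150), 3.0)
        sl = slope_estimate(make_tc(vals), 600.0, n_boot=20, rng_seed=0)
        np.testing.assert_allclose(sl.slope, 0.0, atol=1e-12)

    def test_window_exceeding_span_rejected(self):
        vals = np.zeros((3, 20))
        with pytest.raises(ValueError, match="span"):
            slope_estimate(make_tc(vals), 600.0)

    def test_ci_contains_point_estimate_for_homogeneous_rows(self):
        rng = np.random.default_rng(0)
        times = np.arange(0, 1500, 10.0)
        base = times / 1000.0 * 5.0
        vals = base + rng.standard_normal((20, times.size)) * 0.1
        sl = slope_estimate(make_tc(vals, times), 600.0, n_boot=200, rng_seed=1)
        inside = (sl.ci_low <= sl.slope) & (sl.slope <= sl.ci_high)
        assert inside.mean() > 0.9
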