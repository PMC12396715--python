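import numpy as np
import pytest

from trnsim.io import FixtureSpec, generate_fixture, planted_trace
from trnsim.spike_analysis import (RateHistogram, SleepAxisGrid, SpikeTrain,
                                   block_mean_correlation, classify_state,
                                   compare_expression_levels, detect_spikes,
                                   histogram_correlation_matrix,
                                   interspike_rate_histogram, log_bin_edges,
                                   segment_bursts, sleep_axis_sweep)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 100, 0.05)
        vm = np.full(t.size, -69.0)
        assert len(detect_spikes((t, vm))) == 0

    def test_planted_spikes_recovered(self):
        times = np.arange(100.0, 1000.0, 90.0)
        t, vm = planted_trace(times)
        det = detect_spikes((t, vm))
        assert len(det) == times.size
        assert np.allclose(det.times, times, atol=0.6)

    def test_refractory_suppresses_double_counts(self):
        t, vm = planted_trace([100.0, 100.8, 200.0])
        det = detect_spikes((t, vm), refractory=2.0)
        assert len(det) == 2

    def test_sampling_rate_consistency(self):
        times = [100.0, 300.0, 500.0]
        t1, v1 = planted_trace(times, dt=0.05)
        t2, v2 = planted_trace(times, dt=0.025)
        d1 = detect_spikes((t1, v1)).times
        d2 = detect_spikes((t2, v2)).times
        assert np.allclose(d1, d2, atol=0.05)


class TestSegmentBursts:
    def test_sparse_spikes_all_tonic(self):
        train = SpikeTrain(np.arange(0.0, 1000.0, 100.0), (0.0, 1000.0))
        seg = segment_bursts(train, intra_burst_isi_max=30.0)
        assert seg.bursts == []
        assert seg.tonic_spikes.size == 10

    def test_planted_two_bursts_and_tonic_tail(self):
        """6 spikes at 5 ms ISI, gap, 6 at 8 ms, then 14 at 70 ms with a
        30 ms threshold: exactly two bursts plus 14 tonic spikes."""
        spec = FixtureSpec(bursts=[(100.0, 6, 5.0), (600.0, 6, 8.0)],
                           tonic=[(1200.0, 14, 70.0)])
        train = generate_fixture(spec)
        seg = segment_bursts(train, intra_burst_isi_max=30.0,
                             min_spikes_per_burst=3)
        truth = spec.ground_truth()
        assert len(seg.bursts) == truth["n_bursts"]
        assert seg.tonic_spikes.size == truth["n_tonic"]

    def test_duration_is_span_of_member_spikes(self):
        train = SpikeTrain(np.array([10.0, 15.0, 20.0, 25.0]), (0.0, 100.0))
        seg = segment_bursts(train)
        assert seg.bursts[0].duration == pytest.approx(15.0)
        assert seg.bursts[0].n_spikes == 4

    def test_every_spike_assigned_once(self):
        spec = FixtureSpec(bursts=[(0.0, 5, 6.0), (300.0, 4, 10.0)],
                           tonic=[(600.0, 7, 90.0)], jitter_ms=1.0, seed=3)
        train = generate_fixture(spec)
        seg = segment_bursts(train)
        n_in_bursts = sum(b.n_spikes for b in seg.bursts)
        assert n_in_bursts + seg.tonic_spikes.size == len(train)


class TestRateHistogram:
    def test_periodic_train_single_bin(self):
        train = SpikeTrain(np.arange(0.0, 5000.0, 50.0), (0.0, 5000.0))
        h = interspike_rate_histogram(train)
        assert h.counts.sum() == len(train) - 1
        centers = h.centers()
        assert abs(centers[np.argmax(h.counts)] - 20.0) < 5.0
        assert h.mass_in_band(15.0, 30.0) == pytest.approx(1.0)

    def test_mixed_isis_land_in_expected_bins(self):
        train = SpikeTrain(np.array([0.0, 10.0, 1010.0]), (0.0, 2000.0))
        h = interspike_rate_histogram(train)
        assert h.counts.sum() == 2
        assert h.mass_below(2.0) == pytest.approx(0.5)
        assert h.mass_in_band(50.0, 200.0) == pytest.approx(0.5)

    def test_count_conservation_with_overflow(self):
        train = SpikeTrain(np.array([0.0, 1.0, 2.0, 500.0]), (0.0, 1000.0))
        h = interspike_rate_histogram(train)  # 1000 Hz rates overflow
        assert h.counts.sum() + h.overflow + h.underflow == len(train) - 1
        assert h.overflow == 2

    def test_too_few_spikes_flagged_empty(self):
        h = interspike_rate_histogram(SpikeTrain(np.array([5.0]),
                                                 (0.0, 10.0)))
        assert h.empty

    def test_zoom_view_shares_edges(self):
        edges = log_bin_edges()
        assert edges[0] == pytest.approx(0.01)
        assert edges[-1] == pytest.approx(380.0)
        assert np.all(np.diff(edges) > 0)


class TestClassifyState:
    def test_pure_20hz_is_wake_like(self):
        train = SpikeTrain(np.arange(0.0, 5000.0, 50.0), (0.0, 5000.0))
        h = interspike_rate_histogram(train)
        assert classify_state(h) == "wake-like"

    def test_slow_plus_fast_is_sleep_like(self):
        # interburst ~3 Hz with fast intraburst components
        times = []
        for k in range(12):
            t0 = 333.0 * k
            times.extend([t0, t0 + 8.0, t0 + 16.0])
        h = interspike_rate_histogram(SpikeTrain(np.array(times),
                                                 (0.0, 5000.0)))
        assert classify_state(h) == "sleep-like"

    def test_empty_histogram_indeterminate(self):
        h = interspike_rate_histogram(SpikeTrain(np.array([1.0]),
                                                 (0.0, 10.0)))
        assert classify_state(h) == "indeterminate"


def _synthetic_runner(g_kl, delay, strength, duration):
    """Deterministic fake network: wake-like at low G_KL, sleep-like
    otherwise; period scales with delay."""
    if g_kl < 0.1:
        times = np.arange(200.0, 10000.0, 50.0 + duration / 10.0)
    else:
        times = []
        period = delay * 2.5
        t0 = 200.0
        while t0 < 10000.0:
            times.extend([t0 + 6.0 * k for k in range(int(strength))])
            t0 += period
        times = np.array(times)
    return SpikeTrain(np.asarray(times), (0.0, 10000.0))


class TestSleepAxisSweep:
    def test_nested_order_and_count(self):
        grid = sleep_axis_sweep([0.07, 0.14, 0.21], [120.0, 200.0],
                                [4.0, 6.0], [15.0, 30.0],
                                _synthetic_runner)
        assert len(grid) == 24
        # outermost loop is adenosine: first third shares the lowest level
        assert all(grid.param_tuples[i][0] == 0.07 for i in grid.third(0))
        # innermost loop is duration: consecutive tuples differ in it
        assert grid.param_tuples[0][:3] == grid.param_tuples[1][:3]
        assert grid.param_tuples[0][3] != grid.param_tuples[1][3]

    def test_low_adenosine_third_wake_like(self):
        grid = sleep_axis_sweep([0.07, 0.14, 0.21], [120.0, 200.0],
                                [4.0, 6.0], [15.0, 30.0],
                                _synthetic_runner)
        for i in grid.third(0):
            assert grid.histograms[i].mass_below(10.0) < 0.01

    def test_failed_trial_records_gap(self):
        def failing(g_kl, delay, strength, duration):
            if delay > 150:
                raise RuntimeError("boom")
            return _synthetic_runner(g_kl, delay, strength, duration)

        grid = sleep_axis_sweep([0.07], [120.0, 200.0], [4.0], [15.0],
                                failing)
        assert grid.histograms[0] is not None
        assert grid.histograms[1] is None

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sleep_axis_sweep([], [120.0], [4.0], [15.0], _synthetic_runner)


class TestCorrelationMatrix:
    def _h(self, counts):
        edges = np.arange(len(counts) + 1, dtype=float) + 1.0
        return RateHistogram(edges, np.asarray(counts, dtype=float))

    def test_identical_histograms_correlate_fully(self):
        mat = histogram_correlation_matrix([self._h([1, 2, 3]),
                                            self._h([1, 2, 3])])
        assert mat[0, 1] == pytest.approx(1.0)

    def test_reversed_histograms_anticorrelate(self):
        mat = histogram_correlation_matrix([self._h([1, 2, 3]),
                                            self._h([3, 2, 1])])
        assert mat[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        mat = histogram_correlation_matrix([self._h([1, 0, 2]),
                                            self._h([2, 1, 0])])
        assert mat[0, 1] == pytest.approx(-0.5)

    def test_symmetry_unit_diagonal_and_range(self):
        rng = np.random.default_rng(0)
        hists = [self._h(rng.integers(0, 20, 8)) for _ in range(5)]
        mat = histogram_correlation_matrix(hists)
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.allclose(np.diag(mat), 1.0)
        finite = mat[np.isfinite(mat)]
        assert finite.min() >= -1.0 - 1e-12
        assert finite.max() <= 1.0 + 1e-12

    def test_zero_variance_yields_nan_sentinel(self):
        mat = histogram_correlation_matrix([self._h([2, 2, 2]),
                                            self._h([1, 2, 3])])
        assert np.isnan(mat[0, 1])

    def test_mismatched_edges_rejected(self):
        h1 = self._h([1, 2, 3])
        h2 = RateHistogram(np.array([1.0, 2.0, 4.0, 8.0]),
                           np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="edges"):
            histogram_correlation_matrix([h1, h2])

    def test_block_means_exclude_nan(self):
        mat = np.array([[1.0, 0.5, np.nan], [0.5, 1.0, 0.2],
                        [np.nan, 0.2, 1.0]])
        assert block_mean_correlation(mat, [0, 1], [2]) == pytest.approx(0.2)


class TestCompareExpressionLevels:
    def test_summary_structure(self):
        grids = {}
        for expr in (0.5, 1.0):
            def runner(g_kl, d, s, u, _e=expr):
                if _e < 0.9 and g_kl < 0.1:
                    return _synthetic_runner(0.2, d, s, u)  # bursty
                return _synthetic_runner(g_kl, d, s, u)
            grids[expr] = sleep_axis_sweep([0.07, 0.14, 0.21],
                                           [120.0, 200.0], [4.0, 6.0],
                                           [15.0, 30.0], runner)
        summary = compare_expression_levels(grids)
        assert summary[1.0]["sleep_like_fraction"] <= 0.01
        assert summary[0.5]["sleep_like_fraction"] > 0.5
        assert summary[0.5]["low_freq_mass"] > summary[1.0]["low_freq_mass"]
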