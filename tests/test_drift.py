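"""Drift correction: windowing, pairwise shifts, least squares, recovery."""

import numpy as np
import pytest

import minfluxpaint as mp
from minfluxpaint.drift import (DriftTrace, WindowPairShift, pairwise_shift,
                                render_positions, solve_drift, window_events)
from conftest import drift_recovery_rms, trace_rms


class TestWindowing:
    def test_strided_window_arithmetic(self):
        wins = window_events(6000, target_per_window=2000,
                             overlap_fraction=0.5)
        assert wins == [(0, 2000), (1000, 3000), (2000, 4000),
                        (3000, 5000), (4000, 6000)]

    def test_single_window_when_too_few_events(self):
        assert window_events(2000, 2000) == [(0, 2000)]

    def test_every_event_covered(self):
        wins = window_events(5321, 2000, 0.5)
        covered = np.zeros(5321, bool)
        for a, b in wins:
            covered[a:b] = True
        assert covered.all()

    def test_single_window_refuses_drift_estimation(self, grid_acquisition):
        _, _, ds, _ = grid_acquisition
        events = mp.extract_events(ds)
        with pytest.raises(ValueError, match="window"):
            mp.estimate_drift(events, target_per_window=10 * len(events))


@pytest.fixture(scope="module")
def cloud():
    rng = np.random.default_rng(8)
    return rng.uniform(50, 450, (800, 2))


class TestPairwiseShift:
    def test_self_correlation_zero_shift(self, cloud):
        img = render_positions(cloud)
        s = pairwise_shift(img, img)
        np.testing.assert_allclose(s.shift, 0.0, atol=0.05)
        assert s.quality == pytest.approx(1.0, abs=1e-6)

    def test_known_translation_recovered(self, cloud):
        bounds = np.array([[0.0, 520.0], [0.0, 520.0]])
        a = render_positions(cloud, bounds=bounds)
        b = render_positions(cloud + [10.0, -4.0], bounds=bounds)
        s = pairwise_shift(a, b)
        np.testing.assert_allclose(s.shift, [10.0, -4.0], atol=0.5)

    def test_subpixel_translation_recovered(self, cloud):
        bounds = np.array([[0.0, 520.0], [0.0, 520.0]])
        a = render_positions(cloud, bounds=bounds)
        b = render_positions(cloud + [3.4, 0.0], bounds=bounds)
        s = pairwise_shift(a, b)
        np.testing.assert_allclose(s.shift, [3.4, 0.0], atol=0.5)

    def test_antisymmetry(self, cloud):
        bounds = np.array([[0.0, 520.0], [0.0, 520.0]])
        a = render_positions(cloud, bounds=bounds)
        b = render_positions(cloud + [7.0, 2.0], bounds=bounds)
        sab = pairwise_shift(a, b)
        sba = pairwise_shift(b, a)
        np.testing.assert_allclose(sab.shift, -sba.shift, atol=0.1)

    def test_grid_mismatch_rejected(self, cloud):
        a = render_positions(cloud, pixel=1.0)
        b = render_positions(cloud, pixel=2.0)
        with pytest.raises(ValueError, match="grid"):
            pairwise_shift(a, b)


class TestSolveDrift:
    def _consistent_shifts(self, offsets):
        return [WindowPairShift(i, j, offsets[j] - offsets[i], 1.0)
                for i in range(len(offsets))
                for j in range(i + 1, len(offsets))]

    def test_consistent_linear_shifts_solved_exactly(self):
        times = np.arange(5.0)
        offsets = np.column_stack([2.0 * times, -1.0 * times])
        trace = solve_drift(self._consistent_shifts(offsets), times)
        centered = offsets - offsets.mean(axis=0)
        np.testing.assert_allclose(trace.offsets, centered, atol=1e-9)

    def test_all_zero_shifts_zero_trace(self):
        times = np.arange(4.0)
        shifts = self._consistent_shifts(np.zeros((4, 2)))
        trace = solve_drift(shifts, times)
        np.testing.assert_allclose(trace.offsets, 0.0, atol=1e-12)

    def test_time_translation_leaves_offsets(self):
        times = np.arange(5.0)
        offsets = np.column_stack([times ** 2, times])
        shifts = self._consistent_shifts(offsets)
        a = solve_drift(shifts, times)
        b = solve_drift(shifts, times + 1000.0)
        np.testing.assert_allclose(a.offsets, b.offsets)

    def test_disconnected_graph_names_components(self):
        shifts = [WindowPairShift(0, 1, np.zeros(2), 1.0),
                  WindowPairShift(2, 3, np.zeros(2), 1.0)]
        with pytest.raises(ValueError, match="disconnected"):
            solve_drift(shifts, np.arange(4.0))


class TestCorrection:
    def test_zero_trace_is_identity(self, grid_acquisition):
        _, _, ds, _ = grid_acquisition
        events = mp.extract_events(ds)[:20]
        trace = DriftTrace(times=np.array([0.0, 300.0]),
                           offsets=np.zeros((2, 2)))
        corrected = mp.correct(events, trace)
        for a, b in zip(events, corrected):
            np.testing.assert_array_equal(a.mean_pos, b.mean_pos)

    def test_linear_drift_recovered_below_2nm_rms(self, linear_drift_run):
        assert drift_recovery_rms(linear_drift_run) < 2.0

    def test_spline_drift_recovered_below_2nm_rms(self, spline_drift_run):
        assert drift_recovery_rms(spline_drift_run) < 2.0

    @pytest.mark.parametrize("run_name",
                             ["linear_drift_run", "spline_drift_run"])
    def test_second_pass_much_smaller_than_first(self, run_name, request):
        run = request.getfixturevalue(run_name)
        assert trace_rms(run["trace2"]) < 0.10 * trace_rms(run["trace"])

    def test_corrected_positions_cluster_tighter(self, spline_drift_run):
        raw = np.array([e.mean_pos for e in spline_drift_run["events"]])
        cor = np.array([e.mean_pos for e in spline_drift_run["corrected"]])
        # dispersion around per-site means shrinks after correction
        truth = spline_drift_run["truth"].events
        sites = truth["site"].to_numpy()

        def spread(p):
            tot = 0.0
            for s in np.unique(sites):
                q = p[sites == s]
                tot += ((q - q.mean(axis=0)) ** 2).sum()
            return tot

        assert spread(cor) < spread(raw)

    def test_gauge_invariance_under_global_offset(self, grid_acquisition):
        _, _, ds, _ = grid_acquisition
        events = mp.extract_events(ds)
        shifted = ds.copy()
        shifted.records[["x", "y"]] += 500.0
        events_shifted = mp.extract_events(shifted)
        per_window = max(50, len(events) // 6)
        a = mp.estimate_drift(events, target_per_window=per_window)
        b = mp.estimate_drift(events_shifted, target_per_window=per_window)
        np.testing.assert_allclose(a.offsets, b.offsets, atol=0.05)
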