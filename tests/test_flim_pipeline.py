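"""Grid ROIs, photon pooling, the 1500-photon filter, Ca conversion,
transient measurement, uncaging deltas and volume fraction."""

import numpy as np
import pytest

from caflim import flim_pipeline as fp
from caflim import stats, synth, workflows
from caflim.io import TcspcStack


def _uniform_stack(n_frames=4, ny=8, nx=8, n_bins=25, counts_per_bin=2,
                   frame_interval=0.3):
    photons = np.full((n_frames, ny, nx, n_bins), counts_per_bin,
                      dtype=np.int64)
    return TcspcStack(photons, microtime_bin_ns=0.5,
                      frame_interval_s=frame_interval, pixel_um=1.25,
                      irf_center_ns=1.5, irf_sigma_ns=0.15,
                      record_length_ns=12.5)


class TestRoiGrid:
    def test_60um_field_5um_tiles(self):
        grid = fp.make_roi_grid((60, 60), pixel_um=1.0, tile_um=5.0)
        assert (grid.n_rows, grid.n_cols, grid.n_rois) == (12, 12, 144)

    def test_subpixel_geometry(self):
        grid = fp.make_roi_grid((160, 160), pixel_um=0.5, tile_um=5.0)
        assert (grid.n_rows, grid.n_cols, grid.tile_px) == (16, 16, 10)

    def test_partial_edge_tiles_dropped(self):
        grid = fp.make_roi_grid((23, 23), pixel_um=1.0, tile_um=5.0)
        assert (grid.n_rows, grid.n_cols) == (4, 4)

    def test_mask_flags_touched_tiles(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:2, 0:2] = True
        grid = fp.make_roi_grid((20, 20), 1.0, 5.0, mask=mask)
        assert grid.excluded[0, 0] and not grid.excluded[1, 1]

    def test_tiny_tile_rejected(self):
        with pytest.raises(ValueError):
            fp.make_roi_grid((20, 20), pixel_um=4.0, tile_um=5.0)


class TestPoolPhotons:
    def test_total_photons_conserved(self):
        stack = _uniform_stack()
        grid = fp.make_roi_grid(stack.shape_yx, stack.pixel_um, 5.0)
        pooled = fp.pool_photons(stack, grid, window_s=0.6)
        assert pooled.sum() == stack.photons.sum()

    def test_single_frame_window_equals_tile_sum(self):
        stack = _uniform_stack(n_frames=1, frame_interval=0.6)
        grid = fp.make_roi_grid(stack.shape_yx, stack.pixel_um, 5.0)
        pooled = fp.pool_photons(stack, grid, window_s=0.6)
        t = grid.tile_px
        manual = stack.photons[0, :t, :t].sum()
        assert pooled[0, 0, 0].sum() == manual

    def test_window_smaller_than_frame_rejected(self):
        stack = _uniform_stack(frame_interval=1.0)
        grid = fp.make_roi_grid(stack.shape_yx, stack.pixel_um, 5.0)
        with pytest.raises(ValueError):
            fp.pool_photons(stack, grid, window_s=0.6)

    def test_uniform_rate_within_poisson_error(self, calibration):
        curve, correction, _ = calibration
        cell = synth.generate_baseline_field((4, 4), 100.0, 0.0, seed=0)
        movie = np.broadcast_to(cell.baseline_nm, (20, 4, 4))
        acq = synth.AcquisitionSpec(frame_interval_s=0.3,
                                    pixels_per_roi_side=2)
        stack = synth.render_flim_movie(movie, cell, acquisition=acq, seed=1)
        grid = fp.make_roi_grid(stack.shape_yx, stack.pixel_um, 5.0)
        pooled = fp.pool_photons(stack, grid, 0.6)
        soma = cell.soma_rc
        per_window = pooled[:, soma[0], soma[1]].sum(axis=-1)
        expect = acq.photons_per_roi_per_window \
            * float(synth.INTRA_INDICATOR.brightness(100.0)
                    / synth.INTRA_INDICATOR.brightness(62.7))
        assert np.mean(per_window) == pytest.approx(
            expect, rel=4 / np.sqrt(expect * len(per_window)) + 0.01)


class TestFilterRois:
    def _pooled(self, means, n_windows=4, n_bins=10):
        # pooled histograms whose per-window totals equal `means`
        means = np.asarray(means, dtype=float)
        pooled = np.zeros((n_windows, *means.shape, n_bins))
        pooled[..., 0] = means[None, :, :]
        return pooled

    def test_threshold_boundary_inclusive(self):
        pooled = self._pooled(np.array([[1499.0, 1500.0]]))
        grid = fp.RoiGrid(4, 1, 2, 1.25)
        kept, report = fp.filter_rois(pooled, grid)
        assert not kept[0, 0] and kept[0, 1]
        assert report.iloc[0]["reason"] == "low_photons"

    def test_zero_threshold_keeps_all_unmasked(self):
        pooled = self._pooled(np.array([[0.0, 10.0]]))
        grid = fp.RoiGrid(4, 1, 2, 1.25)
        kept, _ = fp.filter_rois(pooled, grid, min_mean_photons=0.0)
        assert kept.all()

    def test_masked_roi_rejected_with_reason(self):
        pooled = self._pooled(np.array([[5000.0, 5000.0]]))
        excluded = np.array([[True, False]])
        grid = fp.RoiGrid(4, 1, 2, 1.25, excluded)
        kept, report = fp.filter_rois(pooled, grid)
        assert not kept[0, 0] and kept[0, 1]
        assert report.iloc[0]["reason"] == "excluded_mask"

    def test_background_rois_outside_cell_rejected(self, calibration):
        # ROIs beyond the cell border collect essentially no photons and
        # fall to the 1500-photon filter
        cell = synth.generate_baseline_field((9, 9), cell_radius_um=12.0,
                                             seed=5)
        movie = np.broadcast_to(cell.baseline_nm, (10, 9, 9))
        acq = synth.AcquisitionSpec(frame_interval_s=0.3,
                                    pixels_per_roi_side=2)
        stack = synth.render_flim_movie(movie, cell, acquisition=acq, seed=6)
        grid = fp.make_roi_grid(stack.shape_yx, stack.pixel_um, 5.0)
        pooled = fp.pool_photons(stack, grid, 0.6)
        kept, _ = fp.filter_rois(pooled, grid)
        assert not kept[~cell.inside_mask].any()
        assert kept[cell.inside_mask].all()


class TestConvertToCa:
    def test_uniform_stack_recovers_concentration(self, calibration):
        curve, correction, _ = calibration
        cell = synth.generate_baseline_field((4, 4), 100.0, 0.0, seed=0)
        movie = np.broadcast_to(cell.baseline_nm, (40, 4, 4))
        acq = synth.AcquisitionSpec(frame_interval_s=0.3,
                                    pixels_per_roi_side=2)
        stack = synth.render_flim_movie(movie, cell, acquisition=acq, seed=2)
        grid = fp.make_roi_grid(stack.shape_yx, stack.pixel_um, 5.0)
        pooled = fp.pool_photons(stack, grid, 0.6)
        kept, _ = fp.filter_rois(pooled, grid)
        series = fp.convert_to_ca(pooled, grid, kept, curve,
                                  stack.microtime_bin_ns, correction)
        for s in series.values():
            assert np.nanmean(s.ca_nm) == pytest.approx(100.0, rel=0.05)
            assert len(s.ca_nm) == pooled.shape[0]

    def test_empty_window_propagates_as_gap(self, calibration):
        curve, correction, _ = calibration
        pooled = np.zeros((3, 1, 1, 125))
        pooled[0, 0, 0, 10] = 2000  # early-only photons
        pooled[0, 0, 0, 60] = 1500
        pooled[2, 0, 0, 60] = 2000  # window 1 has zero counts -> defined
        # window index 1 left completely empty -> undefined ratio
        grid = fp.RoiGrid(2, 1, 1, 2.5)
        kept = np.ones((1, 1), dtype=bool)
        series = fp.convert_to_ca(pooled, grid, kept, curve, 0.1, correction)
        s = series[(0, 0)]
        assert np.isfinite(s.ca_nm[0])
        assert np.isnan(s.ca_nm[1])
        assert np.isfinite(s.ca_nm[2])


class TestMeasureEvoked:
    def _series(self, values, window_s=0.6):
        values = np.asarray(values, dtype=float)
        t = (np.arange(values.size) + 0.5) * window_s
        return fp.CaTimeSeries((0, 0), t, values, np.full(values.size, 3e3),
                               np.zeros(values.size, dtype=bool))

    def test_flat_series(self):
        m = fp.measure_evoked(self._series([50.0] * 30), stim_time_s=9.0)
        assert (m.baseline, m.peak, m.amplitude) == (50.0, 50.0, 0.0)

    def test_amplitude_identity_exact(self):
        rng = np.random.default_rng(0)
        m = fp.measure_evoked(self._series(50 + rng.normal(0, 3, 40)), 9.0)
        assert m.amplitude == m.peak - m.baseline

    def test_windows_outside_series_rejected(self):
        with pytest.raises(ValueError):
            fp.measure_evoked(self._series([50.0] * 10), stim_time_s=60.0)

    def test_known_kernel_recovered_against_ground_truth(self, calibration):
        curve, correction, _ = calibration
        measured, truth, _ = workflows.flim_evoked_experiment(
            123, curve, correction)
        merged = measured.merge(truth, on=["roi_row", "roi_col"])
        # per-ROI measures track the generator's ground-truth table
        base_err = np.abs(merged.baseline / merged.baseline_nm - 1)
        peak_err = np.abs(merged.peak / merged.peak_nm - 1)
        assert np.median(base_err) < 0.05
        assert np.median(peak_err) < 0.08
        assert stats.spearman_r(merged.baseline, merged.baseline_nm) > 0.9
        assert stats.spearman_r(merged.amplitude, merged.amplitude_nm) > 0.8


class TestDetectSpontaneous:
    def _noisy_series(self, rng, n=1000, sigma=2.0, events=()):
        values = 50.0 + rng.normal(0, sigma, n)
        t = (np.arange(n) + 0.5) * 0.6
        for t_ev, amp in events:
            k = synth.TransientKernel()
            values += amp * k.waveform(t - t_ev)
        return fp.CaTimeSeries((0, 0), t, values, np.full(n, 3e3),
                               np.zeros(n, dtype=bool))

    def test_false_positive_rate_under_null(self):
        rng = np.random.default_rng(0)
        n_events = sum(
            len(fp.detect_spontaneous(self._noisy_series(rng)))
            for _ in range(100))
        # 100 series x 10 min: < 1 false event / 10 min
        assert n_events < 100

    def test_recall_of_injected_events(self):
        rng = np.random.default_rng(1)
        hits = 0
        for i in range(50):
            series = self._noisy_series(rng, events=[(120.0, 10.0)])
            events = fp.detect_spontaneous(series)
            hits += any(abs(e.t_event_s - 121) < 6 for e in events)
        assert hits >= 45  # >= 90% recall at 5-sigma amplitude

    def test_zero_noise_single_event(self):
        series = self._noisy_series(np.random.default_rng(2), sigma=1e-6,
                                    events=[(120.0, 10.0)])
        events = fp.detect_spontaneous(series)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(10.0, rel=0.1)


class TestUncagingDeltas:
    def _measures(self, amps, baselines=None):
        baselines = baselines or [50.0] * len(amps)
        return {
            (0, i): fp.TransientMeasure((0, i), 10.0, b, b + a)
            for i, (a, b) in enumerate(zip(amps, baselines))
        }

    def test_identical_epochs_zero_deltas(self):
        m = self._measures([10.0, 20.0])
        for d in fp.uncaging_deltas(m, m):
            assert d.d_baseline == d.d_peak == d.d_amplitude == 0.0

    def test_response_threshold_boundary(self):
        before = self._measures([5.0, 7.0])
        after = self._measures([6.0, 8.0])
        deltas = {d.roi: d for d in fp.uncaging_deltas(before, after)}
        assert not deltas[(0, 0)].included  # 5 nM response: excluded
        assert deltas[(0, 1)].included      # 7 nM response: included

    def test_roi_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fp.uncaging_deltas(self._measures([10.0]),
                               self._measures([10.0, 12.0]))

    def test_npegta_experiment_sign_structure(self, calibration):
        curve, correction, _ = calibration
        deltas, realized = workflows.flim_uncaging_experiment(
            5, curve, correction)
        assert realized > 0.2  # cage release raised the resting level
        assert stats.spearman_r(deltas.d_baseline, deltas.d_peak) > 0
        assert stats.spearman_r(deltas.d_baseline, deltas.d_amplitude) < 0


class TestComputeVf:
    def test_flat_image_is_100_everywhere(self):
        grid = fp.RoiGrid(5, 4, 4, 1.0)
        vf = fp.compute_vf(np.full((20, 20), 7.0), grid, (1, 1))
        assert np.allclose(vf, 100.0)

    def test_half_intensity_roi(self):
        img = np.full((10, 10), 4.0)
        img[5:, :] = 2.0
        grid = fp.RoiGrid(5, 2, 2, 1.0)
        vf = fp.compute_vf(img, grid, (0, 0))
        assert vf[1, 0] == pytest.approx(50.0)

    def test_zero_soma_rejected(self):
        grid = fp.RoiGrid(5, 2, 2, 1.0)
        with pytest.raises(ValueError):
            fp.compute_vf(np.zeros((10, 10)), grid, (0, 0))

    def test_recovers_generator_field(self):
        cell = synth.generate_baseline_field((6, 6), seed=7)
        k = 4
        img = np.repeat(np.repeat(cell.vf_pct, k, 0), k, 1)
        grid = fp.RoiGrid(k, 6, 6, 5.0 / k)
        vf = fp.compute_vf(img, grid, cell.soma_rc)
        assert np.allclose(vf, cell.vf_pct, rtol=1e-9)
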