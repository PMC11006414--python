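"""Change detection, event segmentation and probability maps."""

import numpy as np
import pandas as pd
import pytest

from nestflux import image_pipeline as ip


def make_sequence(frames, cadence=20.0, pitch=0.15, reference=None):
    frames = np.asarray(frames)
    if reference is None:
        reference = frames[0]
    return ip.TimelapseSequence(frames, cadence * np.arange(len(frames)),
                                pitch, reference)


class TestExtractFrames:
    def test_every_fourth_frame_at_80s(self):
        seq = make_sequence(np.arange(40)[:, None, None] * np.ones((1, 4, 4)))
        sub = ip.extract_frames(seq, 80.0)
        assert len(sub.frames) == 10
        assert sub.frames[1, 0, 0] == 4

    def test_interval_equal_to_cadence_is_identity(self):
        seq = make_sequence(np.zeros((6, 4, 4)))
        sub = ip.extract_frames(seq, 20.0)
        assert len(sub.frames) == 6

    def test_non_multiple_interval_rejected(self):
        seq = make_sequence(np.zeros((6, 4, 4)))
        with pytest.raises(ValueError):
            ip.extract_frames(seq, 70.0)
        with pytest.raises(ValueError):
            ip.extract_frames(seq, 10.0)

    def test_decreasing_timestamps_rejected(self):
        with pytest.raises(ValueError):
            ip.TimelapseSequence(np.zeros((3, 4, 4)), [0.0, 40.0, 20.0],
                                 0.15, np.zeros((4, 4)))


class TestWindowAccounting:
    @pytest.mark.parametrize("n,expected", [(9, 0), (10, 0), (19, 1),
                                            (28, 1), (29, 2), (39, 3)])
    def test_window_count_formula(self, n, expected):
        assert ip.n_windows(n) == (n - ip.MEDIAN_WINDOW + 1) // ip.BLOCK_SIZE
        assert ip.n_windows(n) == expected

    def test_detect_changes_matches_formula(self):
        seq = make_sequence(np.zeros((29, 6, 6)))
        assert len(ip.detect_changes(seq)) == 2


class TestDetectChanges:
    def test_static_sequence_gives_zero_windows(self):
        seq = make_sequence(np.full((19, 8, 8), 50.0))
        cw = ip.detect_changes(seq)
        assert np.allclose(cw.mean, 0.0)
        assert np.allclose(cw.low, 0.0)

    def test_persistent_dark_blob_appears_after_removal(self):
        frames = np.full((29, 16, 16), 100.0)
        frames[5:, 7:10, 7:10] = 40.0    # pellet removed at frame 5
        seq = make_sequence(frames, reference=np.full((16, 16), 100.0))
        cw = ip.detect_changes(seq)
        assert cw.mean[0, 8, 8] < -30     # present in first window
        assert cw.high[1, 8, 8] < -30     # static through the second

    def test_transient_blob_suppressed_by_median(self):
        frames = np.full((19, 16, 16), 100.0)
        frames[4:7, 3:6, 3:6] = 200.0    # "termite" for 3 frames
        seq = make_sequence(frames, reference=np.full((16, 16), 100.0))
        cw = ip.detect_changes(seq)
        assert np.abs(cw.mean).max() < 1e-9

    def test_rgb_frames_converted_by_luminance(self):
        rgb = np.zeros((2, 4, 4, 3))
        rgb[:, :, :, 1] = 100.0
        grey = ip.to_greyscale(rgb[0])
        assert np.allclose(grey, 71.52)


class TestExtractEvents:
    def make_window(self, blobs, shape=(64, 64)):
        """One positive change window with square blobs of given areas."""
        img = np.zeros(shape)
        col = 2
        for area in blobs:
            side = int(np.ceil(np.sqrt(area)))
            block = np.zeros(side * side)
            block[:area] = 50.0
            img[2:2 + side, col:col + side] = block.reshape(side, side)
            col += side + 3
        return img[None]

    @pytest.mark.parametrize("area,kept", [(9, False), (10, True),
                                           (400, True), (401, False)])
    def test_area_filter_closed_interval(self, area, kept):
        win = self.make_window([area], shape=(80, 80))
        events = ip.extract_events(win, "deposition", threshold=10.0)
        assert (len(events[0]) == 1) is kept
        if kept:
            assert events[0][0].area_px == area

    def test_no_suprathreshold_pixels_no_components(self):
        events = ip.extract_events(np.zeros((2, 16, 16)), "collection",
                                   threshold=5.0)
        assert all(len(e) == 0 for e in events)

    def test_polarity_selects_sign(self):
        win = -self.make_window([25])
        assert len(ip.extract_events(win, "collection", threshold=10.0)[0]) == 1
        assert len(ip.extract_events(win, "deposition", threshold=10.0)[0]) == 0

    def test_static_gate_drops_intermittent_trace(self):
        mean = self.make_window([25])
        low = np.zeros_like(mean)         # trace absent in some median frame
        cw = ip.ChangeWindows(mean, low, mean.copy())
        assert len(ip.extract_events(cw, "deposition", threshold=10.0)[0]) == 0
        cw2 = ip.ChangeWindows(mean, mean.copy(), mean.copy())
        assert len(ip.extract_events(cw2, "deposition", threshold=10.0)[0]) == 1

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValueError):
            ip.extract_events(np.zeros((1, 8, 8)), "both")


class TestAccumulate:
    def test_disjoint_events_land_in_their_cells(self):
        events = [[ip.Event(0, (7.0, 7.0), 20, 100.0),
                   ip.Event(0, (32.0, 57.0), 20, 100.0)]]
        hm = ip.accumulate(events, (75, 75), 0.15)
        assert hm.cumulative.shape == (15, 15)
        assert hm.cumulative[1, 1] == 20
        assert hm.cumulative[6, 11] == 20
        assert (hm.cumulative > 0).sum() == 2

    def test_count_mode(self):
        events = [[ip.Event(0, (7.0, 7.0), 20, 100.0)]]
        hm = ip.accumulate(events, (75, 75), 0.15, mode="count")
        assert hm.cumulative.sum() == 1.0

    def test_empty_events_zero_map(self):
        hm = ip.accumulate([], (75, 75), 0.15)
        assert hm.cumulative.sum() == 0

    def test_cumulative_is_last_window(self):
        events = [[ip.Event(0, (7.0, 7.0), 10, 1.0)],
                  [ip.Event(1, (7.0, 7.0), 10, 1.0),
                   ip.Event(1, (40.0, 40.0), 10, 1.0)]]
        hm = ip.accumulate(events, (75, 75), 0.15)
        assert np.array_equal(hm.cumulative, hm.windows[-1])

    def test_non_integer_pitch_ratio_rejected(self):
        with pytest.raises(ValueError):
            ip.accumulate([], (75, 75), 0.2)


class TestOccupancy:
    def test_stationary_point_single_cell(self):
        traj = pd.DataFrame({"frame": np.arange(40), "id": 0,
                             "x": 30.0, "y": 30.0})
        occ = ip.occupancy_map(traj, (75, 75), 0.15)
        assert (occ.cumulative > 0).sum() == 1
        assert occ.cumulative.sum() == 40

    def test_empty_table_zero_map(self):
        traj = pd.DataFrame({"frame": [], "id": [], "x": [], "y": []})
        occ = ip.occupancy_map(traj, (75, 75), 0.15)
        assert occ.cumulative.sum() == 0

    def test_out_of_frame_positions_dropped_and_counted(self):
        traj = pd.DataFrame({"frame": [0, 1, 2], "id": 0,
                             "x": [30.0, -5.0, 900.0], "y": 30.0})
        occ = ip.occupancy_map(traj, (75, 75), 0.15)
        assert occ.n_dropped == 2
        assert occ.cumulative.sum() == 1

    def test_uniform_positions_pass_chi2(self):
        rng = np.random.default_rng(7)
        n = 40000
        traj = pd.DataFrame({"frame": np.zeros(n, int), "id": 0,
                             "x": rng.uniform(0, 75, n),
                             "y": rng.uniform(0, 75, n)})
        occ = ip.occupancy_map(traj, (75, 75), 0.15)
        from scipy.stats import chisquare
        stat, p = chisquare(occ.cumulative.ravel())
        assert p > 0.01


class TestProbabilityMaps:
    def test_mean_normalization(self):
        grid = np.zeros((10, 10))
        grid[3, 4] = 50.0
        out = ip.normalize_by_mean(grid)
        assert out.mean() == pytest.approx(1.0)
        assert out[3, 4] == pytest.approx(100.0)   # N=50 over 100 cells

    def test_constant_map_normalizes_to_ones(self):
        assert np.allclose(ip.normalize_by_mean(np.full((5, 5), 3.0)), 1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            ip.normalize_by_mean(np.zeros((4, 4)))

    def test_conditional_identity_on_valid_cells(self):
        rng = np.random.default_rng(0)
        occ = rng.uniform(0.0, 2.0, (12, 12))
        occ[0, :] = 0.0
        act = rng.uniform(0.0, 1.0, (12, 12))
        cm = ip.conditional(act, occ, eps=1e-6)
        v = cm.valid
        assert not v[0].any()
        assert np.allclose(cm.values[v] * occ[v], act[v])
        assert np.isnan(cm.values[~v]).all()

    def test_conditional_equal_maps_give_ones(self):
        occ = np.full((6, 6), 2.0)
        cm = ip.conditional(occ, occ)
        assert np.allclose(cm.values, 1.0)


class TestProfiles:
    def test_uniform_map_flat_radial_density(self):
        prof = ip.radial_density(np.ones((41, 41)), (20, 20), bin_width=2.0)
        inner = prof.values[:6]
        assert prof.values.sum() == pytest.approx(1.0)
        assert inner.std() / inner.mean() < 0.1

    def test_ring_map_single_dominant_bin(self):
        grid = np.zeros((41, 41))
        ii, jj = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        r = np.hypot(ii - 20, jj - 20) * ip.CELL_MM
        grid[(r > 9.0) & (r < 10.5)] = 1.0
        prof = ip.radial_density(grid, (20, 20), bin_width=1.5)
        assert prof.r[np.argmax(prof.values)] == pytest.approx(9.75, abs=1.5)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            ip.radial_density(np.ones((10, 10)), (20, 20))

    def test_cross_section_constant_map(self):
        prof = ip.cross_section(np.full((9, 9), 4.0), row=4)
        assert np.allclose(prof.values, 1.0)

    def test_cross_section_peak_location(self):
        grid = np.zeros((9, 21))
        grid[4, 15] = 7.0
        prof = ip.cross_section(grid, row=4, center_col=10.0)
        assert prof.values.max() == 1.0
        assert prof.r[np.argmax(prof.values)] == pytest.approx(5 * ip.CELL_MM)

    def test_cross_section_zero_cut_rejected(self):
        with pytest.raises(ValueError):
            ip.cross_section(np.zeros((5, 5)), row=2)
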