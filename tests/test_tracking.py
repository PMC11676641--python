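"""Tests of blob detection, motion history images, and track linking."""

import numpy as np
import pytest

from halotrack.core import ImageStack, Track
from halotrack.metrics import MotilityCriteria, calibrate_motility_criteria
from halotrack.simulate import MotionParams, SceneSpec, build_scene_tracks, render_stack
from halotrack.tracking import (
    Detection,
    DetectionParams,
    LinkingParams,
    compute_mhi,
    count_first_frame_blobs,
    count_motile_tracks,
    detect_blobs,
    link_tracks,
    stitch_tracks,
    track_stack,
)

PX = 0.22  # µm/px of the reduced-resolution test scenes


def scene(w=160, h=120, **kw):
    defaults = dict(
        width_px=w,
        height_px=h,
        field_width_um=w * PX * 1.001,  # keep isotropy exact enough
        field_height_um=h * PX * 1.001,
        n_motile=0,
        n_nonmotile=0,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SceneSpec(**defaults)


def static_track(x_um, y_um, n=5, tid="s"):
    t = np.arange(n) / 7.0
    return Track(tid, np.arange(n), t, np.full(n, x_um), np.full(n, y_um))


class TestDetection:
    def test_constant_frame_no_detections_and_warning(self):
        frame = np.full((50, 50), 10.0)
        with pytest.warns(UserWarning):
            assert detect_blobs(frame, PX) == []

    def test_single_spot_subpixel_centroid(self):
        sc = scene()
        tr = static_track(17.3, 12.9)
        stack, _ = render_stack([tr], sc)
        dets = detect_blobs(stack.frames[0], stack.pixel_size)
        assert len(dets) == 1
        assert abs(dets[0].x_um - 17.3) < 0.25 * stack.pixel_size
        assert abs(dets[0].y_um - 12.9) < 0.25 * stack.pixel_size

    def test_two_well_separated_spots(self):
        sc = scene()
        stack, _ = render_stack([static_track(10.0, 10.0, tid="a"), static_track(20.0, 10.0, tid="b")], sc)
        assert len(detect_blobs(stack.frames[0], stack.pixel_size)) == 2

    def test_overlapping_spots_merge_into_one(self):
        # closer than 2 sigma: a single intensity peak, one detection
        sc = scene()
        stack, _ = render_stack(
            [static_track(10.0, 10.0, tid="a"), static_track(10.4, 10.0, tid="b")], sc
        )
        assert len(detect_blobs(stack.frames[0], stack.pixel_size)) == 1

    def test_touching_spots_split_by_watershed(self):
        # 3 sigma apart: masks touch but two peaks persist
        sc = scene()
        stack, _ = render_stack(
            [static_track(10.0, 10.0, tid="a"), static_track(11.5, 10.0, tid="b")], sc
        )
        assert len(detect_blobs(stack.frames[0], stack.pixel_size)) == 2

    def test_area_window_filters(self):
        sc = scene()
        stack, _ = render_stack([static_track(15.0, 15.0)], sc)
        params = DetectionParams(min_area_px=10_000)
        assert detect_blobs(stack.frames[0], stack.pixel_size, params) == []


class TestFirstFrameCount:
    def grid_scene(self):
        sc = scene(w=320, h=240)
        tracks = []
        k = 0
        for gy in range(6):
            for gx in range(10):
                tracks.append(static_track(5.0 + gx * 6.0, 5.0 + gy * 8.0, tid=f"g{k}"))
                k += 1
        stack, _ = render_stack(tracks, sc)
        return stack, len(tracks)

    def test_count_equals_ground_truth_for_separated_cells(self):
        stack, n = self.grid_scene()
        assert count_first_frame_blobs(stack) == n

    def test_empty_scene_counts_zero(self):
        stack, _ = render_stack([], scene())
        assert count_first_frame_blobs(stack) == 0

    def test_invariant_to_frames_after_first(self):
        stack, n = self.grid_scene()
        frames = stack.frames.copy()
        frames[1:] = frames[1:, ::-1, :]  # scramble everything after frame 0
        other = ImageStack(frames, stack.frame_rate, stack.pixel_size)
        assert count_first_frame_blobs(other) == count_first_frame_blobs(stack)


class TestMHI:
    def test_static_scene_zero_mhi(self):
        sc = scene(noise_sd=1.5)
        stack, _ = render_stack([static_track(10.0, 10.0)], sc)
        mhi = compute_mhi(stack)
        assert mhi.n_active == 0

    def test_two_identical_frames_zero_mhi(self):
        frames = np.tile(np.random.default_rng(0).normal(50, 2, (40, 40)), (2, 1, 1))
        stack = ImageStack(frames, 7.0, PX)
        assert compute_mhi(stack).n_active == 0

    def test_moving_cell_traces_its_path(self):
        sc = scene(w=640, h=480)
        n = 71
        t = np.arange(n) / 7.0
        # straight diagonal at 10 µm/s
        x = 5.0 + 10.0 * t * 0.8
        y = 5.0 + 10.0 * t * 0.6
        tr = Track("m", np.arange(n), t, x, y)
        stack, _ = render_stack([tr], sc)
        mhi = compute_mhi(stack)
        assert mhi.n_active > 0
        rows, cols = np.nonzero(mhi.values)
        xs, ys = cols * sc.pixel_size, rows * sc.pixel_size
        extent = np.hypot(xs.max() - xs.min(), ys.max() - ys.min())
        path = 10.0 * t[-1]
        # active pixels span the path, extended by up to one detection
        # radius (~2.5 sigma) at each end
        assert extent == pytest.approx(path, abs=8.0 * sc.spot_sigma_um)
        # every late track point is near active pixels
        for i in range(1, n):
            d = np.hypot(xs - x[i], ys - y[i]).min()
            assert d < 2.0

    def test_lower_threshold_never_decreases_active_count(self):
        sc = scene(noise_sd=1.0)
        tracks = build_scene_tracks(
            scene(noise_sd=1.0, n_motile=2, n_nonmotile=3), MotionParams(), 5
        )
        stack, _ = render_stack(tracks, sc)
        counts = [
            compute_mhi(stack, diff_threshold=thr).n_active for thr in (40.0, 20.0, 10.0, 5.0)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_window_drops_old_activity(self):
        sc = scene(w=640, h=480)
        n = 71
        t = np.arange(n) / 7.0
        tr = Track("m", np.arange(n), t, 5.0 + 10 * t * 0.8, 5.0 + 10 * t * 0.6)
        stack, _ = render_stack([tr], sc)
        full = compute_mhi(stack)
        recent = compute_mhi(stack, window=2.0)
        assert 0 < recent.n_active < full.n_active
        assert recent.values[recent.values > 0].min() >= stack.duration - 2.0 - 1e-9


def dets_from_path(points_per_frame):
    out = []
    for f, pts in enumerate(points_per_frame):
        out.append([Detection(f, x, y, 10, 100.0) for x, y in pts])
    return out


class TestLinking:
    def test_no_detections_no_tracks(self):
        assert link_tracks([[], [], []], 7.0) == []

    def test_single_moving_cell_recovered_end_to_end(self):
        sc = scene(w=640, h=480)
        n = 71
        t = np.arange(n) / 7.0
        tr = Track("m", np.arange(n), t, 5.0 + 10 * t * 0.8, 5.0 + 10 * t * 0.6)
        stack, _ = render_stack([tr], sc)
        res = track_stack(stack)
        assert len(res.tracks) == 1
        assert res.tracks[0].n_points >= 0.95 * n

    def test_two_parallel_cells_no_identity_swap(self):
        n = 40
        frames = []
        for f in range(n):
            x = 2.0 + 1.2 * f
            frames.append([(x, 10.0), (x, 30.0)])  # 20 µm apart, same velocity
        tracks = link_tracks(dets_from_path(frames), 7.0)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.y) < 1e-9  # each track stays on its own line

    def test_no_step_exceeds_gate(self, rng):
        # random clutter: whatever gets linked must respect the gate
        params = LinkingParams()
        frames = []
        for f in range(30):
            pts = [(rng.uniform(0, 30), rng.uniform(0, 30)) for _ in range(8)]
            frames.append(pts)
        tracks = link_tracks(dets_from_path(frames), 7.0, params, min_track_frames=2)
        step_gate = params.max_speed_um_s / 7.0
        for tr in tracks:
            steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
            assert (steps <= step_gate + 1e-9).all()

    def test_gap_bridged_by_linear_interpolation(self):
        n = 20
        frames = []
        for f in range(n):
            if 8 <= f <= 9:
                frames.append([])  # 2-frame dropout
            else:
                frames.append([(1.0 * f, 5.0)])
        tracks = link_tracks(dets_from_path(frames), 7.0, min_track_frames=2)
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.n_points == n
        assert tr.x[8] == pytest.approx(8.0, abs=1e-6)
        assert tr.x[9] == pytest.approx(9.0, abs=1e-6)

    def test_stitching_rejoins_long_dropout(self):
        n = 30
        frames = []
        for f in range(n):
            if 12 <= f <= 17:  # 6-frame dropout, beyond max_gap
                frames.append([])
            else:
                frames.append([(0.5 * f, 5.0)])
        params = LinkingParams(max_gap=2)
        raw = link_tracks(dets_from_path(frames), 7.0, params, min_track_frames=2)
        assert len(raw) == 2
        stitched = stitch_tracks(raw, 7.0, params)
        assert len(stitched) == 1
        assert stitched[0].n_points == n


class TestMotileCounting:
    def test_empty_mhi_counts_zero(self, motion_params):
        sc = scene(noise_sd=1.0)
        stack, _ = render_stack([static_track(10.0, 10.0)], sc)
        mhi = compute_mhi(stack)
        tracks = [static_track(10.0, 10.0)]
        assert count_motile_tracks(tracks, mhi, MotilityCriteria()) == 0

    def test_small_scene_counts_exact_motile_number(self, motion_params):
        sc = scene(w=640, h=480, n_motile=3, n_nonmotile=27, seed=2)
        crit = calibrate_motility_criteria(motion_params, seed=0)
        tracks = build_scene_tracks(sc, motion_params, 77, static_nonmotile=True, fixed_speed=10.6)
        stack, truth = render_stack(tracks, sc)
        res = track_stack(stack)
        assert res.n_first_frame_blobs == 30
        assert count_motile_tracks(res.tracks, res.mhi, crit) == truth.n_motile
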