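"""Detection, sub-pixel refinement, linking: conventions and bias structure."""

import numpy as np
import pytest

from spifftrack import (
    PlacementModel,
    PsfModel,
    RefinementError,
    TrackingConfig,
    build_meta_pixel,
    detect_candidates,
    identification_fraction,
    link_nearest,
    refine_centroid,
    refine_gaussian,
    render_frame,
    render_movie,
    sample_two_particle_positions,
    track_movie,
    uniformity_test,
)
from spifftrack.tracking import TrackedSet, Localization


def _single_spot(x, y, psf, shape=(24, 32), seed=None):
    return render_frame([(x, y)], psf, shape, seed=seed)


class TestDetectCandidates:
    def test_uniform_frame_yields_nothing(self):
        frame = np.full((16, 16), 7.0)
        assert detect_candidates(frame, TrackingConfig()) == []

    def test_single_spot_gives_one_candidate_at_peak(self, default_psf):
        frame = _single_spot(15.5, 11.5, default_psf, seed=1)
        cands = detect_candidates(frame, TrackingConfig())
        assert len(cands) == 1
        assert cands[0] == (15, 11)

    def test_close_pair_pruned_to_brighter(self, noiseless_psf):
        bright = PsfModel(amplitude=80.0, background_sd=0.0, shot_noise=False)
        frame = render_frame([(10.5, 10.5)], bright, (24, 24)) + render_frame(
            [(12.5, 10.5)], noiseless_psf, (24, 24)
        )
        cfg = TrackingConfig(radius_px=1, min_separation_px=4.0)
        cands = detect_candidates(frame, cfg)
        assert cands == [(10, 10)]

    def test_max_candidates_keeps_brightest(self, noiseless_psf):
        bright = PsfModel(amplitude=80.0, background_sd=0.0, shot_noise=False)
        frame = render_frame([(8.5, 8.5)], bright, (24, 32)) + render_frame(
            [(20.5, 12.5)], noiseless_psf, (24, 32)
        )
        cfg = TrackingConfig(max_candidates=1)
        assert detect_candidates(frame, cfg) == [(8, 8)]


class TestRefineCentroid:
    def test_delta_spot_localizes_at_pixel_center(self):
        frame = np.zeros((16, 16))
        frame[3, 7] = 5.0  # (x=7, y=3)
        for radius in (1, 2, 3):
            loc = refine_centroid(frame, (7, 3), radius)
            assert (loc.x_px, loc.y_px) == (7.5, 3.5)

    def test_symmetric_cross_is_centered(self):
        frame = np.zeros((11, 11))
        frame[5, 5] = 4.0
        frame[5, 4] = frame[5, 6] = frame[4, 5] = frame[6, 5] = 1.0
        loc = refine_centroid(frame, (5, 5), 1)
        assert (loc.x_px, loc.y_px) == (5.5, 5.5)

    def test_zero_mass_window_raises(self):
        with pytest.raises(RefinementError, match="zero net intensity"):
            refine_centroid(np.full((9, 9), 3.0), (4, 4), 1)

    def test_window_crossing_edge_raises(self):
        with pytest.raises(RefinementError, match="edge"):
            refine_centroid(np.ones((9, 9)), (0, 4), 2)

    def test_small_window_bias_exceeds_large_window_bias(self, noiseless_psf):
        """Noiseless truncation bias: the centroid over a small window pulls
        toward the window center, and the pull shrinks as R grows."""
        offsets = np.linspace(0.05, 0.95, 19)
        errors = {}
        for radius in (1, 3):
            errs = []
            for off in offsets:
                frame = _single_spot(15 + off, 12.5, noiseless_psf)
                cand = (15 if off < 1 else 16, 12)
                loc = refine_centroid(frame, cand, radius)
                errs.append(abs(loc.x_px - (15 + off)))
            errors[radius] = np.mean(errs)
        assert errors[1] > errors[3]
        assert errors[1] > 0.02  # R=1 truncation bias is well above float noise


class TestRefineGaussian:
    def test_noiseless_spot_recovered_with_large_window(self, noiseless_psf):
        frame = _single_spot(15.3, 12.8, noiseless_psf)
        loc = refine_gaussian(frame, (15, 12), 5)
        assert loc.x_px == pytest.approx(15.3, abs=1e-3)
        assert loc.y_px == pytest.approx(12.8, abs=1e-3)
        assert not loc.fallback

    def test_pixel_center_spot_is_exact_for_both_refiners(self, noiseless_psf):
        frame = _single_spot(15.5, 12.5, noiseless_psf)
        for refiner in (refine_centroid, refine_gaussian):
            loc = refiner(frame, (15, 12), 3)
            assert loc.x_px == pytest.approx(15.5, abs=1e-6)
            assert loc.y_px == pytest.approx(12.5, abs=1e-6)

    def test_small_window_locks_under_noise(self, default_psf):
        """With noise, R=1 estimates are biased toward pixel centers while
        R=3 estimates are not: fractional parts pile up around 0.5."""
        rng = np.random.default_rng(6)
        n = 300
        xs, ys = 15 + rng.uniform(0, 1, n), 12 + rng.uniform(0, 1, n)
        mean_dev = {}
        for radius in (1, 3):
            fracs = []
            for i in range(n):
                frame = _single_spot(xs[i], ys[i], default_psf, seed=i)
                cand = detect_candidates(frame, TrackingConfig(radius_px=radius))[0]
                loc = refine_gaussian(frame, cand, radius)
                fracs.append(loc.x_px - np.floor(loc.x_px))
            # mean absolute deviation of fractional parts from the pixel
            # center; 0.25 for uniform, smaller when locked
            mean_dev[radius] = np.mean(np.abs(np.array(fracs) - 0.5))
        assert mean_dev[1] < mean_dev[3]
        assert mean_dev[1] < 0.22

    def test_flat_window_falls_back_or_fails(self):
        frame = np.full((11, 11), 50.0)
        with pytest.raises(RefinementError):
            refine_gaussian(frame, (5, 5), 2)

    def test_needs_five_pixels(self):
        # radius accepted by the API starts at 1 = 5 pixels; direct check
        frame = np.ones((11, 11))
        with pytest.raises(RefinementError):
            refine_gaussian(frame, (0, 5), 1)  # edge -> window incomplete


class TestRoundTrip:
    def test_tracking_inverts_rendering_for_isolated_spots(self, noiseless_psf):
        """With a generous window and no noise, render -> track is the
        identity to better than 10^-2 px."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = 12 + rng.uniform(0, 8)
            y = 10 + rng.uniform(0, 4)
            frame = _single_spot(x, y, noiseless_psf)
            cand = detect_candidates(frame, TrackingConfig(radius_px=4))[0]
            loc = refine_gaussian(frame, cand, 4)
            assert np.hypot(loc.x_px - x, loc.y_px - y) < 1e-2


class TestTrackMovie:
    def test_empty_frames_give_zero_counts(self):
        frames = np.full((5, 16, 16), 10.0)
        tracked = track_movie(frames, TrackingConfig())
        np.testing.assert_array_equal(tracked.counts, 0)

    def test_single_particle_found_in_most_frames(self, default_psf):
        truth = sample_two_particle_positions(
            100, PlacementModel(anchor_pixel=(10, 11), sigma_x_px=1e-9,
                                sigma_y_px=1e-9), seed=0
        )
        # keep only the anchored particle
        frames = [
            render_frame(truth.positions[i, :1], default_psf, (24, 32), seed=i)
            for i in range(100)
        ]
        tracked = track_movie(frames, TrackingConfig(radius_px=2))
        assert np.mean(tracked.counts >= 1) >= 0.95

    def test_counts_equal_localization_list_lengths(self, default_psf):
        truth = sample_two_particle_positions(20, PlacementModel(anchor_pixel=(10, 11)), 3)
        frames = list(render_movie(truth, default_psf, (24, 32), seed=4))
        tracked = track_movie(frames, TrackingConfig(radius_px=1))
        assert all(len(f) == c for f, c in zip(tracked.frames, tracked.counts))


class TestIdentificationFraction:
    def test_all_frames_at_expected_count(self):
        loc = Localization(0, 1.0, 1.0, 1.0, 1)
        tracked = TrackedSet([[loc], [loc], [loc]])
        assert identification_fraction(tracked, 1) == 1.0
        assert identification_fraction(tracked, 2) == 0.0

    def test_rejects_nonpositive_expectation(self):
        with pytest.raises(ValueError):
            identification_fraction(TrackedSet([[]]), 0)


class TestLinkNearest:
    @staticmethod
    def _tracked_from_positions(per_frame):
        frames = []
        for fi, pts in enumerate(per_frame):
            frames.append(
                [Localization(fi, x, y, 1.0, 1) for x, y in pts]
            )
        return TrackedSet(frames)

    def test_single_particle_yields_single_full_trajectory(self):
        tracked = self._tracked_from_positions(
            [[(5.0 + 0.1 * i, 7.0)] for i in range(10)]
        )
        trajs = link_nearest(tracked, max_step_px=1.0)
        assert len(trajs) == 1
        assert trajs[0].n_frames == 10

    def test_two_stationary_particles_never_swap(self):
        tracked = self._tracked_from_positions(
            [[(5.0, 5.0), (15.0, 5.0)] for _ in range(20)]
        )
        trajs = link_nearest(tracked, max_step_px=2.0)
        assert len(trajs) == 2
        for traj in trajs:
            assert np.ptp(traj.positions[:, 0]) == 0.0

    def test_long_jump_splits_trajectory(self):
        tracked = self._tracked_from_positions(
            [[(5.0, 5.0)], [(5.1, 5.0)], [(12.0, 5.0)], [(12.1, 5.0)]]
        )
        trajs = link_nearest(tracked, max_step_px=1.0)
        assert len(trajs) == 2
        assert [t.start_frame for t in trajs] == [0, 2]


class TestMetaPixelSignature:
    def test_small_window_centroid_meta_pixel_is_nonuniform(self, default_psf):
        """Uniformly placed spots tracked with R=1 produce a measurably
        compressed meta-pixel (the pixel-locking signature)."""
        rng = np.random.default_rng(8)
        n = 10_000
        xs = 15 + rng.uniform(0, 1, n)
        ys = 12 + rng.uniform(0, 1, n)
        fracs = []
        for i in range(n):
            frame = _single_spot(xs[i], ys[i], default_psf, seed=i)
            cands = detect_candidates(
                frame, TrackingConfig(radius_px=1, max_candidates=1)
            )
            if not cands:
                continue
            try:
                loc = refine_centroid(frame, cands[0], 1)
            except RefinementError:
                continue
            fracs.append((loc.x_px, loc.y_px))
        mp = build_meta_pixel(np.array(fracs))
        report = uniformity_test(mp)
        assert report.locked
        assert report.p_x < 1e-3
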