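"""Fusion detection, release-duration recovery, residence taxonomy, linking."""

import warnings

import numpy as np
import pytest
from scipy import stats

from tirfpuncta import detection, event_kinetics as ek, synthetic_data as sd
from tirfpuncta.detection import PunctumDetection
from tirfpuncta.fluorometry import FluorescenceTrace, RoiSpec

from conftest import match_ground_truth


def make_trace(values, dt=0.1):
    v = np.asarray(values, dtype=float)
    return FluorescenceTrace(roi=RoiSpec(10, 10), delta_f=v,
                             time_s=np.arange(len(v)) * dt)


def make_track(frames, xs, ys):
    t = ek.Track()
    for f, x, y in zip(frames, xs, ys):
        t.append(f, x, y)
    return t


class TestReleaseDuration:
    def test_step_trace_single_frame_release(self, thresholds):
        tr = make_trace([80.0] * 10 + [0.0] * 30)
        m = ek.release_duration(tr, thresholds, background_level=0.0,
                                background_sd=1.0)
        assert m.status == "ok"
        assert m.time0_frame == 9
        assert m.end_frame == 10
        assert m.duration_s == pytest.approx(0.1)

    def test_linear_ramp_recovers_duration(self, thresholds):
        ramp = [80.0] * 20 + list(80 * (1 - np.arange(1, 46) / 45)) + [0.0] * 20
        m = ek.release_duration(make_trace(ramp), thresholds, 0.0, 1.0)
        assert m.status == "ok"
        assert m.duration_s == pytest.approx(4.5, abs=0.1)  # ± 1 frame

    def test_constant_trace_is_no_release(self, thresholds):
        m = ek.release_duration(make_trace([50.0] * 60), thresholds, 0.0, 1.0)
        assert m.status == "no_release"

    def test_truncated_decay_is_incomplete(self, thresholds):
        cut = [80.0] * 20 + list(80 * (1 - np.arange(1, 36) / 40))
        m = ek.release_duration(make_trace(cut), thresholds, 0.0, 1.0)
        assert m.status == "incomplete_decay"

    def test_transient_dip_with_recovery_is_no_release(self, thresholds):
        vals = [80.0] * 20 + [40.0, 78.0] + [80.0] * 20
        m = ek.release_duration(make_trace(vals), thresholds, 0.0, 1.0)
        assert m.status == "no_release"


class TestClassifyResidence:
    dt = 0.1
    ps = 0.16

    def classify(self, track, n_frames, thresholds):
        return ek.classify_residence(track, n_frames, thresholds,
                                     self.dt, self.ps)

    def test_full_movie_confined_track_is_docking(self, thresholds):
        t = make_track(range(400), [50.0] * 400, [50.0] * 400)
        ev = self.classify(t, 400, thresholds)
        assert ev.event_class == "docking"
        assert ev.disappear_frame == ek.MOVIE_EDGE

    def test_appearing_then_confined_to_end_is_docking(self, thresholds):
        t = make_track(range(100, 400), [50.0] * 300, [50.0] * 300)
        assert self.classify(t, 400, thresholds).event_class == "docking"

    def test_present_at_start_then_leaving_is_undocking(self, thresholds):
        t = make_track(range(0, 60), [50.0] * 60, [50.0] * 60)
        ev = self.classify(t, 400, thresholds)
        assert ev.event_class == "undocking"
        assert ev.disappear_frame == 60

    def test_forty_five_frame_mid_movie_residence_is_dock_and_undock(
            self, thresholds):
        t = make_track(range(50, 95), [50.0] * 45, [50.0] * 45)
        ev = self.classify(t, 400, thresholds)
        assert ev.event_class == "dock_and_undock"
        assert ev.residence_s == pytest.approx(4.5)

    def test_exactly_threshold_frames_is_docked_side(self, thresholds):
        t = make_track(range(50, 90), [50.0] * 40, [50.0] * 40)
        assert self.classify(t, 400, thresholds).event_class == \
            "dock_and_undock"

    def test_short_residence_is_visiting(self, thresholds):
        t = make_track(range(50, 60), [50.0] * 10, [50.0] * 10)
        ev = self.classify(t, 400, thresholds)
        assert ev.event_class == "visiting"
        assert ev.residence_s == pytest.approx(1.0)

    def test_below_minimum_visit_is_discarded(self, thresholds):
        t = make_track(range(50, 53), [50.0] * 3, [50.0] * 3)
        assert self.classify(t, 400, thresholds) is None

    def test_long_unconfined_track_unclassified(self, thresholds):
        xs = 50.0 + np.arange(60) * 0.5  # walks 30 px = 4.8 µm
        t = make_track(range(50, 110), xs, [50.0] * 60)
        assert self.classify(t, 400, thresholds) is None

    def test_empty_track_raises(self, thresholds):
        with pytest.raises(ValueError):
            self.classify(ek.Track(), 400, thresholds)


class TestLinkTracks:
    def det(self, frame, x, y):
        return PunctumDetection(frame, x, y, 100.0, 50.0)

    def test_immobile_punctum_one_track(self):
        dets = [[self.det(f, 20, 20)] for f in range(100)]
        tracks = ek.link_tracks(dets, 0.3, 0.16)
        assert len(tracks) == 1
        assert tracks[0].n_points == 100

    def test_distant_puncta_never_merge(self):
        sep_px = int(3.0 / 0.16)
        dets = [[self.det(f, 20, 20), self.det(f, 20 + sep_px, 20)]
                for f in range(50)]
        tracks = ek.link_tracks(dets, 0.5, 0.16)
        assert len(tracks) == 2
        assert all(t.n_points == 50 for t in tracks)

    def test_single_frame_gap_is_closed(self):
        dets = [[self.det(f, 20, 20)] if f != 25 else []
                for f in range(50)]
        tracks = ek.link_tracks(dets, 0.3, 0.16)
        assert len(tracks) == 1
        assert tracks[0].n_points == 49

    def test_visiting_steps_follow_rayleigh_law(self, thresholds):
        """Per-frame displacements of linked mobile puncta match the
        generating isotropic random walk, observed through the same
        integer-pixel snapping the detector applies (two-sample KS against a
        snapped Gaussian-walk oracle)."""
        mobility = 0.05
        cfg = sd.SimulationConfig(n_frames=360, noise_sd=0.0, seed=14)
        cfg.events = sd.schedule_random_events(
            cfg, {"visiting": 10},
            mobility_sd_um={"visiting": mobility}, seed=15)
        movie, _, _ = sd.render_movie(cfg)
        # prominence above the cell-baseline step so only puncta qualify
        dets = detection.detect_movie(movie, prominence=50.0)
        tracks = ek.link_tracks(dets, max_step_um=0.4,
                                pixel_size=movie.pixel_size)
        steps = np.concatenate([t.steps_um(movie.pixel_size)
                                for t in tracks if t.n_points > 5])
        assert steps.size > 100
        # oracle: many short continuous walks, each starting on a pixel
        # center like a scheduled event, snapped to the pixel lattice
        rng = np.random.default_rng(99)
        lengths = [t.n_points for t in tracks if t.n_points > 5]
        oracle = []
        for _ in range(500):
            m = lengths[int(rng.integers(0, len(lengths)))]
            walk = np.cumsum(
                rng.normal(0, mobility / movie.pixel_size, size=(m, 2)),
                axis=0)
            oracle.append(np.hypot(*np.diff(np.rint(walk), axis=0).T))
        oracle = np.concatenate(oracle) * movie.pixel_size
        ks = stats.ks_2samp(steps, oracle)
        assert ks.pvalue > 0.01


class TestFusionDetection:
    def test_all_fast_events_recovered_with_matched_positions(
            self, fast_fusion_run):
        run = fast_fusion_run
        assert len(run["events"]) == len(run["log"]) == 10
        for ev in run["events"]:
            gt, dist = match_ground_truth(ev, run["log"])
            assert dist <= 1.0
            assert abs(ev.fusion_time0_frame - gt.disappear_frame) <= 1

    def test_fast_durations_within_one_frame(self, fast_fusion_run):
        run = fast_fusion_run
        for ev in run["events"]:
            gt, _ = match_ground_truth(ev, run["log"])
            assert ev.release_duration_s == pytest.approx(
                gt.release_duration_s, abs=0.3)

    def test_slow_durations_recovered(self, slow_fusion_run):
        run = slow_fusion_run
        assert len(run["events"]) == 10
        for ev in run["events"]:
            gt, _ = match_ground_truth(ev, run["log"])
            assert ev.release_duration_s == pytest.approx(
                gt.release_duration_s, abs=0.8)

    def test_no_fusions_reported_on_docking_visiting_movie(self, thresholds):
        cfg = sd.SimulationConfig(n_frames=200, noise_sd=10.0, seed=5)
        cfg.events = sd.schedule_random_events(
            cfg, {"docking": 6, "visiting": 8}, seed=6)
        movie, mask, _ = sd.render_movie(cfg)
        dets = detection.detect_movie(movie)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ek.detect_fusion_events(movie, dets, mask, thresholds, 0)
        assert events == []

    def test_reappearing_punctum_is_not_fusion(self, thresholds):
        """A punctum that vanishes but re-renders at the same site later
        violates the no-reappearance criterion."""
        cfg = sd.SimulationConfig(n_frames=200, noise_sd=5.0, seed=2)
        # same site occupied twice: 60-frame dock, 20 dark frames, redock
        cfg.events = [
            sd.EventSpec("dock_and_undock", 128.0, 128.0, appear_frame=2,
                         residence_frames=60),
            sd.EventSpec("docking", 128.0, 128.0, appear_frame=82,
                         residence_frames=118),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            movie, mask, _ = sd.render_movie(cfg)
            dets = detection.detect_movie(movie)
            events = ek.detect_fusion_events(movie, dets, mask, thresholds, 0)
        assert events == []

    def test_movie_without_events_gives_empty_list(self, thresholds):
        cfg = sd.SimulationConfig(n_frames=60, noise_sd=5.0, seed=1)
        movie, mask, _ = sd.render_movie(cfg)
        dets = detection.detect_movie(movie)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert ek.detect_fusion_events(movie, dets, mask,
                                           thresholds, 0) == []


class TestBehaviourRecovery:
    def test_confusion_matrix_is_diagonal(self, behaviour_run, thresholds):
        """On noise-free movies with safety margins from the thresholds,
        every scheduled event is recovered with its true class."""
        run = behaviour_run
        movie = run["movie"]
        events = []
        for t in run["tracks"]:
            ev = ek.classify_residence(t, movie.n_frames, thresholds,
                                       movie.frame_interval, movie.pixel_size)
            if ev is not None:
                events.append(ev)
        got = {}
        for ev in events:
            got[ev.event_class] = got.get(ev.event_class, 0) + 1
        truth = run["log"].event_class.value_counts().to_dict()
        assert got == truth
        # and each classified event sits on a true event of the same class
        for ev in events:
            gt, dist = match_ground_truth(ev, run["log"])
            assert dist <= 1.0
            assert gt.event_class == ev.event_class

    def test_docked_class_count_conserved(self, behaviour_run, thresholds):
        run = behaviour_run
        movie = run["movie"]
        n_docked = 0
        for t in run["tracks"]:
            ev = ek.classify_residence(t, movie.n_frames, thresholds,
                                       movie.frame_interval, movie.pixel_size)
            if ev and ev.event_class in ("docking", "dock_and_undock"):
                n_docked += 1
        truth = run["log"].event_class.isin(
            ["docking", "dock_and_undock"]).sum()
        assert n_docked == truth


class TestEventRateHistogram:
    def test_no_events_all_bins_zero(self):
        h = ek.event_rate_histogram([], stimulation_frame=100,
                                    frame_interval=0.1, bin_s=5.0,
                                    mask_area_um2=80.0)
        assert h.counts.sum() == 0
        assert h.density_per_um2 == 0.0

    def test_density_and_rate_arithmetic(self):
        roi = RoiSpec(10, 10)
        events = [ek.KineticEvent("fusion", roi, 0, 50, 5.0,
                                  fusion_time0_frame=110 + i,
                                  release_end_frame=115 + i,
                                  release_duration_s=0.5)
                  for i in range(8)]
        h = ek.event_rate_histogram(events, stimulation_frame=100,
                                    frame_interval=0.1, bin_s=10.0,
                                    mask_area_um2=80.0, total_time_s=60.0)
        assert h.density_per_um2 == pytest.approx(8 / 80.0)
        assert h.rate_per_min == pytest.approx(8.0)
        assert h.counts[0] == 8  # all onsets within 10 s of stimulation

    def test_post_stimulation_fraction_recovered(self, fast_fusion_run):
        run = fast_fusion_run
        movie = run["movie"]
        h = ek.event_rate_histogram(run["events"], stimulation_frame=0,
                                    frame_interval=movie.frame_interval,
                                    bin_s=10.0,
                                    mask_area_um2=run["mask"].area_um2)
        assert h.counts.sum() == len(run["events"])


def test_threshold_consistency_warning():
    thr = ek.KineticThresholds()
    with pytest.warns(UserWarning, match="frame count takes precedence"):
        thr.check_frame_interval(0.1)
    # at the implied behavioural frame interval the pairing is consistent
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        thr.check_frame_interval(0.148)


def test_min_visit_frames_derivation():
    thr = ek.KineticThresholds()
    assert thr.min_visit_frames(0.1) == 6
    assert thr.min_visit_frames(0.148) == 4
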