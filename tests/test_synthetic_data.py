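"""Generator contracts: exact rendering, determinism, schedules, logs."""

import numpy as np
import pytest

from tirfpuncta import spatial, synthetic_data as sd


def make_config(**kw):
    base = dict(image_shape=(128, 128), pixel_size=0.16, frame_interval=0.1,
                n_frames=30, noise_sd=0.0, cell_baseline=0.0,
                background_level=10.0, punctum_amplitude=100.0,
                cell_semi_axes_um=(8.0, 6.0), seed=0)
    base.update(kw)
    return sd.SimulationConfig(**base)


def test_empty_scene_is_flat_background():
    movie, mask, log = sd.render_movie(make_config())
    assert np.all(movie.data == 10.0)
    assert len(log) == 0
    assert mask.mask.any()


def test_docking_event_peak_equals_background_plus_amplitude():
    ev = sd.EventSpec("docking", x_px=64.0, y_px=64.0, appear_frame=5,
                      residence_frames=40)
    movie, mask, log = sd.render_movie(make_config(events=[ev]))
    frame = movie.data[5]
    assert frame.max() == pytest.approx(110.0, abs=1e-9)
    assert np.unravel_index(frame.argmax(), frame.shape) == (64, 64)
    # absent before appearance
    assert movie.data[4].max() == pytest.approx(10.0)


def test_fast_fusion_disappears_within_single_frame():
    ev = sd.EventSpec("fusion_fast", x_px=64.0, y_px=64.0, appear_frame=2,
                      residence_frames=10, release_duration_s=0.1)
    movie, _, log = sd.render_movie(make_config(events=[ev], noise_sd=0.0))
    onset = int(log.disappear_frame.iloc[0])
    assert onset == 12
    assert movie.data[onset].max() == pytest.approx(110.0)
    assert movie.data[onset + 1].max() <= 10.0 + 3 * 1e-9


def test_slow_fusion_ramps_linearly():
    ev = sd.EventSpec("fusion_slow", x_px=64.0, y_px=64.0, appear_frame=2,
                      residence_frames=10, release_duration_s=1.0)
    movie, _, log = sd.render_movie(make_config(events=[ev]))
    onset = int(log.disappear_frame.iloc[0])
    peak = movie.data[:, 64, 64] - 10.0
    assert peak[onset] == pytest.approx(130.0)  # overshoot frame
    # halfway through the 1 s ramp the amplitude is half
    assert peak[onset + 5] == pytest.approx(50.0, rel=1e-6)
    assert peak[onset + 10] == pytest.approx(0.0, abs=1e-9)


def test_determinism_bit_identical():
    cfg1 = make_config(noise_sd=5.0, static_density=0.2)
    cfg2 = make_config(noise_sd=5.0, static_density=0.2)
    m1, _, l1 = sd.render_movie(cfg1)
    m2, _, l2 = sd.render_movie(cfg2)
    assert np.array_equal(m1.data, m2.data)
    assert l1.equals(l2)


def test_gaussian_integral_of_isolated_punctum():
    cfg = make_config()
    ev = sd.EventSpec("docking", x_px=64.0, y_px=64.0, appear_frame=0,
                      residence_frames=40)
    cfg.events = [ev]
    movie, _, _ = sd.render_movie(cfg)
    total = (movie.data[0] - 10.0).sum()
    expected = 100.0 * 2 * np.pi * cfg.psf_sigma_px**2
    assert total == pytest.approx(expected, rel=0.01)


def test_event_outside_footprint_rejected():
    ev = sd.EventSpec("docking", x_px=2.0, y_px=2.0, appear_frame=0,
                      residence_frames=40)
    with pytest.raises(ValueError, match="outside the cell footprint"):
        sd.render_movie(make_config(events=[ev]))


def test_overlapping_events_warn():
    evs = [
        sd.EventSpec("docking", x_px=64.0, y_px=64.0, appear_frame=0,
                     residence_frames=40),
        sd.EventSpec("docking", x_px=65.0, y_px=64.0, appear_frame=0,
                     residence_frames=40),
    ]
    with pytest.warns(UserWarning, match="confounded"):
        sd.render_movie(make_config(events=evs))


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="psf_sigma"):
        make_config(psf_sigma_um=0.05).validate()
    with pytest.raises(ValueError, match="ellipse"):
        make_config(cell_semi_axes_um=(50.0, 50.0)).validate()
    with pytest.raises(ValueError, match="visiting residence"):
        sd.EventSpec("visiting", 64.0, 64.0, 0, residence_frames=60).validate(
            100, 0.1)


class TestScheduleRandomEvents:
    def test_empty_request_gives_empty_list(self):
        assert sd.schedule_random_events(make_config(n_frames=200), {}) == []

    def test_counts_match_exactly_and_visitors_below_threshold(self):
        cfg = make_config(n_frames=300)
        evs = sd.schedule_random_events(
            cfg, {"visiting": 50}, seed=5, min_spacing_um=1.0,
            residence_samplers={"visiting":
                                lambda rng: int(rng.integers(4, 40))})
        assert len(evs) == 50
        assert all(e.residence_frames < 40 for e in evs)
        assert all(e.residence_frames >= 4 for e in evs)

    def test_seed_reproducibility(self):
        cfg = make_config(n_frames=300)
        a = sd.schedule_random_events(cfg, {"visiting": 5, "docking": 3},
                                      seed=2)
        b = sd.schedule_random_events(cfg, {"visiting": 5, "docking": 3},
                                      seed=2)
        assert a == b

    def test_rendered_event_count_per_class_conserved(self):
        cfg = make_config(n_frames=200, image_shape=(256, 256),
                          cell_semi_axes_um=(16.0, 12.0))
        counts = {"docking": 3, "visiting": 4, "fusion_fast": 2}
        cfg.events = sd.schedule_random_events(cfg, counts, seed=1)
        _, _, log = sd.render_movie(cfg)
        assert log.event_class.value_counts().to_dict() == counts

    def test_zone_labels_agree_with_spatial_classifier(self):
        cfg = make_config(n_frames=200, image_shape=(256, 256),
                          cell_semi_axes_um=(16.0, 12.0))
        cfg.events = sd.schedule_random_events(
            cfg, {"docking": 10, "visiting": 10},
            zone_fractions={"peripheral": 0.5, "non_peripheral": 0.5}, seed=4)
        _, mask, log = sd.render_movie(cfg)
        for row in log.itertuples():
            z = spatial.classify_zone(mask, row.x_px, row.y_px,
                                      cfg.zone_band_um)
            assert z.zone == row.zone
        # both zones actually represented
        assert set(log.zone) == {"peripheral", "non_peripheral"}

    def test_infeasible_placement_names_zone(self):
        cfg = make_config(n_frames=200)
        with pytest.raises(ValueError, match="peripheral"):
            sd.schedule_random_events(
                cfg, {"docking": 500},
                zone_fractions={"peripheral": 1.0},
                min_spacing_um=3.0, seed=0)


def test_condition_density_presets_positive_and_ordered():
    rng = np.random.default_rng(0)
    nd = sd.sample_condition_densities("CD63", "ND", 200, rng)
    t2d = sd.sample_condition_densities("CD63", "T2D", 200, rng)
    assert (nd > 0).all() and (t2d > 0).all()
    assert nd.mean() > t2d.mean()
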