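import warnings

import numpy as np
import pytest

from tirfpuncta import detection, event_kinetics, synthetic_data as sd


@pytest.fixture(scope="session")
def thresholds():
    return event_kinetics.KineticThresholds()


def _render(cls_counts, n_frames, noise_sd, seed, schedule_seed, **cfg_kwargs):
    cfg = sd.SimulationConfig(n_frames=n_frames, noise_sd=noise_sd,
                              punctum_amplitude=100.0, seed=seed, **cfg_kwargs)
    cfg.events = sd.schedule_random_events(cfg, cls_counts, seed=schedule_seed)
    return (cfg,) + sd.render_movie(cfg)


@pytest.fixture(scope="session")
def fast_fusion_run(thresholds):
    """SNR-10 movie with 10 fast (sub-second) fusion events, fully analysed."""
    cfg, movie, mask, log = _render({"fusion_fast": 10}, 200, 10.0, 7, 3)
    dets = detection.detect_movie(movie)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        events = event_kinetics.detect_fusion_events(
            movie, dets, mask, thresholds, stimulation_frame=0)
    return dict(cfg=cfg, movie=movie, mask=mask, log=log, dets=dets,
                events=events)


@pytest.fixture(scope="session")
def slow_fusion_run(thresholds):
    """SNR-10 movie with 10 slow (multi-second) fusion events, analysed."""
    cfg, movie, mask, log = _render({"fusion_slow": 10}, 250, 10.0, 11, 12)
    dets = detection.detect_movie(movie)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        events = event_kinetics.detect_fusion_events(
            movie, dets, mask, thresholds, stimulation_frame=0)
    return dict(cfg=cfg, movie=movie, mask=mask, log=log, dets=dets,
                events=events)


@pytest.fixture(scope="session")
def behaviour_run(thresholds):
    """Noise-free 400-frame movie with all four residence classes."""
    cfg, movie, mask, log = _render(
        {"docking": 5, "undocking": 5, "dock_and_undock": 5, "visiting": 8},
        400, 0.0, 9, 10)
    # prominence above the cell-baseline step so only puncta qualify
    dets = detection.detect_movie(movie, prominence=50.0)
    tracks = event_kinetics.link_tracks(
        dets, thresholds.confinement_radius_um, movie.pixel_size)
    return dict(cfg=cfg, movie=movie, mask=mask, log=log, dets=dets,
                tracks=tracks)


def match_ground_truth(event, log):
    """Nearest ground-truth row for a detected event's ROI position."""
    d = np.hypot(log.x_px - event.roi.center_x_px,
                 log.y_px - event.roi.center_y_px)
    return log.iloc[int(d.idxmin())], float(d.min())
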