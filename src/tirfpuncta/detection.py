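"""Punctum detection by prominence-thresholded local maxima, and densities.

A punctum is a local intensity maximum standing at least ``prominence``
counts above the saddle that connects it to any brighter region — the same
"noise tolerance" notion as ImageJ's find-maxima.  Maxima are located with a
morphological h-maxima transform (greyscale reconstruction), which computes
the saddle criterion exactly; plateau maxima are reduced to their top-left
pixel, and detections closer than a minimum separation are merged keeping
the brighter one.  Exact flood-fill equivalence with ImageJ is not promised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import reconstruction

from .image_io import CellMask, TimeLapseMovie

DEFAULT_MIN_SEPARATION_PX = 3.0


@dataclass(frozen=True)
class PunctumDetection:
    frame: int
    x_px: int
    y_px: int
    peak_intensity: float
    prominence: float


@dataclass(frozen=True)
class DensityResult:
    n_puncta: int
    area_um2: float
    density_per_um2: float


def robust_noise_sd(image: np.ndarray) -> float:
    """Robust pixel-noise sd via the MAD of horizontal first differences.

    Differencing neighbouring pixels cancels flat structure (cell baseline,
    background steps), so the estimate tracks the noise rather than the
    scene; the √2 accounts for differencing two independent noise samples.
    """
    image = np.asarray(image, dtype=float)
    d = np.diff(image, axis=1).ravel()
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def auto_prominence(image: np.ndarray, factor: float = 5.0) -> float:
    """Default detection prominence: ``factor`` × robust noise sd."""
    sd = robust_noise_sd(image)
    return max(factor * sd, 1e-6)


def auto_prominence_movie(movie: TimeLapseMovie, factor: float = 5.0) -> float:
    """Movie-level default prominence.

    With two or more frames the noise is estimated from the frame-to-frame
    difference of the first two frames, which cancels all static structure
    (puncta included) and so stays accurate even in dense scenes; a 1-frame
    movie falls back to the spatial estimate.
    """
    if movie.n_frames >= 2:
        d = (movie.data[1] - movie.data[0]).ravel()
        sd = float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))
        return max(factor * sd, 1e-6)
    return auto_prominence(movie.data[0], factor)


def find_maxima(
    frame_image: np.ndarray,
    prominence: float,
    min_separation: float = DEFAULT_MIN_SEPARATION_PX,
    frame: int = 0,
) -> list[PunctumDetection]:
    """Detect local maxima with height-above-saddle of at least ``prominence``.

    Returns an empty list when nothing qualifies (flat images included).
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    img = np.asarray(frame_image, dtype=float)
    if np.ptp(img) < prominence:
        return []
    # h-maxima: pixels where the h-dome (image minus its reconstruction from
    # image - h) reaches h are regional maxima of dynamics >= h
    seed = img - prominence
    rec = reconstruction(seed, img, method="dilation")
    dome = img - rec
    peaks_mask = dome >= prominence - 1e-9
    if not peaks_mask.any():
        return []
    from scipy import ndimage

    labels, n = ndimage.label(peaks_mask)
    detections: list[PunctumDetection] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        vals = img[ys, xs]
        best = int(np.argmax(vals))  # row-major ties resolve top-left-most
        detections.append(PunctumDetection(
            frame=frame,
            x_px=int(xs[best]),
            y_px=int(ys[best]),
            peak_intensity=float(vals[best]),
            prominence=float(dome[ys[best], xs[best]]),
        ))
    return _merge_close(detections, min_separation)


def _merge_close(detections: list[PunctumDetection],
                 min_separation: float) -> list[PunctumDetection]:
    """Merge detections within ``min_separation`` px, keeping the brighter."""
    if min_separation <= 0 or len(detections) < 2:
        return sorted(detections, key=lambda d: (d.y_px, d.x_px))
    order = sorted(detections,
                   key=lambda d: (-d.peak_intensity, d.y_px, d.x_px))
    kept: list[PunctumDetection] = []
    for d in order:
        ok = all(math.hypot(d.x_px - k.x_px, d.y_px - k.y_px) >= min_separation
                 for k in kept)
        if ok:
            kept.append(d)
    return sorted(kept, key=lambda d: (d.y_px, d.x_px))


def detect_movie(
    movie: TimeLapseMovie,
    prominence: float | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION_PX,
) -> list[list[PunctumDetection]]:
    """Per-frame detection over the whole movie.

    With ``prominence=None`` the threshold is fixed once from the movie's
    noise level (5 × robust noise sd) and reused for every frame, so
    detection counts are comparable across frames.
    """
    if prominence is None:
        prominence = auto_prominence_movie(movie)
    return [find_maxima(movie.data[f], prominence, min_separation, frame=f)
            for f in range(movie.n_frames)]


def puncta_density(
    movie: TimeLapseMovie,
    mask: CellMask,
    frame: int = 0,
    prominence: float | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION_PX,
) -> DensityResult:
    """Puncta count inside the mask on one frame, normalized to cell area."""
    if not (0 <= frame < movie.n_frames):
        raise ValueError("frame index out of range")
    area = mask.area_um2
    if area <= 0:
        raise ValueError("mask has zero area")
    img = movie.data[frame]
    if prominence is None:
        prominence = auto_prominence_movie(movie)
    dets = find_maxima(img, prominence, min_separation, frame=frame)
    inside = [d for d in dets if mask.mask[d.y_px, d.x_px]]
    return DensityResult(n_puncta=len(inside), area_um2=area,
                         density_per_um2=len(inside) / area)


def mean_spot_intensity(
    movie: TimeLapseMovie,
    mask: CellMask,
    prominence: float | None = None,
    frame: int = 0,
    min_separation: float = DEFAULT_MIN_SEPARATION_PX,
) -> float:
    """Mean peak intensity of in-mask detections on one frame.

    Returns NaN (with a warning) when nothing is detected.
    """
    img = movie.data[frame]
    if prominence is None:
        prominence = auto_prominence_movie(movie)
    dets = find_maxima(img, prominence, min_separation, frame=frame)
    inside = [d for d in dets if mask.mask[d.y_px, d.x_px]]
    if not inside:
        warnings.warn("no detections inside mask; mean spot intensity undefined")
        return float("nan")
    return float(np.mean([d.peak_intensity for d in inside]))
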