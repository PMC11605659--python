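"""Calibrated movie / mask containers and file round-trips.

Movies are plain (T, Y, X) intensity arrays carrying their spatial and
temporal calibration.  Calibration is never guessed from file metadata:
the caller must supply pixel size (µm/pixel) and frame interval (s/frame)
explicitly, mirroring how acquisition settings are recorded in a lab
notebook rather than trusted from TIFF tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class TimeLapseMovie:
    """A calibrated single-channel time-lapse stack.

    Parameters
    ----------
    data
        Intensity array of shape (T, Y, X), nonnegative.
    pixel_size
        µm per pixel (isotropic).
    frame_interval
        Seconds per frame.
    channel_label
        Free-text channel name (e.g. fluorophore).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"movie must be (T, Y, X); got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 (µm/pixel)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 (s/frame)")
        if np.nanmin(self.data) < 0:
            raise ValueError("movie intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class CellMask:
    """Binary cell footprint with area and boundary-distance map.

    ``boundary_distance`` holds, for every pixel, the Euclidean distance (µm)
    to the nearest background pixel: zero outside the mask, strictly positive
    inside.  A mask pixel touching background is one pixel step away, so a
    band of N pixels from the border corresponds to distance ≤ N × pixel_size.
    """

    mask: np.ndarray
    pixel_size: float
    boundary_distance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.mask.any():
            raise ValueError("mask is empty: no foreground")
        self.boundary_distance = (
            ndimage.distance_transform_edt(self.mask) * self.pixel_size
        )

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    def contains(self, x_px: float, y_px: float) -> bool:
        iy, ix = int(round(y_px)), int(round(x_px))
        if not (0 <= iy < self.mask.shape[0] and 0 <= ix < self.mask.shape[1]):
            return False
        return bool(self.mask[iy, ix])

    def distance_at(self, x_px: float, y_px: float) -> float:
        """Boundary distance (µm) at a pixel position, nearest-pixel lookup."""
        iy, ix = int(round(y_px)), int(round(x_px))
        return float(self.boundary_distance[iy, ix])


def load_movie(
    path: str | Path,
    pixel_size: float,
    frame_interval: float,
    channel_label: str = "",
) -> TimeLapseMovie:
    """Read a (multi-page) TIFF stack as a calibrated movie.

    Calibration must be passed explicitly; a missing or nonpositive value
    raises rather than being guessed from metadata.
    """
    if pixel_size is None or frame_interval is None:
        raise ValueError("pixel_size and frame_interval are required")
    data = tifffile.imread(str(path))
    return TimeLapseMovie(
        data=data,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_label=channel_label,
    )


def save_movie(movie: TimeLapseMovie, path: str | Path) -> None:
    """Write a movie as multi-page 16-bit TIFF (values rounded and clipped)."""
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    # photometric stated explicitly so short stacks (T <= 4) are not
    # misread as multi-sample RGB planes
    tifffile.imwrite(str(path), data, photometric="minisblack")


def load_mask(path: str | Path, pixel_size: float) -> CellMask:
    """Read a binary mask from single-page TIFF or PNG (any nonzero = inside)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
        if arr.ndim == 3:  # collapse RGB(A)
            arr = arr[..., 0]
    return CellMask(mask=arr > 0, pixel_size=pixel_size)


def save_mask(mask: CellMask, path: str | Path) -> None:
    """Write the footprint as single-page 8-bit TIFF (255 inside, 0 outside)."""
    tifffile.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def segment_cell(
    movie: TimeLapseMovie,
    threshold: float | None = None,
) -> CellMask:
    """Segment the cell footprint from the temporal median projection.

    The median projection suppresses transient puncta (visitors, fusions)
    while keeping the steady cytosolic fluorescence of the footprint.  The
    projection is thresholded (Otsu by default, or a manual value), the
    largest connected component is kept, and holes are filled.  Being
    histogram-shape based, the default threshold is invariant to additive
    intensity offsets.
    """
    proj = np.median(movie.data, axis=0)
    if np.ptp(proj) == 0:
        raise ValueError("no foreground: median projection is constant")
    thr = threshold_otsu(proj) if threshold is None else threshold
    binary = proj > thr
    if not binary.any():
        raise ValueError("no foreground above threshold")
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    footprint = ndimage.binary_fill_holes(labels == largest)
    return CellMask(mask=footprint, pixel_size=movie.pixel_size)


# ---------------------------------------------------------------------------
# Tabular / config round-trips

CSV_HEADER_COMMENT = (
    "# frame indices 0-based; times in seconds; positions in pixels (x=col, y=row)\n"
)


def write_table(df, path: str | Path) -> None:
    """Write an event/detection table as UTF-8 CSV with a units header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(CSV_HEADER_COMMENT)
        df.to_csv(fh, index=False)


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, comment="#")


def load_yaml(path: str | Path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path: str | Path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
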