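"""Movie container and TIFF / CSV plumbing.

TIFF metadata for physical calibration is unreliable across acquisition
software, so pixel size and frame interval always travel alongside the pixel
data and must be supplied explicitly when reading a stack.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class Movie:
    """A (time x row x column) intensity stack with physical calibration.

    Attributes
    ----------
    data:
        Intensity array of shape ``(n_frames, n_rows, n_cols)``.
    pixel_size_um:
        Lateral pixel size in micrometres per pixel.
    frame_interval_s:
        Time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (time, row, col)")
        if self.data.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibrations must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Movie":
        """Same calibration, new pixel data."""
        return replace(self, data=data)


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as a multi-page 16-bit unsigned TIFF.

    Intensities are clipped to the uint16 range; the float data kept in
    memory is unaffected.
    """
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), data.astype(np.uint16))


def read_movie(path: str | Path, pixel_size_um: float, frame_interval_s: float) -> Movie:
    """Read a multi-page TIFF as a float movie with explicit calibration."""
    data = tifffile.imread(str(path)).astype(np.float64)
    if data.ndim == 2:  # single page
        data = data[None]
    return Movie(data=data, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)


def read_seed_points(path: str | Path) -> pd.DataFrame:
    """Read ring seed-point pairs from CSV.

    Expected columns: ``ring_id, x1, y1, x2, y2`` (pixel coordinates of two
    user-chosen points on the ring, ideally roughly diametrically opposite).
    """
    df = pd.read_csv(path)
    required = {"ring_id", "x1", "y1", "x2", "y2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"seed-point CSV missing columns: {sorted(missing)}")
    return df
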