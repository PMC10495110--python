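"""Core containers shared across the pipeline.

A :class:`Movie` is a time-lapse fluorescence stack with acquisition
metadata attached: the frame interval in seconds and the pixel size in
micrometres.  All image data is indexed ``(frame, row, col)`` with 0-based
pixel indices throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class Movie:
    """A 3-D fluorescence time-lapse stack with acquisition metadata.

    Parameters
    ----------
    data
        Intensity stack, shape ``(n_frames, rows, cols)``.
    frame_interval
        Time between consecutive frames, seconds.
    pixel_size
        Physical pixel size, micrometres per pixel.
    nh4cl_window
        Optional ``(start_s, end_s)`` of an NH4Cl dequench segment.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0
    nh4cl_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"movie data must be 3-D (frame, row, col), got shape {self.data.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame_index(self, t: float) -> int:
        """Index of the frame acquired at or just before time ``t`` (seconds)."""
        return int(np.floor(t / self.frame_interval + 1e-9))

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Frame slice covering the half-open time window ``[start_s, end_s)``."""
        start, end = window
        if end <= start:
            raise ValueError(f"empty time window {window}")
        i0 = max(0, int(np.ceil(start / self.frame_interval - 1e-9)))
        i1 = min(self.n_frames, int(np.ceil(end / self.frame_interval - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"time window {window} contains no frames")
        return slice(i0, i1)

    def with_data(self, data: np.ndarray) -> "Movie":
        """A copy of this movie with the pixel data replaced."""
        return replace(self, data=data)


@dataclass(frozen=True)
class StimProtocol:
    """Electric-field stimulation paradigm: repeated pulse trains.

    The default matches a widely used strong depolarisation protocol for
    dense-core-vesicle exocytosis: 16 trains of 50 pulses at 50 Hz,
    separated by 0.5 s, starting after 30 s of baseline.
    """

    n_trains: int = 16
    pulses_per_train: int = 50
    pulse_frequency: float = 50.0
    inter_train_interval: float = 0.5
    start_time: float = 30.0

    def __post_init__(self) -> None:
        if min(self.n_trains, self.pulses_per_train) < 1:
            raise ValueError("train counts must be positive")
        if self.pulse_frequency <= 0 or self.inter_train_interval <= 0:
            raise ValueError("frequencies and intervals must be positive")
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")

    @property
    def duration(self) -> float:
        """Total stimulation span in seconds."""
        train = self.pulses_per_train / self.pulse_frequency
        return self.n_trains * train + (self.n_trains - 1) * self.inter_train_interval

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def window(self) -> tuple[float, float]:
        return (self.start_time, self.end_time)
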