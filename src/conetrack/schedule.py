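"""Acquisition schedule: burst/cycle timing of the time-lapse protocol.

Growth cones are imaged in short bursts of rapid frames (to resolve comet
motion) repeated at long intervals (to score net growth-cone displacement).
The canonical protocol is 33 frames at 2-s intervals per burst, bursts
repeated every 10 min over 30 min, at 0.211 μm/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionSchedule", "make_schedule", "DEFAULT_SCHEDULE"]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing and sampling of a burst/cycle acquisition.

    Attributes
    ----------
    frames_per_burst : int
        Number of frames acquired in one rapid burst.
    frame_interval : float
        Seconds between consecutive frames within a burst.
    burst_interval : float
        Seconds between the starts of consecutive bursts.
    n_bursts : int
        Number of bursts in the acquisition.
    pixel_size : float
        Lateral pixel size in μm.
    """

    frames_per_burst: int
    frame_interval: float
    burst_interval: float
    n_bursts: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.frames_per_burst < 1:
            raise ValueError("frames_per_burst must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.burst_interval <= 0:
            raise ValueError("burst_interval must be > 0")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.burst_interval < self.frames_per_burst * self.frame_interval:
            raise ValueError(
                "burst_interval must cover the burst: "
                f"{self.burst_interval} < "
                f"{self.frames_per_burst * self.frame_interval}"
            )

    @property
    def n_frames_total(self) -> int:
        return self.frames_per_burst * self.n_bursts

    @property
    def total_duration(self) -> float:
        """Time of the last frame, in seconds."""
        return self.time_of(self.n_bursts - 1, self.frames_per_burst - 1)

    def time_of(self, burst: int, frame: int) -> float:
        """Absolute time (s) of frame ``frame`` within burst ``burst``."""
        if not (0 <= burst < self.n_bursts):
            raise ValueError(f"burst {burst} out of range [0, {self.n_bursts})")
        if not (0 <= frame < self.frames_per_burst):
            raise ValueError(
                f"frame {frame} out of range [0, {self.frames_per_burst})"
            )
        return burst * self.burst_interval + frame * self.frame_interval

    def frame_times(self) -> np.ndarray:
        """Absolute times (s) of all frames, shape (n_bursts, frames_per_burst)."""
        b = np.arange(self.n_bursts)[:, None] * self.burst_interval
        f = np.arange(self.frames_per_burst)[None, :] * self.frame_interval
        return b + f


def make_schedule(
    frames_per_burst: int,
    frame_interval: float,
    burst_interval: float,
    n_bursts: int,
    pixel_size: float,
) -> AcquisitionSchedule:
    """Build a validated :class:`AcquisitionSchedule`.

    Raises
    ------
    ValueError
        If any argument is non-positive or the burst does not fit within
        the burst interval.
    """
    return AcquisitionSchedule(
        frames_per_burst=int(frames_per_burst),
        frame_interval=float(frame_interval),
        burst_interval=float(burst_interval),
        n_bursts=int(n_bursts),
        pixel_size=float(pixel_size),
    )


#: The canonical protocol: 33 × 2-s frames per burst, every 10 min, 4 bursts
#: over 30 min, 0.211 μm/pixel.
DEFAULT_SCHEDULE = make_schedule(33, 2.0, 600.0, 4, 0.211)
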