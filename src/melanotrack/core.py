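"""Acquisition settings and the trajectory container.

The canonical internal conventions are: positions in micrometres, times in
seconds, 0-based integer frame indices. All dialect and unit variation is
handled at the I/O boundary (:mod:`melanotrack.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class AcquisitionSettings:
    """Constants of the imaging acquisition.

    Defaults correspond to brightfield video microscopy at one image every
    0.5 s for 5 minutes (601 frames) with a 0.16 μm pixel.

    Parameters
    ----------
    frame_interval : float
        Time between consecutive frames, seconds.
    n_frames : int
        Number of frames in a complete recording.
    pixel_size : float
        Side of a camera pixel in the sample plane, μm. Displacements below
        this size are unresolvable and treated as pauses.
    """

    frame_interval: float = 0.5
    n_frames: int = 601
    pixel_size: float = 0.16

    def __post_init__(self):
        if not self.frame_interval > 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        if not self.pixel_size > 0:
            raise InvalidParameterError("pixel_size must be > 0")

    @property
    def duration(self) -> float:
        """Total observed time span, seconds: (n_frames − 1)·frame_interval."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class Trajectory:
    """One tracked particle: time-ordered 2D positions plus metadata.

    Attributes
    ----------
    track_id : str
        Identifier of the track.
    frames : ndarray of int
        0-based frame indices, strictly increasing. Contiguous for complete
        recordings; may contain gaps when a reader was asked to tolerate them.
    positions : ndarray, shape (n, 2)
        Positions in μm.
    settings : AcquisitionSettings
    provenance : object, optional
        For simulated tracks, the generating :class:`SimulationParams`.
    """

    track_id: str
    frames: np.ndarray
    positions: np.ndarray
    settings: AcquisitionSettings
    provenance: Optional[object] = None
    times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidParameterError("positions must have shape (n, 2)")
        if len(self.frames) != len(self.positions):
            raise InvalidParameterError("frames and positions length mismatch")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise InvalidParameterError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        self.times = (self.frames - self.frames[0]) * self.settings.frame_interval

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def is_contiguous(self) -> bool:
        """True when every consecutive frame pair differs by exactly 1."""
        return bool(np.all(np.diff(self.frames) == 1))

    @property
    def duration(self) -> float:
        """Observed time span of this track, seconds."""
        return float(self.times[-1] - self.times[0])

    def with_positions(self, positions: np.ndarray, provenance=None) -> "Trajectory":
        """Copy of this trajectory with replaced positions."""
        return Trajectory(
            track_id=self.track_id,
            frames=self.frames.copy(),
            positions=np.asarray(positions, dtype=float),
            settings=self.settings,
            provenance=self.provenance if provenance is None else provenance,
        )

    def step_vectors(self) -> np.ndarray:
        """Displacement vectors between consecutive recorded frames, μm."""
        return np.diff(self.positions, axis=0)

    def step_frame_gaps(self) -> np.ndarray:
        """Frame-index difference for each consecutive step (1 = no gap)."""
        return np.diff(self.frames)
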