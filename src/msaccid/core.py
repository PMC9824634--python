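"""Core data containers shared across the pipeline.

Coordinates are gaze positions in degrees of visual angle, sampled at a
fixed rate (1 kHz by default, so one sample per millisecond).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MsaccidError(Exception):
    """Base class for all package errors."""


class ParameterError(MsaccidError, ValueError):
    """An operation was called with an invalid parameter."""


class TraceError(MsaccidError, ValueError):
    """A gaze trace is malformed (lengths, NaNs, sampling)."""


class DetectionError(MsaccidError, RuntimeError):
    """Event detection could not run on the given trace."""


class EmptySegmentError(MsaccidError, ValueError):
    """A segment or person record with no events where one is required."""


@dataclass
class GazeTrace:
    """Fixed-rate monocular gaze trace for one fixation recording.

    Attributes
    ----------
    x, y : ndarray
        Gaze coordinates in degrees, equal length >= 2, all finite.
    rate_hz : float
        Sampling rate; 1000 Hz throughout unless stated otherwise.
    meta : dict
        Free-form labels (person_id, fixation_id, ...).
    """

    x: np.ndarray
    y: np.ndarray
    rate_hz: float = 1000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise TraceError("trace coordinates must be 1-D arrays")
        if len(self.x) != len(self.y):
            raise TraceError(
                f"x and y lengths differ: {len(self.x)} vs {len(self.y)}"
            )
        if len(self.x) < 2:
            raise TraceError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TraceError("trace contains non-finite values")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def dt_ms(self) -> float:
        """Sample spacing in milliseconds."""
        return 1000.0 / self.rate_hz

    def xy(self) -> np.ndarray:
        """Return an (n, 2) array of points."""
        return np.column_stack([self.x, self.y])

    def replace(self, x: np.ndarray, y: np.ndarray) -> "GazeTrace":
        """New trace with the same rate/meta but different coordinates."""
        return GazeTrace(x=x, y=y, rate_hz=self.rate_hz, meta=dict(self.meta))


@dataclass
class Microsaccade:
    """One detected microsaccade: an ordered run of gaze points.

    ``points`` is an (n, 2) array of x/y in degrees at fixed spacing
    (``dt_ms`` milliseconds between consecutive points, 1 ms at 1 kHz).
    """

    points: np.ndarray
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ParameterError("points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise ParameterError("a microsaccade needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("microsaccade points must be finite")
        if self.dt_ms <= 0:
            raise ParameterError("dt_ms must be positive")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class Segment:
    """All microsaccades extracted from one fixation-point recording."""

    microsaccades: list
    person_id: str = ""
    fixation_id: str = ""

    def __post_init__(self) -> None:
        if len(self.microsaccades) == 0:
            raise EmptySegmentError(
                f"segment {self.person_id}/{self.fixation_id} has no events"
            )

    def __len__(self) -> int:
        return len(self.microsaccades)


@dataclass
class PersonRecord:
    """One person's segments, one per fixation point (typically five)."""

    person_id: str
    segments: list

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise EmptySegmentError(f"person {self.person_id} has no segments")

    def __len__(self) -> int:
        return len(self.segments)
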