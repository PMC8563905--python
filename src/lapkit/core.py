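"""Core in-memory containers shared across the pipeline.

Everything downstream operates on three primitives: a uniformly sampled
scalar :class:`TimeSeries`, a sorted :class:`EventSeries` of time stamps
(lick onsets, lick-port contacts, stimulus onsets), and a per-frame
:class:`PoseTrack` carrying (x, y, likelihood) for one tracked body part.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeries", "EventSeries", "PoseTrack"]

EVENT_KINDS = ("lick_onset", "contact", "stim_onset")


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar signal.

    Parameters
    ----------
    values : array-like of float
        Sample values, arbitrary units.
    rate_hz : float
        Sampling rate in Hz; must be positive.
    t0_s : float
        Time of the first sample in seconds (session clock).
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"TimeSeries values must be 1-D, got shape {vals.shape}")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds on the session clock."""
        return self.t0_s + np.arange(self.values.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        """Time span from first to last sample."""
        return max(self.values.size - 1, 0) / self.rate_hz

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Copy of this series with new values on the same grid."""
        return replace(self, values=np.asarray(values, dtype=float))

    def same_grid(self, other: "TimeSeries", atol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.rate_hz - other.rate_hz) <= atol * max(self.rate_hz, 1.0)
            and abs(self.t0_s - other.t0_s) <= atol
        )


@dataclass(frozen=True)
class EventSeries:
    """Sorted point events on the session clock.

    ``kind`` is one of ``lick_onset``, ``contact`` or ``stim_onset``.
    Times must be strictly increasing.
    """

    times_s: np.ndarray
    kind: str = "contact"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("event times must be 1-D")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times_s", t)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class PoseTrack:
    """Markerless-tracker output for one body part at the video rate.

    ``x``/``y`` are in pixels as emitted by the tracker, or millimetres
    after calibration (``units``).  ``likelihood`` is the tracker's
    per-frame confidence in [0, 1].  Image convention: y grows downward,
    so mouth opening increases jaw y.
    """

    body_part: str
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    rate_hz: float = 120.0
    units: str = "px"
    t0_s: float = 0.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        lk = np.asarray(self.likelihood, dtype=float)
        if not (x.shape == y.shape == lk.shape) or x.ndim != 1:
            raise ValueError("x, y and likelihood must be equal-length 1-D arrays")
        if lk.size and (lk.min() < 0 or lk.max() > 1):
            raise ValueError("likelihood must lie in [0, 1]")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        for name, arr in (("x", x), ("y", y), ("likelihood", lk)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.y.size

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.y.size) / self.rate_hz

    def y_series(self) -> TimeSeries:
        """The vertical trajectory as a :class:`TimeSeries`."""
        return TimeSeries(self.y, rate_hz=self.rate_hz, t0_s=self.t0_s)
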