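"""Core in-memory containers shared across the pipeline.

A recording travels through the pipeline as a :class:`Movie` (T x H x W
fluorescence stack), is reduced to a :class:`ROISet` (paired spatial
footprints and temporal traces), and finally to per-event
:class:`Transient` records and tabular feature rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Movie",
    "MotionTrace",
    "ROISet",
    "Transient",
    "StimulusEvent",
    "StimulusSchedule",
]


@dataclass
class Movie:
    """A fluorescence movie: ``data`` is T x H x W, ``fps`` in Hz.

    ``scale_tag`` records whether values are raw fluorescence (``"raw"``,
    arbitrary units) or relative change over baseline (``"dff"``).
    """

    data: np.ndarray
    fps: float
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("movie data must be T x H x W")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.scale_tag not in ("raw", "dff"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, **kw) -> "Movie":
        return replace(self, **kw)


@dataclass
class MotionTrace:
    """Per-frame rigid (dy, dx) shifts estimated against a template."""

    shifts: np.ndarray  # T x 2, (dy, dx) in px
    template_id: str = ""

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be T x 2")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")


@dataclass
class ROISet:
    """The two matrices of source extraction.

    ``footprints`` holds the spatial components (N x H x W, nonnegative
    weights) and ``traces`` the temporal components (N x T): the
    footprint-weighted mean fluorescence of each ROI over time.
    """

    footprints: np.ndarray
    traces: np.ndarray
    ids: list[str] = field(default_factory=list)
    accepted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.footprints = np.asarray(self.footprints, dtype=np.float64)
        self.traces = np.asarray(self.traces, dtype=np.float64)
        n = self.footprints.shape[0]
        if self.traces.shape[0] != n:
            raise ValueError("footprints and traces disagree on N")
        if not self.ids:
            self.ids = [f"roi{i:04d}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length must equal N")
        if self.accepted is None:
            self.accepted = np.ones(n, dtype=bool)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if n and self.footprints.reshape(n, -1).sum(axis=1).min() <= 0:
            raise ValueError("each footprint must have positive total weight")

    @property
    def n_rois(self) -> int:
        return self.footprints.shape[0]

    def subset(self, idx: Sequence[int]) -> "ROISet":
        idx = list(idx)
        return ROISet(
            footprints=self.footprints[idx],
            traces=self.traces[idx],
            ids=[self.ids[i] for i in idx],
            accepted=self.accepted[idx],
        )


@dataclass
class Transient:
    """One detected suprathreshold calcium event and its six features.

    Times are in seconds on the trace's own clock.  ``amplitude`` is the
    peak excursion over the baseline mean (dF/F units); ``rise`` and
    ``decay`` are straight-line slopes from event start to peak and peak
    to event end respectively (decay reported as a magnitude).
    """

    roi_id: str
    t_start: float
    t_peak: float
    t_end: float
    amplitude: float
    duration: float
    n_peaks: int
    integral: float
    rise: float
    decay: float

    def __post_init__(self) -> None:
        if not (self.t_start <= self.t_peak <= self.t_end):
            raise ValueError("require t_start <= t_peak <= t_end")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.rise < 0 or self.decay < 0:
            raise ValueError("rise/decay must be nonnegative")


@dataclass(frozen=True)
class StimulusEvent:
    """One labelled application to the nerve (agonist or saline wash)."""

    label: str
    onset: float  # s
    post_window: float = 100.0
    pre_window: float | None = None

    @property
    def pre(self) -> float:
        return self.post_window if self.pre_window is None else self.pre_window

    def __post_init__(self) -> None:
        if self.post_window <= 0:
            raise ValueError("post_window must be positive")
        if self.onset - self.pre < 0:
            raise ValueError("pre-stimulus window extends before recording start")


@dataclass
class StimulusSchedule:
    """Ordered application events plus the initial quiet baseline period."""

    events: list[StimulusEvent]
    baseline_duration: float = 60.0
    fps: float = 20.0

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and onsets[0] <= 0:
            raise ValueError("first onset must be positive")
        if onsets and onsets[0] < self.baseline_duration:
            raise ValueError("all onsets must follow the baseline period")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]
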