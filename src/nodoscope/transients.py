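"""Calcium-transient detection, featurization and artifact rejection.

A transient is a contiguous excursion of a dF/F trace above a threshold
of (baseline mean + k_sd * baseline SD), extended outward to the
crossings of the baseline mean, carrying six features: peak amplitude,
duration, number of sub-peaks, response integral (area under the
curve), rise slope and decay slope.

Breathing and other whole-field movement artifacts masquerade as
near-simultaneous transients across the population; windows in which at
least 30% of ROIs peak within 1 s are flagged and their transients
discarded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import Transient

__all__ = [
    "DetectionParams",
    "ArtifactParams",
    "baseline_stats",
    "detect_transients",
    "count_subpeaks",
    "featurize",
    "detect_and_featurize",
    "detect_artifacts",
    "remove_artifact_transients",
]


@dataclass
class DetectionParams:
    """Detection thresholds; times in s, amplitudes in dF/F units.

    ``baseline_window`` is a (start, stop) span of quiet recording used
    for the mean/SD estimate; the detection threshold sits ``k_sd``
    standard deviations above the baseline mean.  Sub-peaks are local
    maxima above threshold with prominence >= ``peak_prominence_sd``
    baseline SDs, at least ``min_separation`` apart; the trace is
    lightly smoothed (Gaussian, ``count_smooth_s``) before the sub-peak
    scan so single noise excursions are not counted.  Suprathreshold
    runs belong to one response when the gap between them is shorter
    than ``gap_merge`` or the trace stays above the baseline mean
    throughout the gap (a multi-peak burst rides on a sustained plateau
    and never returns to baseline between sub-peaks); merged runs
    shorter than ``min_event_s`` are discarded - an isolated sample
    above threshold is a noise excursion, not a calcium event (GCaMP6f
    transients last hundreds of milliseconds).
    """

    baseline_window: tuple[float, float] = (0.0, 55.0)
    k_sd: float = 3.0
    min_separation: float = 0.5
    peak_prominence_sd: float = 1.0
    gap_merge: float = 2.0
    count_smooth_s: float = 0.1
    min_event_s: float = 0.2

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.baseline_window[1] <= self.baseline_window[0]:
            raise ValueError("baseline_window must be a nonempty span")


@dataclass
class ArtifactParams:
    """Coincidence rule for movement-artifact windows."""

    coincidence_fraction: float = 0.30
    window: float = 1.0
    min_rois: int = 5  # fractions over tiny populations are degenerate

    def __post_init__(self) -> None:
        if not 0 < self.coincidence_fraction <= 1:
            raise ValueError("coincidence_fraction must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")


def baseline_stats(
    trace: np.ndarray, fps: float, window: tuple[float, float]
) -> tuple[float, float]:
    """Mean and SD of the trace over the baseline window."""
    lo = int(round(window[0] * fps))
    hi = int(round(window[1] * fps))
    seg = np.asarray(trace, dtype=float)[lo:hi]
    if seg.size < 2:
        raise ValueError("baseline window holds fewer than 2 samples")
    return float(seg.mean()), float(seg.std(ddof=0))


def _suprathreshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_transients(
    trace: np.ndarray,
    fps: float,
    params: DetectionParams | None = None,
    roi_id: str = "roi",
) -> list[Transient]:
    """Detect suprathreshold events on one dF/F trace.

    Threshold = baseline mean + k_sd * baseline SD.  Maximal runs at or
    above threshold are merged when separated by less than ``gap_merge``
    and extended outward to the nearest crossings of the baseline mean;
    each event's peak is the global maximum of the run.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    mean, sd = baseline_stats(trace, fps, params.baseline_window)
    if sd == 0:
        raise ValueError(
            "baseline SD is zero; choose a baseline window containing noise"
        )
    theta = mean + params.k_sd * sd
    runs = _suprathreshold_runs(trace >= theta)
    if not runs:
        return []
    # merge runs into responses: short gaps, or gaps bridged above the
    # baseline mean (the trace never came back down between sub-peaks)
    gap = params.gap_merge * fps
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        prev_end = merged[-1][1]
        bridged = bool(np.all(trace[prev_end:a] > mean))
        if a - prev_end < gap or bridged:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    # discard events with too little suprathreshold signal (count samples
    # at/above threshold, not the merged span: gap-merging must not let
    # a pair of isolated noise spikes masquerade as a sustained event)
    min_len = params.min_event_s * fps
    above = trace >= theta
    merged = [r for r in merged if above[r[0] : r[1]].sum() >= min_len]
    out = []
    T = trace.size
    for a, b in merged:
        # extend outward to baseline-mean crossings
        s = a
        while s > 0 and trace[s - 1] > mean:
            s -= 1
        e = b - 1
        while e < T - 1 and trace[e + 1] > mean:
            e += 1
        p = a + int(np.argmax(trace[a:b]))
        # clip end so the event is well-formed even at trace edges
        if e <= s:
            e = s + 1 if s + 1 < T else s
        tr = featurize(
            trace,
            fps,
            s,
            p,
            e,
            baseline_mean=mean,
            baseline_sd=sd,
            params=params,
            roi_id=roi_id,
        )
        out.append(tr)
    return out


def count_subpeaks(
    trace: np.ndarray,
    fps: float,
    start: int,
    end: int,
    theta: float,
    prominence: float,
    min_separation: float,
    smooth_s: float = 0.1,
) -> int:
    """Count sub-peaks of the event spanning samples [start, end].

    Local maxima of the (lightly smoothed) trace above the detection
    threshold, with the given prominence and a minimum mutual
    separation; the event's global peak always counts, so the result is
    at least 1.
    """
    from scipy.signal import find_peaks

    seg = np.asarray(trace, dtype=float)[start : end + 1]
    if smooth_s > 0:
        seg = gaussian_filter1d(seg, sigma=smooth_s * fps, mode="nearest")
    dist = max(1, int(round(min_separation * fps)))
    pk, _ = find_peaks(seg, height=theta, prominence=prominence, distance=dist)
    return max(1, pk.size)


def featurize(
    trace: np.ndarray,
    fps: float,
    start: int,
    peak: int,
    end: int,
    baseline_mean: float,
    baseline_sd: float,
    params: DetectionParams | None = None,
    roi_id: str = "roi",
) -> Transient:
    """Compute the six features of one event given its sample indices.

    amplitude = trace(peak) - baseline mean; duration = t_end - t_start;
    integral = trapezoid area of (trace - baseline mean) clipped below
    at zero; rise and decay are straight-line slopes start->peak and
    peak->end (decay as a magnitude).  Zero-length rise or decay legs at
    the event edge are evaluated over one frame interval.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    dt = 1.0 / fps
    amp = trace[peak] - baseline_mean
    dur = (end - start) * dt
    seg = np.clip(trace[start : end + 1] - baseline_mean, 0.0, None)
    integral = float(np.trapezoid(seg, dx=dt))
    if peak > start:
        rise = (trace[peak] - trace[start]) / ((peak - start) * dt)
    else:  # degenerate: peak at the first sample, slope over one frame
        nxt = min(peak + 1, trace.size - 1)
        rise = abs(trace[nxt] - trace[peak]) / dt
    if end > peak:
        decay = abs(trace[end] - trace[peak]) / ((end - peak) * dt)
    else:
        prv = max(peak - 1, 0)
        decay = abs(trace[peak] - trace[prv]) / dt
    theta = baseline_mean + params.k_sd * baseline_sd
    n_peaks = count_subpeaks(
        trace,
        fps,
        start,
        end,
        theta=theta,
        prominence=params.peak_prominence_sd * baseline_sd,
        min_separation=params.min_separation,
        smooth_s=params.count_smooth_s,
    )
    return Transient(
        roi_id=roi_id,
        t_start=start * dt,
        t_peak=peak * dt,
        t_end=end * dt,
        amplitude=float(amp),
        duration=float(dur),
        n_peaks=int(n_peaks),
        integral=integral,
        rise=float(max(rise, 0.0)),
        decay=float(decay),
    )


def detect_and_featurize(
    traces: np.ndarray,
    fps: float,
    params: DetectionParams | None = None,
    ids: list[str] | None = None,
) -> dict[str, list[Transient]]:
    """Run detection over an N x T trace matrix; returns per-ROI events."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    ids = ids or [f"roi{i:04d}" for i in range(traces.shape[0])]
    return {
        rid: detect_transients(tr, fps, params, roi_id=rid)
        for rid, tr in zip(ids, traces)
    }


def detect_artifacts(
    transients_by_roi: dict[str, list[Transient]],
    n_rois: int,
    fps: float,
    params: ArtifactParams | None = None,
) -> list[tuple[float, float]]:
    """Flag windows in which too many ROIs peak near-simultaneously.

    Slides a ``window``-second window frame by frame; a window is
    flagged when the fraction of distinct ROIs with a transient peak
    inside it reaches ``coincidence_fraction`` (inclusive).  Overlapping
    flagged windows are merged.  Populations smaller than ``min_rois``
    are never flagged (the fraction is degenerate there).
    """
    params = params or ArtifactParams()
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if n_rois < params.min_rois:
        return []
    peaks = []  # (t_peak, roi index)
    roi_index = {rid: i for i, rid in enumerate(transients_by_roi)}
    for rid, trs in transients_by_roi.items():
        for tr in trs:
            peaks.append((tr.t_peak, roi_index[rid]))
    if not peaks:
        return []
    peaks.sort()
    times = np.array([p[0] for p in peaks])
    rois = np.array([p[1] for p in peaks])
    t_max = times.max()
    dt = 1.0 / fps
    flagged = []
    n_steps = int(math.ceil(t_max / dt)) + 1
    lo = 0
    hi = 0
    for s in range(n_steps):
        w0 = s * dt
        w1 = w0 + params.window
        while lo < times.size and times[lo] < w0:
            lo += 1
        while hi < times.size and times[hi] <= w1:
            hi += 1
        if hi > lo:
            frac = np.unique(rois[lo:hi]).size / n_rois
            if frac >= params.coincidence_fraction:
                flagged.append((w0, w1))
    if not flagged:
        return []
    merged = [list(flagged[0])]
    for a, b in flagged[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def remove_artifact_transients(
    transients_by_roi: dict[str, list[Transient]],
    flagged: list[tuple[float, float]],
) -> tuple[dict[str, list[Transient]], dict[str, list[Transient]]]:
    """Drop transients whose peak falls in a flagged interval.

    Returns (kept, removed) keyed by ROI id.
    """
    kept: dict[str, list[Transient]] = {}
    removed: dict[str, list[Transient]] = {}
    for rid, trs in transients_by_roi.items():
        k, r = [], []
        for tr in trs:
            if any(a <= tr.t_peak <= b for a, b in flagged):
                r.append(tr)
            else:
                k.append(tr)
        kept[rid] = k
        removed[rid] = r
    return kept, removed
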