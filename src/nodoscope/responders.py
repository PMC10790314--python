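"""Stimulus-responder selectivity filtering and the feature table.

A neuron counts as a responder to an application event when it has at
least one detected transient peaking inside the post-stimulus window
and is not excluded by prior activity: if the maximum amplitude during
the pre-stimulus control window exceeds 50% of the post-stimulus
maximum, the response is considered nonspecific (ongoing or mechanical
activity) and the neuron is excluded for that event.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import StimulusEvent, Transient

__all__ = [
    "ResponderResult",
    "classify_responders",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "amplitude_dff",
    "duration_s",
    "n_peaks",
    "integral_dff_s",
    "rise_dff_per_s",
    "decay_dff_per_s",
]


@dataclass
class ResponderResult:
    roi_id: str
    event_label: str
    event_onset: float
    responder: bool
    reason: str  # responded | no_transient | pre_activity_exclusion
    window_transients: list[Transient] = field(default_factory=list)
    pre_max: float = 0.0
    post_max: float = 0.0


def _pre_activity_max(
    transients: list[Transient],
    event: StimulusEvent,
    trace: np.ndarray | None,
    fps: float | None,
    baseline_mean: float,
) -> float:
    """Maximum activity amplitude in the pre-stimulus control window.

    Detected-transient amplitude by default; when no transient peaks in
    the window and the raw trace is available, falls back to the
    maximum baseline-subtracted trace value (subthreshold activity also
    counts as 'activity')."""
    lo, hi = event.onset - event.pre, event.onset
    amps = [t.amplitude for t in transients if lo <= t.t_peak <= hi]
    if amps:
        return max(amps)
    if trace is not None and fps is not None:
        a, b = int(round(lo * fps)), int(round(hi * fps))
        seg = np.asarray(trace, dtype=float)[a:b]
        if seg.size:
            return float(max(seg.max() - baseline_mean, 0.0))
    return 0.0


def classify_responders(
    transients_by_roi: dict[str, list[Transient]],
    event: StimulusEvent,
    traces: np.ndarray | None = None,
    fps: float | None = None,
    baseline_means: dict[str, float] | None = None,
    exclusion_ratio: float = 0.5,
    use_trace_fallback: bool = True,
) -> list[ResponderResult]:
    """Label every ROI responder / non-responder for one event.

    post_max is the largest transient amplitude peaking in
    (onset, onset + post_window]; the ROI responds iff post_max exists
    and the pre-window maximum is NOT greater than
    ``exclusion_ratio * post_max`` (strict inequality: a pre maximum of
    exactly half the post maximum still responds).
    """
    out = []
    ids = list(transients_by_roi)
    for i, rid in enumerate(ids):
        trs = transients_by_roi[rid]
        in_post = [
            t for t in trs if event.onset < t.t_peak <= event.onset + event.post_window
        ]
        if not in_post:
            out.append(
                ResponderResult(rid, event.label, event.onset, False, "no_transient")
            )
            continue
        post_max = max(t.amplitude for t in in_post)
        trace = traces[i] if (traces is not None and use_trace_fallback) else None
        bmean = (baseline_means or {}).get(rid, 0.0)
        pre_max = _pre_activity_max(trs, event, trace, fps, bmean)
        if pre_max > exclusion_ratio * post_max:
            out.append(
                ResponderResult(
                    rid,
                    event.label,
                    event.onset,
                    False,
                    "pre_activity_exclusion",
                    pre_max=pre_max,
                    post_max=post_max,
                )
            )
        else:
            out.append(
                ResponderResult(
                    rid,
                    event.label,
                    event.onset,
                    True,
                    "responded",
                    window_transients=in_post,
                    pre_max=pre_max,
                    post_max=post_max,
                )
            )
    return out


def build_feature_table(
    results: list[ResponderResult],
    aggregation: str = "per_transient",
) -> pd.DataFrame:
    """Tabulate responder features, one row per responding transient
    (``per_transient``, matching per-response scatter points) or one
    row per responder with within-window means (``per_responder``).

    Saline and other negative-control events simply contribute zero
    rows when nothing responds.
    """
    if aggregation not in ("per_transient", "per_responder"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    seen = set()
    rows = []
    for r in results:
        key = (r.roi_id, r.event_label, r.event_onset)
        if key in seen:
            raise ValueError(f"duplicate (roi, event) result: {key}")
        seen.add(key)
        if not r.responder:
            continue
        feats = [
            {
                "amplitude_dff": t.amplitude,
                "duration_s": t.duration,
                "n_peaks": t.n_peaks,
                "integral_dff_s": t.integral,
                "rise_dff_per_s": t.rise,
                "decay_dff_per_s": t.decay,
                "t_peak_s": t.t_peak,
            }
            for t in r.window_transients
        ]
        if aggregation == "per_responder":
            agg = pd.DataFrame(feats).mean().to_dict()
            agg["t_peak_s"] = feats[0]["t_peak_s"]
            feats = [agg]
        for f in feats:
            rows.append(
                {
                    "roi_id": r.roi_id,
                    "event_label": r.event_label,
                    "responder_reason": r.reason,
                    **f,
                }
            )
    cols = ["roi_id", "event_label", "t_peak_s", *FEATURE_COLUMNS, "responder_reason"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
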