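"""Source extraction: from a dF/F movie to the two matrices.

A seeded extractor in the CNMF-E family's spirit: seed pixels are local
maxima of the neighbor-correlation image gated by the peak-to-noise
ratio image, footprints are grown around each seed inside a gSiz box by
half-max thresholding of a gSig-smoothed local correlation patch, and
each trace is the footprint-weighted mean dF/F per frame.  Externally
produced footprint/trace matrices (e.g. from a full constrained NMF
factorization) can be imported and re-applied to new movies unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .containers import Movie, ROISet

__all__ = [
    "ExtractParams",
    "correlation_pnr_images",
    "seed_and_segment",
    "merge_rois",
    "apply_fixed_rois",
    "review_rois",
    "save_roiset",
    "load_roiset",
    "match_rois_to_truth",
]

MAX_DOWNSAMPLE = 2  # spatial/temporal downsampling beyond 2x is refused


@dataclass
class ExtractParams:
    """Seeded-extraction parameters (px unless noted).

    ``gSig``/``gSiz`` are the Gaussian width and bounding size of a
    soma; ``min_corr``/``min_pnr`` threshold the seeding statistics
    (typical useful ranges 0.6-0.9 and 4-10); ``merge_thresh`` is the
    trace correlation above which spatially overlapping ROIs are one
    neuron (kept very high, 0.999, so proximal neurons do not blend).
    ``patch_half``/``stride`` tile the seeding on large fields.
    """

    gSig: float = 6.0
    gSiz: int = 25
    patch_half: int = 36
    stride: int = 25
    min_corr: float = 0.8
    min_pnr: float = 6.0
    merge_thresh: float = 0.999

    def __post_init__(self) -> None:
        if self.gSig >= self.gSiz:
            raise ValueError("require gSig < gSiz")
        if not 0 < self.min_corr < 1:
            raise ValueError("min_corr must be in (0, 1)")
        if self.merge_thresh > 1:
            raise ValueError("merge_thresh must be <= 1")


def correlation_pnr_images(movie: Movie) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor-correlation and peak-to-noise-ratio images.

    corr: mean Pearson correlation of each pixel's time course with its
    8 neighbors (zero-variance pixels contribute 0).  pnr: per-pixel
    peak dF/F divided by a robust noise scale (1.4826 * MAD of the
    temporal first difference / sqrt(2), insensitive to transients).
    """
    if movie.n_frames < 10:
        raise ValueError("need at least 10 frames")
    data = movie.data
    T, H, W = data.shape
    mean = data.mean(axis=0)
    centered = (data - mean).astype(np.float32)
    sd = centered.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(centered)
    z[:, ok] = centered[:, ok] / sd[ok]
    corr = np.zeros((H, W))
    count = np.zeros((H, W))
    for dy, dx in [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]:
        a = z[:, max(dy, 0) : H + min(dy, 0), max(dx, 0) : W + min(dx, 0)]
        b = z[:, max(-dy, 0) : H + min(-dy, 0), max(-dx, 0) : W + min(-dx, 0)]
        c = np.einsum("tij,tij->ij", a, b, dtype=np.float64) / T
        corr[max(-dy, 0) : H + min(-dy, 0), max(-dx, 0) : W + min(-dx, 0)] += c
        count[max(-dy, 0) : H + min(-dy, 0), max(-dx, 0) : W + min(-dx, 0)] += 1
    corr /= count
    # robust noise from first differences: transients are slow, noise is not
    diff = np.diff(data, axis=0)
    noise = 1.4826 * np.median(np.abs(diff - np.median(diff, axis=0)), axis=0)
    noise /= np.sqrt(2.0)
    peak = data.max(axis=0) - np.median(data, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pnr = np.where(noise > 0, peak / noise, 0.0)
    return corr, pnr


def _segment_footprint(
    corr_smooth: np.ndarray, seed: tuple[int, int], gSiz: int
) -> np.ndarray:
    """Footprint = connected half-max region of the smoothed local
    correlation image inside a gSiz box around the seed."""
    H, W = corr_smooth.shape
    r = gSiz // 2
    y0, y1 = max(0, seed[0] - r), min(H, seed[0] + r + 1)
    x0, x1 = max(0, seed[1] - r), min(W, seed[1] + r + 1)
    patch = corr_smooth[y0:y1, x0:x1]
    level = 0.5 * corr_smooth[seed]
    mask = patch >= level
    lab, _ = ndimage.label(mask)
    keep = lab == lab[seed[0] - y0, seed[1] - x0]
    fp = np.zeros((H, W))
    weights = np.where(keep, patch, 0.0)
    fp[y0:y1, x0:x1] = np.clip(weights, 0.0, None)
    return fp


def _weighted_traces(data: np.ndarray, footprints: np.ndarray) -> np.ndarray:
    flat = footprints.reshape(footprints.shape[0], -1)
    wsum = flat.sum(axis=1, keepdims=True)
    return (data.reshape(data.shape[0], -1) @ (flat / wsum).T).T


def seed_and_segment(movie: Movie, params: ExtractParams | None = None) -> ROISet:
    """Detect ROIs on a dF/F movie; empty result when nothing passes."""
    from skimage.feature import peak_local_max

    params = params or ExtractParams()
    corr, pnr = correlation_pnr_images(movie)
    gate = (corr >= params.min_corr) & (pnr >= params.min_pnr)
    score = np.where(gate, corr, 0.0)
    if not gate.any():
        return ROISet(
            footprints=np.empty((0,) + movie.shape[1:]),
            traces=np.empty((0, movie.n_frames)),
        )
    seeds = peak_local_max(
        score,
        min_distance=max(1, int(round(params.gSig))),
        threshold_abs=1e-12,
        exclude_border=False,
    )
    corr_smooth = ndimage.gaussian_filter(np.clip(corr, 0, None), params.gSig / 2.0)
    fps_ = [
        _segment_footprint(corr_smooth, (int(y), int(x)), params.gSiz)
        for y, x in seeds
    ]
    fps_ = [f for f in fps_ if f.sum() > 0]
    if not fps_:
        return ROISet(
            footprints=np.empty((0,) + movie.shape[1:]),
            traces=np.empty((0, movie.n_frames)),
        )
    footprints = np.stack(fps_)
    traces = _weighted_traces(movie.data, footprints)
    roiset = ROISet(footprints=footprints, traces=traces)
    return merge_rois(roiset, params.merge_thresh, movie=movie)


def merge_rois(
    roiset: ROISet, merge_thresh: float, movie: Movie | None = None
) -> ROISet:
    """Merge ROI groups with spatial overlap and near-identical traces.

    Pairs overlapping in space whose trace correlation reaches
    ``merge_thresh`` are joined under transitive closure (union-find);
    merged footprints are summed and traces recomputed (on the movie
    when given, else as footprint-weighted means of member traces).
    """
    n = roiset.n_rois
    if n <= 1:
        return roiset
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    flat = roiset.footprints.reshape(n, -1)
    overlap = (flat > 0) @ (flat > 0).T
    tr = roiset.traces - roiset.traces.mean(axis=1, keepdims=True)
    sd = tr.std(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if not overlap[i, j]:
                continue
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = float(tr[i] @ tr[j] / (sd[i] * sd[j] * tr.shape[1]))
            if r >= merge_thresh:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    if len(groups) == n:
        return roiset
    footprints, traces, ids, accepted = [], [], [], []
    for members in groups.values():
        fp = roiset.footprints[members].sum(axis=0)
        footprints.append(fp)
        if movie is not None:
            traces.append(_weighted_traces(movie.data, fp[None])[0])
        else:
            w = np.array([roiset.footprints[m].sum() for m in members])
            traces.append((w / w.sum()) @ roiset.traces[members])
        ids.append(roiset.ids[members[0]])
        accepted.append(all(roiset.accepted[m] for m in members))
    return ROISet(
        footprints=np.stack(footprints),
        traces=np.stack(traces),
        ids=ids,
        accepted=np.array(accepted),
    )


def apply_fixed_rois(movie: Movie, roiset: ROISet) -> ROISet:
    """Recompute traces on a new movie with footprints and ids fixed."""
    if roiset.footprints.shape[1:] != movie.shape[1:]:
        raise ValueError(
            f"footprint field {roiset.footprints.shape[1:]} does not match "
            f"movie field {movie.shape[1:]}"
        )
    return ROISet(
        footprints=roiset.footprints.copy(),
        traces=_weighted_traces(movie.data, roiset.footprints),
        ids=list(roiset.ids),
        accepted=roiset.accepted.copy(),
    )


def review_rois(roiset: ROISet, decisions: dict[str, bool]) -> tuple[ROISet, list]:
    """Apply manual accept/reject decisions; returns (roiset, audit log)."""
    unknown = set(decisions) - set(roiset.ids)
    if unknown:
        raise KeyError(f"unknown ROI ids: {sorted(unknown)}")
    accepted = roiset.accepted.copy()
    log = []
    for rid, ok in decisions.items():
        i = roiset.ids.index(rid)
        log.append({"roi_id": rid, "before": bool(accepted[i]), "after": bool(ok)})
    for rid, ok in decisions.items():
        accepted[roiset.ids.index(rid)] = ok
    out = ROISet(
        footprints=roiset.footprints.copy(),
        traces=roiset.traces.copy(),
        ids=list(roiset.ids),
        accepted=accepted,
    )
    return out, log


def save_roiset(roiset: ROISet, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("footprints", data=roiset.footprints)
        h5.create_dataset("traces", data=roiset.traces)
        h5.create_dataset("ids", data=np.array(roiset.ids, dtype="S"))
        h5.create_dataset("accepted", data=roiset.accepted)


def load_roiset(path: str | Path) -> ROISet:
    import h5py

    with h5py.File(path, "r") as h5:
        return ROISet(
            footprints=h5["footprints"][...],
            traces=h5["traces"][...],
            ids=[s.decode() for s in h5["ids"][...]],
            accepted=h5["accepted"][...],
        )


def match_rois_to_truth(
    roiset: ROISet, true_centroids: np.ndarray, tol_px: float
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy centroid matching; returns (recall, precision, pairs)."""
    if roiset.n_rois == 0:
        return 0.0, 0.0, []
    cents = []
    for fp in roiset.footprints:
        ys, xs = np.nonzero(fp)
        w = fp[ys, xs]
        cents.append((np.average(ys, weights=w), np.average(xs, weights=w)))
    cents = np.array(cents)
    true_centroids = np.asarray(true_centroids, dtype=float)
    d = np.linalg.norm(cents[:, None, :] - true_centroids[None, :, :], axis=2)
    pairs = []
    used_r, used_t = set(), set()
    for k in np.argsort(d, axis=None):
        i, j = divmod(int(k), d.shape[1])
        if i in used_r or j in used_t or d[i, j] > tol_px:
            continue
        pairs.append((i, j))
        used_r.add(i)
        used_t.add(j)
    recall = len(pairs) / len(true_centroids)
    precision = len(pairs) / roiset.n_rois
    return recall, precision, pairs
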