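"""Raw movie conditioning: chunk reading, half-sizing, rigid motion
correction and per-pixel binned-percentile dF/F.

Raw miniscope recordings arrive as consecutive 1000-frame TIFF chunks.
The field of view is 2x2 mean-pooled so somata measure ~12 px across,
each frame is registered to an early-baseline template by FFT phase
correlation, and fluorescence is converted to dF/F against a low
(20th) percentile baseline computed per pixel in non-overlapping 5 s
bins.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import Movie, MotionTrace

__all__ = [
    "DFFParams",
    "read_chunked_tiff",
    "write_chunked_tiff",
    "spatial_halve",
    "motion_correct_rigid",
    "compute_dff",
    "drop_frames",
]


@dataclass
class DFFParams:
    """Binned-percentile dF/F parameters.

    The baseline F0 of a pixel is the ``baseline_percentile``-th
    percentile (linear interpolation convention) of its values within
    each non-overlapping ``bin_length``-second bin; output is
    ``output_scale * (F - F0) / F0``.  The default scale of 100 puts
    dF/F in the tens-to-hundreds range typical of these recordings.
    """

    bin_length: float = 5.0
    baseline_percentile: float = 20.0
    output_scale: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_percentile < 100:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if self.bin_length <= 0:
            raise ValueError("bin_length must be positive")


def read_chunked_tiff(paths: list[str | Path], fps: float = 20.0) -> Movie:
    """Concatenate multi-page TIFF chunks, in the given path order.

    The caller owns the ordering: pass sorted paths for chronological
    chunks (``movie_chunk000.tif``, ``movie_chunk001.tif``, ...).
    """
    import tifffile

    if not paths:
        raise ValueError("no paths given")
    frames = []
    shape = None
    dtype = None
    for p in paths:
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if shape is None:
            shape, dtype = arr.shape[1:], arr.dtype
        elif arr.shape[1:] != shape or arr.dtype != dtype:
            raise ValueError(
                f"chunk {p} has frames {arr.shape[1:]} ({arr.dtype}), "
                f"expected {shape} ({dtype})"
            )
        frames.append(arr)
    return Movie(data=np.concatenate(frames, axis=0), fps=fps)


def write_chunked_tiff(
    movie: Movie, outdir: str | Path, chunk_frames: int = 1000, prefix: str = "movie"
) -> list[Path]:
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = []
    for c in range(0, movie.n_frames, chunk_frames):
        p = outdir / f"{prefix}_chunk{c // chunk_frames:03d}.tif"
        tifffile.imwrite(p, movie.data[c : c + chunk_frames].astype(np.float32))
        out.append(p)
    return out


def spatial_halve(movie: Movie) -> Movie:
    """Halve the field of view by 2x2 mean pooling.

    A trailing odd row/column is dropped.  Neuron diameters halve
    accordingly.
    """
    T, H, W = movie.shape
    if H < 2 or W < 2:
        raise ValueError("field too small to halve")
    d = movie.data[:, : H - H % 2, : W - W % 2]
    pooled = d.reshape(T, H // 2, 2, W // 2, 2).mean(axis=(2, 4))
    return movie.copy_with(data=pooled)


def motion_correct_rigid(
    movie: Movie,
    template_frames: tuple[int, int] = (0, 100),
    upsample: int = 1,
) -> tuple[Movie, MotionTrace]:
    """Register every frame to a template by FFT phase correlation.

    The template is the mean of ``template_frames`` (an early-baseline
    span is stable by default).  The estimated per-frame displacement is
    undone by applying its negative; borders exposed by the shift are
    filled by edge replication.  Subpixel registration at 1/``upsample``
    px uses upsampled cross-correlation.
    """
    a, b = template_frames
    if not (0 <= a < b <= movie.n_frames):
        raise ValueError("template_frames outside movie")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    template = movie.data[a:b].mean(axis=0)
    T = movie.n_frames
    shifts = np.zeros((T, 2))
    out = np.empty_like(movie.data)
    for f in range(T):
        frame = movie.data[f]
        if not frame.any():
            warnings.warn(
                f"frame {f} is all zero; phase correlation undefined, "
                "assuming zero shift",
                stacklevel=2,
            )
            out[f] = frame
            continue
        corr_shift, _, _ = phase_cross_correlation(
            template, frame, upsample_factor=upsample, normalization=None
        )
        # record the frame's displacement; the applied correction is its
        # negative (which is what phase correlation returns directly)
        shifts[f] = -corr_shift
        if np.any(corr_shift):
            order = 0 if upsample == 1 else 1
            out[f] = ndimage.shift(frame, corr_shift, order=order, mode="nearest")
        else:
            out[f] = frame
    mt = MotionTrace(shifts=shifts, template_id=f"mean[{a}:{b}]")
    return movie.copy_with(data=out), mt


def compute_dff(movie: Movie, params: DFFParams | None = None) -> Movie:
    """Per-pixel binned-percentile dF/F.

    For each pixel and each non-overlapping bin of ``bin_length``
    seconds, F0 is the ``baseline_percentile`` of that pixel's values in
    the bin; the last partial bin uses its own percentile.  Raw
    fluorescence must be positive (offset the movie if needed).
    """
    params = params or DFFParams()
    if movie.scale_tag == "dff":
        raise ValueError("movie is already dF/F scaled")
    bin_frames = int(round(params.bin_length * movie.fps))
    if bin_frames < 2:
        raise ValueError("bin must cover at least 2 frames")
    data = movie.data
    T = movie.n_frames
    out = np.empty_like(data)
    for s in range(0, T, bin_frames):
        seg = data[s : s + bin_frames]
        f0 = np.percentile(seg, params.baseline_percentile, axis=0)
        if np.any(f0 <= 0):
            raise ValueError(
                "baseline F0 <= 0 at some pixel; raw fluorescence must be "
                "positive - add a constant offset before computing dF/F"
            )
        out[s : s + bin_frames] = params.output_scale * (seg - f0) / f0
    return movie.copy_with(data=out, scale_tag="dff")


def drop_frames(movie: Movie, frame_ids) -> tuple[Movie, dict]:
    """Remove bad frames; returns the movie and an old->new index map."""
    ids = np.asarray(sorted(set(int(i) for i in frame_ids)), dtype=int)
    if len(ids) != len(list(frame_ids)):
        warnings.warn("duplicate frame ids deduplicated", stacklevel=2)
    if ids.size and (ids.min() < 0 or ids.max() >= movie.n_frames):
        raise IndexError("frame id out of range")
    keep = np.setdiff1d(np.arange(movie.n_frames), ids)
    index_map = {int(old): int(new) for new, old in enumerate(keep)}
    log = {"dropped": ids.tolist(), "index_map": index_map}
    return movie.copy_with(data=movie.data[keep]), log
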