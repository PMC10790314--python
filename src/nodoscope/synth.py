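"""Ground-truth synthetic recordings emulating 1P ganglion imaging.

The generator produces GCaMP6f-like multi-peak calcium transients on
~12-px somata over a bright diffuse background, with breathing-coupled
global artifact bumps and rigid x-y jitter, at the desk-scale schedule
of a 60 s quiet baseline followed by 150 s stimulus windows.

Class presets are calibrated so that the *population* means of the
analytic kernel features (peak amplitude, duration, number of sub-peaks)
equal the printed group means for each agonist class.  Printed standard
errors are converted to population SDs via SEM*sqrt(n); amplitude and
duration use right-skewed log-normal laws (SD clipped at the mean to
avoid absurd tails), the sub-peak count uses a shifted negative-binomial
(>= 1) matched to the implied variance.  The three marginals are coupled
through a Gaussian copula with positive rank correlation - weak responses
tend to be brief and single-peaked - which keeps multi-peak kernels
geometrically feasible without rejection bias on the marginal means.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Movie, StimulusEvent, StimulusSchedule

__all__ = [
    "TransientKernel",
    "ClassPreset",
    "NoiseModel",
    "SyntheticNeuron",
    "CLASS_PRESETS",
    "preset_from_printed",
    "draw_kernel",
    "draw_kernels",
    "render_trace",
    "render_trace_set",
    "render_movie",
    "write_fixture",
    "read_fixture",
    "make_class_traces",
]

# Fraction of the kernel duration spent rising to the first sub-peak and
# decaying after the last one; sub-peaks occupy the remaining middle span.
RISE_FRAC = 0.12
TAIL_FRAC = 0.12
#: kernel value at end_time before the closing ramp zeroes it exactly
END_FLOOR_FRAC = 0.02
#: minimum spacing between sub-peaks (s); must exceed the detector's
#: default sub-peak separation so counts are recoverable
MIN_SUBPEAK_SPACING = 0.55
#: later sub-peak heights relative to the first (global) peak
SUB_AMP_RANGE = (0.55, 0.90)
#: valley level between sub-peaks, relative to the lower adjacent peak
VALLEY_FRAC = 0.45


class CalibrationError(ValueError):
    """Raised when a preset's moments cannot be realised as kernels."""


@dataclass
class TransientKernel:
    """Analytic multi-peak transient: linear rise to the first (global)
    sub-peak, exponential decay between sub-peaks with a short linear
    rise into each, exponential tail closed by a ramp so the kernel is
    exactly zero outside ``[onset, end_time]``."""

    onset: float
    subpeak_times: list[float]
    subpeak_amplitudes: list[float]
    rise_time: float
    decay_tau: float
    end_time: float
    valley_levels: list[float] = field(default_factory=list)
    valley_rise: float = 0.0

    def __post_init__(self) -> None:
        if self.end_time <= self.onset:
            raise ValueError("end_time must exceed onset")
        if len(self.subpeak_times) < 1:
            raise ValueError("need at least one sub-peak")
        if min(self.subpeak_amplitudes) <= 0:
            raise ValueError("sub-peak amplitudes must be positive")
        if self.subpeak_amplitudes[0] < max(self.subpeak_amplitudes):
            raise ValueError("first sub-peak must be the global maximum")
        if len(self.valley_levels) != len(self.subpeak_times) - 1:
            raise ValueError("need one valley level per adjacent sub-peak pair")

    # -- analytic form -------------------------------------------------
    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel waveform sampled at times ``t`` (s)."""
        t = np.asarray(t, dtype=np.float64)
        y = np.zeros_like(t)
        p = self.subpeak_times
        h = self.subpeak_amplitudes
        # linear rise
        m = (t >= self.onset) & (t <= p[0])
        if self.rise_time > 0:
            y[m] = h[0] * (t[m] - self.onset) / self.rise_time
        else:
            y[m] = h[0]
        # inter-peak segments: exponential fall to the valley, linear rise
        for i in range(len(p) - 1):
            c = self.valley_levels[i]
            t_v = p[i + 1] - self.valley_rise
            tau = (t_v - p[i]) / math.log(h[i] / c)
            m = (t > p[i]) & (t <= t_v)
            y[m] = h[i] * np.exp(-(t[m] - p[i]) / tau)
            m = (t > t_v) & (t <= p[i + 1])
            y[m] = c + (h[i + 1] - c) * (t[m] - t_v) / self.valley_rise
        # closing tail: exponential minus a ramp that zeroes it at end_time
        L = self.end_time - p[-1]
        eps = END_FLOOR_FRAC * h[-1]
        m = (t > p[-1]) & (t <= self.end_time)
        y[m] = h[-1] * np.exp(-(t[m] - p[-1]) / self.decay_tau) - eps * (
            t[m] - p[-1]
        ) / L
        return y

    # -- closed-form features -----------------------------------------
    def analytic_features(self) -> dict[str, float]:
        """Features of the noiseless kernel under the detector's own
        definitions (peak over zero baseline, duration between zero
        crossings, straight-line rise/decay slopes, trapezoid-free exact
        area)."""
        p = self.subpeak_times
        h = self.subpeak_amplitudes
        amp = h[0]
        dur = self.end_time - self.onset
        area = 0.5 * amp * self.rise_time
        for i in range(len(p) - 1):
            c = self.valley_levels[i]
            t_v = p[i + 1] - self.valley_rise
            tau = (t_v - p[i]) / math.log(h[i] / c)
            area += tau * (h[i] - c)  # exponential segment
            area += 0.5 * (c + h[i + 1]) * self.valley_rise
        L = self.end_time - p[-1]
        eps = END_FLOOR_FRAC * h[-1]
        area += self.decay_tau * h[-1] * (1.0 - math.exp(-L / self.decay_tau))
        area -= 0.5 * eps * L
        return {
            "amplitude": amp,
            "duration": dur,
            "n_peaks": len(p),
            "integral": area,
            "rise": amp / self.rise_time,
            "decay": amp / (self.end_time - p[0]),
            "t_peak": p[0],
        }

    def shifted(self, dt: float) -> "TransientKernel":
        return TransientKernel(
            onset=self.onset + dt,
            subpeak_times=[t + dt for t in self.subpeak_times],
            subpeak_amplitudes=list(self.subpeak_amplitudes),
            rise_time=self.rise_time,
            decay_tau=self.decay_tau,
            end_time=self.end_time + dt,
            valley_levels=list(self.valley_levels),
            valley_rise=self.valley_rise,
        )


@dataclass
class ClassPreset:
    """Generative law of one agonist class's transient features.

    ``amp``/``dur`` are log-normal with the given mean and SD (dF/F
    units and seconds); the sub-peak count is ``1 + NegBinom`` matched
    to ``peaks_mean``/``peaks_var``.  ``n_responses`` is the class
    sample size of the emulated dataset.
    """

    label: str
    n_responses: int
    amp_mean: float
    amp_sd: float
    dur_mean: float
    dur_sd: float
    peaks_mean: float
    peaks_var: float
    # copula correlations: (amp,dur), (amp,peaks), (dur,peaks)
    rho: tuple[float, float, float] = (0.30, 0.50, 0.85)

    def __post_init__(self) -> None:
        if min(self.amp_mean, self.dur_mean, self.peaks_mean) <= 0:
            raise CalibrationError("preset means must be positive")
        if self.n_responses <= 0:
            raise CalibrationError("n_responses must be positive")
        if self.peaks_mean < 1:
            raise CalibrationError("mean sub-peak count must be >= 1")
        # a kernel must fit peaks_mean sub-peaks at minimum spacing inside
        # the middle span of a typical duration
        span = (1.0 - RISE_FRAC - TAIL_FRAC) * self.dur_mean
        if span < (self.peaks_mean - 1.0) * MIN_SUBPEAK_SPACING * 0.5:
            raise CalibrationError(
                f"dur_mean {self.dur_mean} too short to hold "
                f"{self.peaks_mean} sub-peaks"
            )

    # marginal inverse-CDFs used by the Gaussian copula ---------------
    def _lognorm_ppf(self, u, mean, sd):
        if sd == 0:
            return np.full_like(np.asarray(u, dtype=float), mean)
        s2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - 0.5 * s2
        return np.exp(mu + math.sqrt(s2) * stats.norm.ppf(u))

    def _count_ppf(self, u):
        mu = self.peaks_mean - 1.0
        if mu <= 0 or self.peaks_var == 0:
            return np.full_like(np.asarray(u, dtype=float), round(self.peaks_mean))
        var = self.peaks_var
        if var > mu:  # over-dispersed: negative binomial
            r = mu * mu / (var - mu)
            p = r / (r + mu)
            return 1.0 + stats.nbinom.ppf(u, r, p)
        return 1.0 + stats.poisson.ppf(u, mu)

    def draw_features(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw ``n`` (amplitude, duration, n_peaks) triples."""
        r_ad, r_ak, r_dk = self.rho
        corr = np.array([[1.0, r_ad, r_ak], [r_ad, 1.0, r_dk], [r_ak, r_dk, 1.0]])
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, 3)) @ chol.T
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        return pd.DataFrame(
            {
                "amplitude": self._lognorm_ppf(u[:, 0], self.amp_mean, self.amp_sd),
                "duration": self._lognorm_ppf(u[:, 1], self.dur_mean, self.dur_sd),
                "n_peaks": self._count_ppf(u[:, 2]).astype(int),
            }
        )


def preset_from_printed(
    label: str,
    n: int,
    amp_mean: float,
    amp_sem: float,
    dur_mean: float,
    dur_sem: float,
    peaks_mean: float,
    peaks_sem: float,
) -> ClassPreset:
    """Build a preset from printed group means and standard errors.

    SEMs are converted to population SDs by SEM*sqrt(n); the amplitude
    and duration SDs are clipped at their means (log-normal tails at
    CV > 1 produce implausible transients).
    """
    rt = math.sqrt(n)
    return ClassPreset(
        label=label,
        n_responses=n,
        amp_mean=amp_mean,
        amp_sd=min(amp_sem * rt, amp_mean),
        dur_mean=dur_mean,
        dur_sd=min(dur_sem * rt, dur_mean),
        peaks_mean=peaks_mean,
        peaks_var=(peaks_sem * rt) ** 2,
    )


#: agonist classes with printed group means/SEMs and sample sizes
CLASS_PRESETS: dict[str, ClassPreset] = {
    "capsaicin": preset_from_printed(
        "capsaicin", 200, 50.40, 4.007, 8.588, 0.3836, 5.965, 0.2634
    ),
    "glutamate": preset_from_printed(
        "glutamate", 102, 17.74, 1.627, 14.25, 0.7881, 4.814, 0.3979
    ),
    "aitc": preset_from_printed(
        "aitc", 51, 44.75, 5.518, 14.63, 1.130, 3.039, 0.3131
    ),
}


def _kernel_from_features(
    amp: float, dur: float, n_peaks: int, rng: np.random.Generator, onset: float = 0.0
) -> TransientKernel:
    """Realise a kernel with the given analytic amplitude/duration and
    (up to geometric feasibility) sub-peak count."""
    rise = RISE_FRAC * dur
    tail = TAIL_FRAC * dur
    span = dur - rise - tail
    k = int(n_peaks)
    if k > 1:
        k_max = 1 + int(span / MIN_SUBPEAK_SPACING)
        k = max(1, min(k, k_max))
    if k > 1:
        spacing = span / (k - 1)
        times = [onset + rise + i * spacing for i in range(k)]
        valley_rise = 0.3 * spacing
    else:
        times = [onset + rise]
        valley_rise = 0.0
    heights = [amp] + list(amp * rng.uniform(*SUB_AMP_RANGE, size=k - 1))
    valleys = [
        VALLEY_FRAC * min(heights[i], heights[i + 1]) for i in range(k - 1)
    ]
    L = (onset + dur) - times[-1]
    tau = L / math.log(1.0 / END_FLOOR_FRAC)
    return TransientKernel(
        onset=onset,
        subpeak_times=times,
        subpeak_amplitudes=heights,
        rise_time=rise,
        decay_tau=tau,
        end_time=onset + dur,
        valley_levels=valleys,
        valley_rise=valley_rise,
    )


def draw_kernel(preset: ClassPreset, rng_seed) -> TransientKernel:
    """Draw one transient kernel from a class preset."""
    rng = np.random.default_rng(rng_seed)
    return draw_kernels(preset, 1, rng)[0]


def draw_kernels(
    preset: ClassPreset, n: int, rng: np.random.Generator
) -> list[TransientKernel]:
    feats = preset.draw_features(n, rng)
    return [
        _kernel_from_features(a, d, k, rng)
        for a, d, k in zip(feats["amplitude"], feats["duration"], feats["n_peaks"])
    ]


@dataclass
class NoiseModel:
    """Stochastic nuisances of a 1P ganglion recording.

    ``trace_noise_sd`` is white noise on dF/F traces; the remaining
    fields shape the rendered movie: shot-like pixel noise, diffuse
    background with slow drift, breathing-locked global bumps, and rigid
    frame jitter.  Breathing sits in the anaesthetised range
    (100-150 breaths/min ~ 1.6-2.5 Hz).
    """

    trace_noise_sd: float = 0.5  # DFF units
    photon_noise_sd: float = 3.0  # a.u. (~1% of background)
    background_level: float = 400.0  # a.u.
    background_drift: float = 0.2  # a.u./s
    breathing_rate: float = 2.0  # Hz
    artifact_prob_per_min: float = 2.0
    artifact_gain: float = 25.0  # DFF units
    artifact_fraction: float = 0.6  # fraction of neurons hit per event
    jitter_sd: float = 1.0  # px

    def __post_init__(self) -> None:
        vals = [
            self.trace_noise_sd, self.photon_noise_sd, self.background_level,
            self.background_drift, self.breathing_rate,
            self.artifact_prob_per_min, self.artifact_gain, self.jitter_sd,
        ]
        if min(vals) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 0 < self.artifact_fraction <= 1:
            raise ValueError("artifact_fraction must be in (0, 1]")


@dataclass
class SyntheticNeuron:
    """A soma at ``centroid`` (row, col px) with assigned kernels."""

    centroid: tuple[float, float]
    diameter: float = 12.0
    baseline_brightness: float = 300.0
    kernels: list[TransientKernel] = field(default_factory=list)
    responder_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


def render_trace(
    kernels: list[TransientKernel],
    n_frames: int,
    fps: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    baseline: float = 0.0,
) -> np.ndarray:
    """Sum of kernel waveforms + baseline + white noise, sampled at fps.

    Kernels extending past the last frame are truncated with a warning.
    """
    t = np.arange(n_frames) / fps
    y = np.full(n_frames, baseline, dtype=np.float64)
    t_max = (n_frames - 1) / fps
    for k in kernels:
        if k.end_time > t_max:
            import warnings

            warnings.warn(
                f"kernel ending at {k.end_time:.1f}s truncated at {t_max:.1f}s",
                stacklevel=2,
            )
        lo = max(0, int(math.floor(k.onset * fps)))
        hi = min(n_frames, int(math.ceil(k.end_time * fps)) + 1)
        if hi > lo:
            y[lo:hi] += k.evaluate(t[lo:hi])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        y += rng.normal(0.0, noise_sd, size=n_frames)
    return y


def _artifact_kernel(t0: float, gain: float) -> TransientKernel:
    """Short sharp global bump standing in for a breathing jolt."""
    return TransientKernel(
        onset=t0,
        subpeak_times=[t0 + 0.15],
        subpeak_amplitudes=[gain],
        rise_time=0.15,
        decay_tau=(0.85 - 0.15) / math.log(1.0 / END_FLOOR_FRAC),
        end_time=t0 + 0.85,
    )


def render_trace_set(
    kernels_per_neuron: list[list[TransientKernel]],
    n_frames: int,
    fps: float,
    noise: NoiseModel,
    rng: np.random.Generator,
    duration_s: float | None = None,
    inject_artifacts: bool = False,
) -> tuple[np.ndarray, dict]:
    """Render an N x T dF/F trace matrix; optionally inject coincident
    global artifact bumps in a random >= ``artifact_fraction`` subset of
    neurons at Poisson-scheduled times.  Returns (traces, truth)."""
    n = len(kernels_per_neuron)
    dur = (n_frames - 1) / fps if duration_s is None else duration_s
    artifact_times: list[float] = []
    hit_sets: list[np.ndarray] = []
    extra: list[list[TransientKernel]] = [[] for _ in range(n)]
    if inject_artifacts and noise.artifact_prob_per_min > 0:
        n_art = rng.poisson(noise.artifact_prob_per_min * dur / 60.0)
        for _ in range(n_art):
            t0 = rng.uniform(2.0, dur - 2.0)
            hit = rng.permutation(n)[: max(1, int(round(noise.artifact_fraction * n)))]
            for i in hit:
                extra[i].append(_artifact_kernel(t0, noise.artifact_gain))
            artifact_times.append(t0)
            hit_sets.append(np.sort(hit))
    traces = np.empty((n, n_frames))
    for i, ks in enumerate(kernels_per_neuron):
        traces[i] = render_trace(
            ks + extra[i], n_frames, fps, noise.trace_noise_sd, rng
        )
    order = np.argsort(artifact_times) if artifact_times else []
    truth = {
        "artifact_times": np.array([artifact_times[i] for i in order]),
        "artifact_hits": [hit_sets[i] for i in order],
    }
    return traces, truth


def gaussian_footprint(
    shape: tuple[int, int], centroid: tuple[float, float], diameter: float
) -> np.ndarray:
    """2-D Gaussian soma profile (sigma = diameter/4), truncated at one
    diameter from the centre and peak-normalised."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    r2 = (yy - centroid[0]) ** 2 + (xx - centroid[1]) ** 2
    sig = diameter / 4.0
    fp = np.exp(-r2 / (2.0 * sig * sig))
    fp[r2 > diameter * diameter] = 0.0
    return fp


def render_movie(
    neurons: list[SyntheticNeuron],
    schedule: StimulusSchedule,
    noise: NoiseModel,
    dims: tuple[int, int] = (376, 240),
    fps: float = 20.0,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
    dff_scale: float = 100.0,
) -> tuple[Movie, dict]:
    """Render a raw-fluorescence movie plus ground truth.

    Each neuron is a Gaussian footprint whose brightness follows
    ``b * (1 + dff/dff_scale)``; a diffuse drifting background and
    shot-like noise are added, breathing artifacts are injected as
    coincident dF/F bumps, and recorded integer rigid jitter is applied
    per frame.
    """
    if not neurons:
        raise ValueError("need at least one neuron")
    H, W = dims
    dmax = max(nr.diameter for nr in neurons)
    if H < 2 * dmax or W < 2 * dmax:
        raise ValueError(f"dims {dims} too small for neuron diameter {dmax}")
    rng = np.random.default_rng(rng)
    if duration_s is None:
        last = schedule.events[-1].onset + 150.0 if schedule.events else 120.0
        duration_s = last
    T = int(round(duration_s * fps))
    t = np.arange(T) / fps

    traces, art_truth = render_trace_set(
        [nr.kernels for nr in neurons],
        T,
        fps,
        noise,
        rng,
        duration_s=duration_s,
        inject_artifacts=True,
    )
    footprints = np.stack(
        [gaussian_footprint((H, W), nr.centroid, nr.diameter) for nr in neurons]
    )
    background = noise.background_level + noise.background_drift * t  # per frame
    bright = np.array([nr.baseline_brightness for nr in neurons])
    # soma brightness over time, N x T
    soma = bright[:, None] * (1.0 + traces / dff_scale)

    shifts = np.zeros((T, 2), dtype=int)
    if noise.jitter_sd > 0:
        shifts = np.round(rng.normal(0.0, noise.jitter_sd, size=(T, 2))).astype(int)

    data = np.empty((T, H, W), dtype=np.float64)
    flat_fp = footprints.reshape(len(neurons), -1)
    for f in range(T):
        frame = np.full(H * W, background[f])
        frame += soma[:, f] @ flat_fp
        frame = frame.reshape(H, W)
        dy, dx = shifts[f]
        if dy or dx:
            frame = np.roll(frame, (dy, dx), axis=(0, 1))
        if noise.photon_noise_sd > 0:
            frame += rng.normal(0.0, noise.photon_noise_sd, size=(H, W))
        data[f] = frame
    truth = {
        "traces": traces,
        "footprints": footprints,
        "centroids": np.array([nr.centroid for nr in neurons]),
        "shifts": shifts.astype(float),
        "artifact_times": art_truth["artifact_times"],
        "artifact_hits": art_truth["artifact_hits"],
        "dff_scale": dff_scale,
    }
    return Movie(data=data, fps=fps, scale_tag="raw"), truth


# ---------------------------------------------------------------------------
# fixture I/O

CHUNK_FRAMES = 1000


def write_fixture(movie: Movie, truth: dict, outdir: str | Path) -> list[Path]:
    """Save a movie as consecutive 1000-frame 16-bit TIFF chunks plus the
    ground truth (kernel log CSV + HDF5 arrays).  Returns written paths."""
    import tifffile
    import h5py

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = movie.data
    if not np.all(np.isfinite(data)):
        raise ValueError("movie must be finite-valued")
    lo, hi = data.min(), data.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    enc = np.round((data - lo) * scale).astype(np.uint16)
    paths = []
    for c in range(0, enc.shape[0], CHUNK_FRAMES):
        p = outdir / f"movie_chunk{c // CHUNK_FRAMES:03d}.tif"
        tmp = p.with_suffix(".tif.part")
        tifffile.imwrite(tmp, enc[c : c + CHUNK_FRAMES])
        tmp.rename(p)  # no stale partial chunk on failure
        paths.append(p)
    meta = outdir / "fixture_meta.h5"
    with h5py.File(meta, "w") as h5:
        h5.attrs["fps"] = movie.fps
        h5.attrs["encode_offset"] = float(lo)
        h5.attrs["encode_scale"] = float(scale)
        for key in ("traces", "footprints", "centroids", "shifts", "artifact_times"):
            if key in truth:
                h5.create_dataset(key, data=np.asarray(truth[key]))
    paths.append(meta)
    return paths


def read_fixture(outdir: str | Path) -> tuple[Movie, dict]:
    """Read back a chunked fixture written by :func:`write_fixture`."""
    import tifffile
    import h5py

    outdir = Path(outdir)
    chunks = sorted(outdir.glob("movie_chunk*.tif"))
    if not chunks:
        raise FileNotFoundError(f"no movie chunks under {outdir}")
    data = np.concatenate([tifffile.imread(p) for p in chunks], axis=0)
    truth: dict = {}
    with h5py.File(outdir / "fixture_meta.h5", "r") as h5:
        fps = float(h5.attrs["fps"])
        off = float(h5.attrs["encode_offset"])
        scale = float(h5.attrs["encode_scale"])
        for key in h5:
            truth[key] = h5[key][...]
    movie = Movie(data=data.astype(np.float64) / scale + off, fps=fps)
    return movie, truth


def make_movie_fixture(
    seed,
    n_neurons: int = 10,
    dims: tuple[int, int] = (96, 72),
    fps: float = 20.0,
    duration_s: float = 90.0,
    noise: NoiseModel | None = None,
    stimulus_onset: float = 40.0,
) -> tuple[Movie, dict, StimulusSchedule]:
    """Default movie fixture: visibly active somata on a jittered grid.

    Emulates the population a user would keep after ROI review: each
    neuron fires one clear transient (amplitude floored well above the
    noise floor, duration shorter than the dF/F baseline bin so the
    binned-percentile baseline stays faithful) at a random latency
    after the stimulus.  Ground truth carries footprints, traces,
    shifts and artifact times.
    """
    rng = np.random.default_rng(seed)
    noise = noise or NoiseModel()
    H, W = dims
    # jittered grid placement, >= ~1.5 diameters apart
    pitch = 20
    rows = range(pitch // 2 + 4, H - pitch // 2 - 2, pitch)
    cols = range(pitch // 2 + 4, W - pitch // 2 - 2, pitch)
    sites = [(float(r), float(c)) for r in rows for c in cols]
    if len(sites) < n_neurons:
        raise ValueError(f"dims {dims} hold only {len(sites)} neurons at {pitch}px pitch")
    sites = [sites[i] for i in rng.permutation(len(sites))[:n_neurons]]
    neurons = []
    for y, x in sites:
        amp = max(15.0, rng.lognormal(math.log(40.0), 0.4))
        dur = rng.uniform(2.5, 4.5)
        k = _kernel_from_features(amp, dur, int(rng.integers(1, 4)), rng)
        t0 = stimulus_onset + rng.uniform(1.0, duration_s - stimulus_onset - dur - 2.0)
        neurons.append(
            SyntheticNeuron(
                centroid=(y + rng.uniform(-2, 2), x + rng.uniform(-2, 2)),
                kernels=[k.shifted(t0)],
                responder_labels=["stim"],
            )
        )
    schedule = StimulusSchedule(
        events=[
            StimulusEvent(
                "stim",
                stimulus_onset,
                post_window=duration_s - stimulus_onset,
                pre_window=stimulus_onset,
            )
        ],
        baseline_duration=min(35.0, stimulus_onset),
        fps=fps,
    )
    movie, truth = render_movie(
        neurons, schedule, noise, dims=dims, fps=fps, duration_s=duration_s, rng=rng
    )
    return movie, truth, schedule


def make_class_traces(
    preset: ClassPreset,
    seed,
    fps: float = 20.0,
    baseline_s: float = 60.0,
    window_s: float = 150.0,
    noise: NoiseModel | None = None,
    n: int | None = None,
) -> tuple[np.ndarray, StimulusSchedule, pd.DataFrame]:
    """One-response-per-neuron trace fixture for a single agonist class.

    Each of ``n`` neurons carries one kernel drawn from the preset, with
    onset uniform in the first 20 s after the stimulus.  Returns the
    N x T dF/F matrix, the schedule (single event after the quiet
    baseline) and a ground-truth table of analytic kernel features.
    """
    rng = np.random.default_rng(seed)
    noise = noise or NoiseModel()
    n = preset.n_responses if n is None else n
    onset = baseline_s
    T = int(round((baseline_s + window_s + 60.0) * fps))
    kernels = draw_kernels(preset, n, rng)
    placed = [
        [k.shifted(onset + rng.uniform(0.5, 20.0))] for k in kernels
    ]
    traces, _ = render_trace_set(placed, T, fps, noise, rng, inject_artifacts=False)
    rows = []
    for i, ks in enumerate(placed):
        f = ks[0].analytic_features()
        f["roi_id"] = f"roi{i:04d}"
        f["onset"] = ks[0].onset
        rows.append(f)
    truth = pd.DataFrame(rows)
    schedule = StimulusSchedule(
        events=[
            StimulusEvent(
                label=preset.label,
                onset=onset,
                post_window=100.0,
                pre_window=min(100.0, onset),
            )
        ],
        baseline_duration=baseline_s,
        fps=fps,
    )
    return traces, schedule, truth
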