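"""Naive reference implementations used as independent oracles.

Everything here is written as plain, slow, loop-based code so the
vectorised/library-backed package paths can be checked against an
independent route: threshold-run scanning with explicit loops, dense
numerical features, topographic prominence by outward search, and
Kruskal-Wallis p by permutation enumeration.
"""
from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def naive_baseline(trace, fps, window):
    lo = int(round(window[0] * fps))
    hi = int(round(window[1] * fps))
    seg = trace[lo:hi]
    return float(np.mean(seg)), float(np.std(seg))


def naive_detect(trace, fps, params):
    """Loop-based event scan mirroring the documented semantics:
    suprathreshold runs -> gap/bridge merge -> minimum suprathreshold
    sample count -> outward extension to baseline-mean crossings."""
    trace = np.asarray(trace, dtype=float)
    mean, sd = naive_baseline(trace, fps, params.baseline_window)
    theta = mean + params.k_sd * sd
    T = len(trace)
    runs = []
    i = 0
    while i < T:
        if trace[i] >= theta:
            j = i
            while j + 1 < T and trace[j + 1] >= theta:
                j += 1
            runs.append([i, j + 1])
            i = j + 1
        else:
            i += 1
    merged = []
    for r in runs:
        if merged:
            gap_lo, gap_hi = merged[-1][1], r[0]
            bridged = all(trace[k] > mean for k in range(gap_lo, gap_hi))
            if (gap_hi - gap_lo) < params.gap_merge * fps or bridged:
                merged[-1][1] = r[1]
                continue
        merged.append(list(r))
    keep = []
    for a, b in merged:
        n_above = sum(1 for k in range(a, b) if trace[k] >= theta)
        if n_above >= params.min_event_s * fps:
            keep.append((a, b))
    events = []
    for a, b in keep:
        s = a
        while s > 0 and trace[s - 1] > mean:
            s -= 1
        e = b - 1
        while e < T - 1 and trace[e + 1] > mean:
            e += 1
        p = max(range(a, b), key=lambda k: trace[k])
        if e <= s:
            e = s + 1 if s + 1 < T else s
        events.append((s, p, e))
    return events, mean, sd, theta


def naive_features(trace, fps, s, p, e, mean):
    """Dense-resampling-free but independent feature computation:
    explicit trapezoid sum and slope arithmetic."""
    dt = 1.0 / fps
    amp = trace[p] - mean
    dur = (e - s) * dt
    area = 0.0
    for k in range(s, e):
        y0 = max(trace[k] - mean, 0.0)
        y1 = max(trace[k + 1] - mean, 0.0)
        area += 0.5 * (y0 + y1) * dt
    if p > s:
        rise = (trace[p] - trace[s]) / ((p - s) * dt)
    else:
        nxt = min(p + 1, len(trace) - 1)
        rise = abs(trace[nxt] - trace[p]) / dt
    if e > p:
        decay = abs(trace[e] - trace[p]) / ((e - p) * dt)
    else:
        prv = max(p - 1, 0)
        decay = abs(trace[p] - trace[prv]) / dt
    return amp, dur, area, max(rise, 0.0), decay


def naive_gaussian_smooth(x, sigma):
    """Direct convolution with a truncated Gaussian (matches
    scipy.ndimage.gaussian_filter1d defaults: truncate=4, 'nearest')."""
    if sigma <= 0:
        return np.asarray(x, dtype=float)
    radius = int(4.0 * sigma + 0.5)
    kk = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    kk /= kk.sum()
    padded = np.concatenate(
        [np.full(radius, x[0]), np.asarray(x, dtype=float), np.full(radius, x[-1])]
    )
    return np.convolve(padded, kk, mode="valid")


def naive_prominence(seg, i):
    """Topographic prominence of local max i by outward search."""
    h = seg[i]
    left_min = h
    k = i - 1
    while k >= 0 and seg[k] <= h:
        left_min = min(left_min, seg[k])
        k -= 1
    if k < 0:
        left_base = min(seg[: i + 1])
    else:
        left_base = left_min
    right_min = h
    k = i + 1
    while k < len(seg) and seg[k] <= h:
        right_min = min(right_min, seg[k])
        k += 1
    if k >= len(seg):
        right_base = min(seg[i:])
    else:
        right_base = right_min
    return h - max(left_base, right_base)


def naive_count_subpeaks(trace, fps, s, e, theta, prominence, min_sep, smooth_s):
    """Local maxima above theta, height-priority distance filtering,
    then prominence thresholding (the documented scan order)."""
    seg = naive_gaussian_smooth(np.asarray(trace, dtype=float)[s : e + 1], smooth_s * fps)
    n = len(seg)
    cand = [i for i in range(1, n - 1) if seg[i - 1] < seg[i] > seg[i + 1]]
    cand = [i for i in cand if seg[i] >= theta]
    # distance filter, highest first
    dist = max(1, int(round(min_sep * fps)))
    keep = set(cand)
    for i in sorted(cand, key=lambda i: -seg[i]):
        if i not in keep:
            continue
        for j in cand:
            if j != i and j in keep and abs(j - i) < dist and seg[j] <= seg[i]:
                keep.discard(j)
    out = [i for i in keep if naive_prominence(seg, i) >= prominence]
    return max(1, len(out))


def naive_responder(pre_max, post_max, ratio=0.5):
    """The selectivity rule verbatim: responds iff a post-window maximum
    exists and the pre-window maximum is not greater than ratio x it."""
    if post_max is None:
        return False
    return not (pre_max > ratio * post_max)


def kw_h_statistic(groups):
    """Tie-corrected Kruskal-Wallis H from first principles."""
    pooled = [v for g in groups for v in g]
    N = len(pooled)
    order = sorted(range(N), key=lambda i: pooled[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j + 1 < N and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    # ties
    from collections import Counter

    ties = sum(c**3 - c for c in Counter(pooled).values())
    denom = 1 - ties / (N**3 - N)
    return 0.0 if denom <= 0 else h / denom


def kw_permutation_p(groups):
    """Exact p by full enumeration over distinct group assignments."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = kw_h_statistic(groups)
    seen = set()
    total = hits = 0
    for perm in permutations(range(len(pooled))):
        key = []
        start = 0
        for s in sizes:
            key.append(tuple(sorted(perm[start : start + s])))
            start += s
        key = tuple(key)
        if key in seen:
            continue
        seen.add(key)
        arranged = [pooled[i] for i in perm]
        gs = []
        start = 0
        for s in sizes:
            gs.append(arranged[start : start + s])
            start += s
        total += 1
        if kw_h_statistic(gs) >= h_obs - 1e-12:
            hits += 1
    return hits / total
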