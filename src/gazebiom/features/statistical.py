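"""Basic statistical (93) and pupillary response (8) features.

Eleven event metrics (fixation duration/dispersion; saccade duration,
amplitude, velocity, latency, acceleration, acceleration peak, deceleration
peak, velocity peak; blink duration) are each summarized by eight statistics
(mean, sd, median, max, min, 1/4 and 3/4 quantile, skewness), plus five
scalar features: fixation/saccade/blink frequency (events per second),
scanpath convex-hull area and scanpath length — 11 x 8 + 5 = 93 features.

Pupillary response features are the same eight statistics of the per-sample
mean of the left and right pupil diameters (mm); when raw samples are not
available, the fixations' mean pupil values stand in.

Segments without events yield all-zero blocks (dense input for the forest),
and quantiles use linear interpolation; saccade metric units are
scene-camera pixels (no angular calibration model is available).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from ..segmentation import Segment

STAT_NAMES: tuple[str, ...] = (
    "mean", "sd", "median", "max", "min", "q1", "q3", "skew")

_METRICS: tuple[str, ...] = (
    "fix_duration", "fix_dispersion",
    "sacc_duration", "sacc_amplitude", "sacc_velocity", "sacc_latency",
    "sacc_acceleration", "sacc_acceleration_peak", "sacc_deceleration_peak",
    "sacc_velocity_peak",
    "blink_duration",
)

_SCALARS: tuple[str, ...] = (
    "fixation_freq", "saccade_freq", "blink_freq",
    "scanpath_hull_area", "scanpath_length",
)

BASIC_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{m}_{s}" for m in _METRICS for s in STAT_NAMES) + _SCALARS

PUPIL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"pupil_{s}" for s in STAT_NAMES)


def compute_stats8(values) -> np.ndarray:
    """Eight summary statistics of a value list, in STAT_NAMES order.

    sd uses the n-1 denominator (0 for n < 2); skewness is the biased
    Fisher-Pearson g1 = m3 / m2^1.5 (0 for n < 3 or zero variance); empty
    input yields the zero vector.  Non-finite entries are dropped.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        return np.zeros(8)
    sd = float(v.std(ddof=1)) if n >= 2 else 0.0
    m2 = float(((v - v.mean()) ** 2).mean())
    if n >= 3 and m2 > 0:
        m3 = float(((v - v.mean()) ** 3).mean())
        skew = m3 / m2**1.5
    else:
        skew = 0.0
    return np.array([
        float(v.mean()), sd, float(np.median(v)), float(v.max()),
        float(v.min()), float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)), skew,
    ])


def scanpath_length(fixations) -> float:
    """Summed Euclidean distance between consecutive fixation centroids."""
    if len(fixations) < 2:
        return 0.0
    pts = np.array([[f.cx, f.cy] for f in fixations])
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def convex_hull_area(fixations) -> float:
    """Area of the convex hull of fixation centroids (0 if degenerate)."""
    if len(fixations) < 3:
        return 0.0
    pts = np.array([[f.cx, f.cy] for f in fixations])
    try:
        return float(ConvexHull(pts).volume)  # 2-D: volume is the area
    except QhullError:
        return 0.0  # collinear or coincident points


def basic_features(segment: Segment) -> pd.Series:
    metric_values = {
        "fix_duration": [f.duration for f in segment.fixations],
        "fix_dispersion": [f.dispersion for f in segment.fixations],
        "sacc_duration": [s.duration for s in segment.saccades],
        "sacc_amplitude": [s.amplitude for s in segment.saccades],
        "sacc_velocity": [s.mean_velocity for s in segment.saccades],
        "sacc_latency": [s.latency for s in segment.saccades
                         if math.isfinite(s.latency)],
        "sacc_acceleration": [s.mean_acceleration for s in segment.saccades],
        "sacc_acceleration_peak": [s.peak_acceleration
                                   for s in segment.saccades],
        "sacc_deceleration_peak": [s.peak_deceleration
                                   for s in segment.saccades],
        "sacc_velocity_peak": [s.peak_velocity for s in segment.saccades],
        "blink_duration": [b.duration for b in segment.blinks],
    }
    out = np.empty(len(BASIC_FEATURE_NAMES))
    k = 0
    for m in _METRICS:
        out[k:k + 8] = compute_stats8(metric_values[m])
        k += 8
    t_win = segment.t_win
    out[k:] = [
        len(segment.fixations) / t_win,
        len(segment.saccades) / t_win,
        len(segment.blinks) / t_win,
        convex_hull_area(segment.fixations),
        scanpath_length(segment.fixations),
    ]
    return pd.Series(out, index=list(BASIC_FEATURE_NAMES))


def pupil_features(segment: Segment) -> pd.Series:
    """Eight statistics of the mean left/right pupil diameter in the window."""
    if segment.samples is not None and len(segment.samples):
        s = segment.samples
        valid = s["valid"].to_numpy(bool)
        trace = ((s["pupil_l"].to_numpy(float)
                  + s["pupil_r"].to_numpy(float)) / 2.0)[valid]
    else:
        trace = [f.mean_pupil for f in segment.fixations]
    return pd.Series(compute_stats8(trace), index=list(PUPIL_FEATURE_NAMES))


__all__ = [
    "STAT_NAMES", "BASIC_FEATURE_NAMES", "PUPIL_FEATURE_NAMES",
    "compute_stats8", "scanpath_length", "convex_hull_area",
    "basic_features", "pupil_features",
]
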