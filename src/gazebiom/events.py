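"""Dispersion-threshold (I-DT) event detection from raw gaze samples.

For users supplying raw 60 Hz samples rather than pre-detected event tables.
Fixations are maximal sample windows whose bounding-box dispersion
(max x - min x) + (max y - min y) stays under a pixel threshold for at least
a minimum duration; runs of invalid samples at least ``min_blink_gap`` long
are blinks; the remaining inter-fixation intervals become saccades whose
amplitude/direction come from the fixation centroids and whose kinematics
come from finite differences of the samples.

At 60 Hz, velocity thresholds are noisy (one sample = 16.7 ms), which is why
a dispersion criterion is used rather than I-VT.  Saccade latency is defined
as the time since the previous saccade's offset; continuous real-world
viewing has no stimulus onset to anchor a conventional latency, so this is a
stand-in convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Blink, Fixation, Saccade, SceneGeometry


@dataclass(frozen=True)
class DetectorConfig:
    dispersion_threshold: float = 50.0   # px, bounding-box sum
    min_fixation_duration: float = 0.080  # s
    min_blink_gap: float = 0.070          # s

    def __post_init__(self) -> None:
        if min(self.dispersion_threshold, self.min_fixation_duration,
               self.min_blink_gap) <= 0:
            raise ValueError("detector thresholds must be positive")


def _bbox_dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return float((x.max() - x.min()) + (y.max() - y.min()))


def detect_events(
    samples: pd.DataFrame,
    config: DetectorConfig | None = None,
    geometry: SceneGeometry | None = None,
) -> tuple[list[Fixation], list[Saccade], list[Blink]]:
    """Classify time-sorted raw samples into fixations, saccades and blinks."""
    config = config or DetectorConfig()
    geometry = geometry or SceneGeometry()
    dt = 1.0 / geometry.sampling_rate_hz

    t = samples["t"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be time-sorted")
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    valid = samples["valid"].to_numpy(bool)
    pupil = (samples["pupil_l"].to_numpy(float)
             + samples["pupil_r"].to_numpy(float)) / 2.0

    if valid.sum() < 2:
        return [], [], []

    # blinks: maximal runs of invalid samples spanning >= min_blink_gap
    blinks: list[Blink] = []
    i = 0
    n = len(t)
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            onset, offset = t[i], (t[j - 1] + dt)
            if offset - onset >= config.min_blink_gap:
                blinks.append(Blink(onset, offset))
            i = j
        else:
            i += 1

    # I-DT over valid samples: grow a window while dispersion stays under
    # threshold; accept as fixation if it spans the minimum duration
    vidx = np.flatnonzero(valid)
    fixations: list[Fixation] = []
    fix_member: list[np.ndarray] = []
    i = 0
    m = len(vidx)
    while i < m:
        j = i + 1
        while j <= m:
            win = vidx[i:j]
            if _bbox_dispersion(x[win], y[win]) > config.dispersion_threshold:
                break
            j += 1
        j -= 1  # last size that satisfied the threshold
        win = vidx[i:j]
        if j > i and t[win[-1]] + dt - t[win[0]] >= config.min_fixation_duration:
            fixations.append(Fixation(
                onset=float(t[win[0]]),
                offset=float(t[win[-1]] + dt),
                cx=float(x[win].mean()), cy=float(y[win].mean()),
                dispersion=_bbox_dispersion(x[win], y[win]),
                mean_pupil=float(pupil[win].mean()),
            ))
            fix_member.append(win)
            i = j
        else:
            i += 1

    # saccades: inter-fixation intervals that are not blink-dominated
    saccades: list[Saccade] = []
    prev_sacc_offset = np.nan
    for a, b, wa, wb in zip(fixations, fixations[1:], fix_member,
                            fix_member[1:]):
        onset, offset = a.offset, b.onset
        if offset - onset <= 0:
            continue
        if any(bl.onset < offset and bl.offset > onset for bl in blinks):
            continue
        dx, dy = b.cx - a.cx, b.cy - a.cy
        amplitude = float(np.hypot(dx, dy))
        direction = float(np.arctan2(-dy, dx))  # screen-up positive
        seg = np.arange(wa[-1], wb[0] + 1)
        seg = seg[valid[seg]]
        if len(seg) >= 2:
            vx = np.diff(x[seg]) / np.diff(t[seg])
            vy = np.diff(y[seg]) / np.diff(t[seg])
            speed = np.hypot(vx, vy)
            mean_v = float(speed.mean())
            peak_v = float(speed.max())
            if len(speed) >= 2:
                acc = np.diff(speed) / np.diff(t[seg][:-1] + np.diff(t[seg]) / 2)
                mean_acc = float(np.abs(acc).mean())
                peak_acc = float(acc.max()) if np.any(acc > 0) else 0.0
                peak_dec = float(-acc.min()) if np.any(acc < 0) else 0.0
            else:
                mean_acc = peak_acc = peak_dec = 0.0
        else:
            mean_v = amplitude / (offset - onset)
            peak_v = mean_v
            mean_acc = peak_acc = peak_dec = 0.0
        peak_v = max(peak_v, mean_v)
        saccades.append(Saccade(
            onset=float(onset), offset=float(offset),
            amplitude=amplitude, direction=direction,
            mean_velocity=mean_v, peak_velocity=peak_v,
            mean_acceleration=mean_acc, peak_acceleration=peak_acc,
            peak_deceleration=peak_dec,
            latency=float(onset - prev_sacc_offset),
        ))
        prev_sacc_offset = offset

    return fixations, saccades, blinks


__all__ = ["DetectorConfig", "detect_events"]
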