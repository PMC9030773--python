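"""Fixation semantic features: per-class fixation count and duration.

Each fixation carries one scene-semantic class out of the 19 street-scene
classes plus 'map' (the handheld paper map).  Per segment, FC[class] counts
fixations and FD[class] sums fixation durations in milliseconds — 2 x 20 =
40 features.  Because a class that dominates the scene attracts gaze
regardless of who is looking, both can be divided by N_pixel[class], the
mean number of pixels that class occupies across the route's video frames,
which neutralizes scene crowding; the adjusted variant is what feeds the
classifier by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..data_model import (
    SEMANTIC_CLASSES,
    Fixation,
    FixationSemanticLabel,
    RoutePixelStats,
    ValidationError,
)
from ..segmentation import Segment

logger = logging.getLogger(__name__)


def _slug(c: str) -> str:
    return c.replace(" ", "_")


SEMANTIC_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"fc_{_slug(c)}" for c in SEMANTIC_CLASSES) + tuple(
    f"fd_{_slug(c)}" for c in SEMANTIC_CLASSES)


def semantic_features_raw(
    segment: Segment,
    labels: dict[int, str] | list[FixationSemanticLabel],
) -> pd.Series:
    """FC (count) and FD (ms) per class over the segment's fixations.

    ``labels`` maps recording-level fixation indices to class names (or is a
    list of FixationSemanticLabel).  Fixations labeled 'unknown' or missing
    a label are excluded from the 20 counters and logged.
    """
    if not isinstance(labels, dict):
        labels = {lab.fixation_index: lab.class_label for lab in labels}
    fc = dict.fromkeys(SEMANTIC_CLASSES, 0.0)
    fd = dict.fromkeys(SEMANTIC_CLASSES, 0.0)
    n_unlabeled = 0
    for idx, fix in zip(segment.fixation_indices, segment.fixations):
        cls = labels.get(idx, "unknown")
        if cls == "unknown":
            n_unlabeled += 1
            continue
        if cls not in fc:
            raise ValidationError(f"label {cls!r} outside the 20-class vocabulary")
        fc[cls] += 1
        fd[cls] += fix.duration * 1000.0
    if n_unlabeled:
        logger.info("segment %s/%s#%d: %d unlabeled fixation(s) excluded",
                    segment.subject_id, segment.route_id,
                    segment.segment_index, n_unlabeled)
    values = [fc[c] for c in SEMANTIC_CLASSES] + [fd[c] for c in SEMANTIC_CLASSES]
    return pd.Series(values, index=list(SEMANTIC_FEATURE_NAMES))


def adjust_semantic_features(
    raw: pd.Series, route_pixel_stats: RoutePixelStats
) -> pd.Series:
    """Divide each FC/FD by the class's N_pixel (0 where N_pixel = 0)."""
    out = raw.copy()
    for c in SEMANTIC_CLASSES:
        npx = route_pixel_stats.n_pixel[c]
        for prefix in ("fc", "fd"):
            key = f"{prefix}_{_slug(c)}"
            out[key] = raw[key] / npx if npx > 0 else 0.0
    return out


@dataclass(frozen=True)
class FrameLabels:
    """Per-frame class rasters of a scene video.

    ``times`` are frame timestamps (s); ``rasters`` is one (H, W) integer
    array per frame indexing ``class_names``; ``map_flags`` marks frames
    where the handheld map was detected, with ``map_region`` its bounding
    box (x0, y0, x1, y1) in frame pixels.
    """

    times: np.ndarray
    rasters: list[np.ndarray]
    class_names: tuple[str, ...]
    map_flags: np.ndarray | None = None
    map_region: tuple[float, float, float, float] | None = None


def annotate_fixations(
    fixations: list[Fixation],
    frame_labels: FrameLabels | list[FixationSemanticLabel],
    map_flags=None,
) -> list[FixationSemanticLabel]:
    """Attach a semantic class to every fixation.

    Passthrough mode: precomputed per-fixation labels are returned as-is.
    Raster mode: the label is the class of the pixel under the fixation
    centroid in the frame nearest the fixation's temporal midpoint; if that
    frame's map flag is set and the centroid falls inside the map region,
    the label is 'map' regardless of the raster.  Fixations whose midpoint
    falls outside the covered frame times get 'unknown'.
    """
    if not isinstance(frame_labels, FrameLabels):
        return list(frame_labels)
    fl = frame_labels
    out = []
    t0, t1 = float(fl.times.min()), float(fl.times.max())
    half_step = (np.diff(np.sort(fl.times)).max() / 2
                 if len(fl.times) > 1 else np.inf)
    for i, fix in enumerate(fixations):
        mid = (fix.onset + fix.offset) / 2
        if mid < t0 - half_step or mid > t1 + half_step:
            out.append(FixationSemanticLabel(i, "unknown"))
            continue
        k = int(np.argmin(np.abs(fl.times - mid)))
        if (fl.map_flags is not None and fl.map_flags[k]
                and fl.map_region is not None):
            x0, y0, x1, y1 = fl.map_region
            if x0 <= fix.cx <= x1 and y0 <= fix.cy <= y1:
                out.append(FixationSemanticLabel(i, "map"))
                continue
        raster = fl.rasters[k]
        col = int(np.clip(fix.cx, 0, raster.shape[1] - 1))
        row = int(np.clip(fix.cy, 0, raster.shape[0] - 1))
        out.append(FixationSemanticLabel(i, fl.class_names[raster[row, col]]))
    return out


__all__ = [
    "SEMANTIC_FEATURE_NAMES", "FrameLabels",
    "semantic_features_raw", "adjust_semantic_features", "annotate_fixations",
]
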