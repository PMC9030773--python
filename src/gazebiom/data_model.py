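"""Core domain types, CSV readers/writers, and recording-level quality filtering.

The in-memory model mirrors what a wearable eye tracker exports after event
detection: a time-ordered stream of fixations, saccades and blinks per
(subject, route) recording, optionally backed by the raw 60 Hz gaze samples.
Coordinates are scene-camera pixels with the image convention (origin
top-left, y increasing downward); time is seconds from recording start.

Event tables are a single CSV with a ``type`` discriminator column, mirroring
single-file event exports of commercial analysis software.  Samples tables
carry one row per gaze sample.  See :data:`SAMPLE_COLUMNS` and
:data:`EVENT_COLUMNS_MANDATORY` for the schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 19 Cityscapes object classes plus 'map' (a handheld paper map).
SEMANTIC_CLASSES: tuple[str, ...] = (
    "road", "sidewalk", "building", "wall", "fence", "pole",
    "traffic light", "traffic sign", "vegetation", "terrain", "sky",
    "person", "rider", "car", "truck", "bus", "train", "motorcycle",
    "bicycle", "map",
)

SAMPLE_COLUMNS = ("t", "x", "y", "pupil_l", "pupil_r", "valid")
EVENT_COLUMNS_MANDATORY = ("type", "onset", "offset")

#: Keys every feature table row carries in addition to the feature columns.
FEATURE_KEY_COLUMNS = ("subject_id", "route_id", "segment_id", "window_size")


class FormatError(ValueError):
    """A table is missing mandatory columns or is otherwise malformed."""


class ValidationError(ValueError):
    """A table parsed but violates a domain invariant (e.g. unsorted time)."""


@dataclass(frozen=True)
class SceneGeometry:
    """Scene-camera frame geometry and gaze sampling rate."""

    width_px: int = 1280
    height_px: int = 960
    sampling_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("frame dimensions must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")


@dataclass(frozen=True)
class Fixation:
    onset: float
    offset: float
    cx: float
    cy: float
    dispersion: float = 0.0
    mean_pupil: float = float("nan")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Saccade:
    onset: float
    offset: float
    amplitude: float
    direction: float  # radians; 0 = rightward, positive = screen-up (CCW)
    mean_velocity: float
    peak_velocity: float
    mean_acceleration: float = 0.0
    peak_acceleration: float = 0.0
    peak_deceleration: float = 0.0
    latency: float = float("nan")  # time since previous saccade offset

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Blink:
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Recording:
    """One subject's event stream on one route.

    ``samples`` is an optional DataFrame with :data:`SAMPLE_COLUMNS`;
    ``tracking_ratio`` is the fraction of valid samples (data quality).
    """

    subject_id: str
    route_id: str
    geometry: SceneGeometry
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)
    samples: pd.DataFrame | None = None
    tracking_ratio: float = 1.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.tracking_ratio <= 1.0:
            raise ValidationError(
                f"tracking_ratio {self.tracking_ratio} outside [0, 1]"
            )
        for name in ("fixations", "saccades", "blinks"):
            events = getattr(self, name)
            for ev in events:
                if ev.offset <= ev.onset:
                    raise ValidationError(f"{name[:-1]} with offset <= onset: {ev}")
            for a, b in zip(events, events[1:]):
                if b.onset < a.onset:
                    raise ValidationError(f"{name} not sorted by onset")
                if b.onset < a.offset - 1e-9:
                    raise ValidationError(f"overlapping {name}: {a} / {b}")
        last = max(
            (ev.offset for ev in (*self.fixations, *self.saccades, *self.blinks)),
            default=0.0,
        )
        if self.duration < last - 1e-9:
            raise ValidationError(
                f"duration {self.duration} shorter than last event offset {last}"
            )

    @property
    def n_events(self) -> int:
        return len(self.fixations) + len(self.saccades) + len(self.blinks)


@dataclass(frozen=True)
class FixationSemanticLabel:
    """Scene-semantic class of one fixation (index into Recording.fixations)."""

    fixation_index: int
    class_label: str

    def __post_init__(self) -> None:
        if self.class_label not in SEMANTIC_CLASSES and self.class_label != "unknown":
            raise ValidationError(f"unknown semantic class {self.class_label!r}")


@dataclass(frozen=True)
class RoutePixelStats:
    """Mean total pixels per object class over a (route, subject)'s video frames."""

    n_pixel: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.n_pixel) != set(SEMANTIC_CLASSES):
            missing = set(SEMANTIC_CLASSES) - set(self.n_pixel)
            extra = set(self.n_pixel) - set(SEMANTIC_CLASSES)
            raise ValidationError(
                f"pixel stats must cover exactly the 20 classes "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if any(v < 0 for v in self.n_pixel.values()):
            raise ValidationError("N_pixel values must be nonnegative")


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table missing mandatory columns: {missing}")


def read_recording(
    samples_table_path=None,
    events_table_path=None,
    geometry: SceneGeometry | None = None,
    subject_id: str = "unknown",
    route_id: str = "unknown",
) -> Recording:
    """Build a Recording from a samples CSV and/or an events CSV.

    The events CSV uses a ``type`` column with values fixation/saccade/blink
    and the union of the per-type columns.  The tracking ratio is computed as
    valid/total from the samples table when present, else taken from a
    ``tracking_ratio`` metadata column of the events table (default 1.0).
    """
    if samples_table_path is None and events_table_path is None:
        raise ValueError("at least one of samples/events path is required")
    geometry = geometry or SceneGeometry()

    samples = None
    tracking_ratio = 1.0
    duration = 0.0
    if samples_table_path is not None:
        samples = pd.read_csv(samples_table_path)
        _require_columns(samples, SAMPLE_COLUMNS, "samples")
        if len(samples) == 0:
            raise ValidationError("samples table is empty")
        t = samples["t"].to_numpy(float)
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValidationError("sample timestamps must be nonnegative, nondecreasing")
        samples = samples.astype({"valid": bool})
        tracking_ratio = float(samples["valid"].mean())
        duration = float(t[-1]) + 1.0 / geometry.sampling_rate_hz

    fixations: list[Fixation] = []
    saccades: list[Saccade] = []
    blinks: list[Blink] = []
    if events_table_path is not None:
        events = pd.read_csv(events_table_path)
        _require_columns(events, EVENT_COLUMNS_MANDATORY, "events")
        if len(events) == 0:
            raise ValidationError("events table is empty")
        events = events.sort_values("onset", kind="stable")
        for row in events.itertuples(index=False):
            kind = row.type
            if kind == "fixation":
                fixations.append(Fixation(
                    onset=row.onset, offset=row.offset,
                    cx=row.cx, cy=row.cy,
                    dispersion=getattr(row, "dispersion", 0.0),
                    mean_pupil=getattr(row, "mean_pupil", float("nan")),
                ))
            elif kind == "saccade":
                saccades.append(Saccade(
                    onset=row.onset, offset=row.offset,
                    amplitude=row.amplitude, direction=row.direction,
                    mean_velocity=getattr(row, "mean_vel", 0.0),
                    peak_velocity=getattr(row, "peak_vel", 0.0),
                    mean_acceleration=getattr(row, "mean_acc", 0.0),
                    peak_acceleration=getattr(row, "peak_acc", 0.0),
                    peak_deceleration=getattr(row, "peak_dec", 0.0),
                    latency=getattr(row, "latency", float("nan")),
                ))
            elif kind == "blink":
                blinks.append(Blink(onset=row.onset, offset=row.offset))
            else:
                raise FormatError(f"unknown event type {kind!r}")
        if samples is None and "tracking_ratio" in events.columns:
            tracking_ratio = float(events["tracking_ratio"].iloc[0])
        duration = max(duration, float(events["offset"].max()))

    return Recording(
        subject_id=subject_id, route_id=route_id, geometry=geometry,
        fixations=fixations, saccades=saccades, blinks=blinks,
        samples=samples, tracking_ratio=tracking_ratio, duration=duration,
    )


def write_recording(recording: Recording, events_path, samples_path=None) -> None:
    """Write a Recording back to the CSV schema read by :func:`read_recording`."""
    rows = []
    for f in recording.fixations:
        rows.append(dict(type="fixation", onset=f.onset, offset=f.offset,
                         cx=f.cx, cy=f.cy, dispersion=f.dispersion,
                         mean_pupil=f.mean_pupil))
    for s in recording.saccades:
        rows.append(dict(type="saccade", onset=s.onset, offset=s.offset,
                         amplitude=s.amplitude, direction=s.direction,
                         mean_vel=s.mean_velocity, peak_vel=s.peak_velocity,
                         mean_acc=s.mean_acceleration,
                         peak_acc=s.peak_acceleration,
                         peak_dec=s.peak_deceleration, latency=s.latency))
    for b in recording.blinks:
        rows.append(dict(type="blink", onset=b.onset, offset=b.offset))
    df = pd.DataFrame(rows).sort_values("onset", kind="stable")
    df["tracking_ratio"] = recording.tracking_ratio
    df.to_csv(events_path, index=False)
    if samples_path is not None and recording.samples is not None:
        recording.samples.to_csv(samples_path, index=False)


def filter_recordings(
    recordings: Sequence[Recording], min_tracking_ratio: float = 0.70
) -> list[Recording]:
    """Quality filter: keep recordings with tracking ratio >= the threshold.

    Recordings strictly below the threshold are dropped and logged; order is
    preserved and the operation is idempotent.
    """
    kept: list[Recording] = []
    for rec in recordings:
        if rec.tracking_ratio >= min_tracking_ratio:
            kept.append(rec)
        else:
            logger.info(
                "excluding %s/%s: tracking ratio %.3f < %.2f",
                rec.subject_id, rec.route_id, rec.tracking_ratio,
                min_tracking_ratio,
            )
    return kept


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write a feature table (key columns + named feature columns) to CSV."""
    _require_columns(features, FEATURE_KEY_COLUMNS, "feature")
    features.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table; errors if the key columns are absent."""
    df = pd.read_csv(path)
    _require_columns(df, FEATURE_KEY_COLUMNS, "feature")
    return df


__all__ = [
    "SEMANTIC_CLASSES", "SAMPLE_COLUMNS", "FEATURE_KEY_COLUMNS",
    "FormatError", "ValidationError",
    "SceneGeometry", "Fixation", "Saccade", "Blink", "Recording",
    "FixationSemanticLabel", "RoutePixelStats",
    "read_recording", "write_recording", "filter_recordings",
    "write_feature_table", "read_feature_table",
]
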