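"""Divide recordings into equal, non-overlapping time windows.

The window (``T_win``) is the classification sample unit: a 103 s recording
at T_win = 10 s yields 10 segments and the trailing 3 s is ignored.  Events
are assigned to the segment containing their onset; events spanning a
boundary are truncated at the boundary so total fixation time is conserved
across segments.  Segments with zero events are retained (they yield
zero-filled features downstream) so sample counts stay well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .data_model import Blink, Fixation, Recording, Saccade

#: The experiment sweep: 5 s to 100 s in 5 s steps, 20 windows.
DEFAULT_TWIN_GRID: tuple[float, ...] = tuple(float(t) for t in range(5, 105, 5))


@dataclass(frozen=True)
class SegmentationSpec:
    t_win: float = 50.0
    grid: tuple[float, ...] = DEFAULT_TWIN_GRID

    def __post_init__(self) -> None:
        if self.t_win <= 0:
            raise ValueError("T_win must be positive")


@dataclass
class Segment:
    """One T_win-long window of a recording (1-based segment_index)."""

    subject_id: str
    route_id: str
    segment_index: int
    t_start: float
    t_end: float
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)
    fixation_indices: list[int] = field(default_factory=list)
    samples: pd.DataFrame | None = None

    @property
    def t_win(self) -> float:
        return self.t_end - self.t_start


def _truncate(ev, t_end: float):
    return replace(ev, offset=min(ev.offset, t_end)) if ev.offset > t_end else ev


def segment_recording(recording: Recording, t_win: float) -> list[Segment]:
    """Split into floor(duration / T_win) contiguous segments from t = 0.

    Returns an empty list when the recording is shorter than one window.
    """
    if t_win <= 0:
        raise ValueError("T_win must be positive")
    n = math.floor(recording.duration / t_win + 1e-9)
    segments = [
        Segment(
            subject_id=recording.subject_id,
            route_id=recording.route_id,
            segment_index=k + 1,
            t_start=k * t_win,
            t_end=(k + 1) * t_win,
        )
        for k in range(n)
    ]
    if not segments:
        return segments

    def place(events, attr: str, track_index: bool = False):
        for i, ev in enumerate(events):
            k = math.floor(ev.onset / t_win + 1e-9)
            if 0 <= k < n and ev.onset < segments[k].t_end:
                getattr(segments[k], attr).append(
                    _truncate(ev, segments[k].t_end))
                if track_index:
                    segments[k].fixation_indices.append(i)

    place(recording.fixations, "fixations", track_index=True)
    place(recording.saccades, "saccades")
    place(recording.blinks, "blinks")

    if recording.samples is not None:
        t = recording.samples["t"]
        for seg in segments:
            seg.samples = recording.samples[
                (t >= seg.t_start) & (t < seg.t_end)]
    return segments


__all__ = ["SegmentationSpec", "Segment", "segment_recording",
           "DEFAULT_TWIN_GRID"]
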