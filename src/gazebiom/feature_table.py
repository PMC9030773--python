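"""Assemble per-segment feature tables from recordings.

The static blocks (basic 93, pupil 8, density 400, semantic 40) are computed
once per segment; the saccade-encoding block (40) depends on artifacts fitted
on a training partition (amplitude threshold, wordbook), so the table keeps
each segment's raw saccade amplitudes/directions alongside the static
columns and the recognition layer fits an encoder inside every training
fold.  ``export_table`` additionally materializes the 40 encoding columns
with an encoder fitted on the whole table, for audit/export only — never as
classifier input under cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FEATURE_KEY_COLUMNS, Recording, SceneGeometry
from .features import (
    FEATURE_BLOCKS,
    SACCADE_FEATURE_NAMES,
    DensityConfig,
    SaccadeEncoder,
    basic_features,
    density_features,
    pupil_features,
    adjust_semantic_features,
    semantic_features_raw,
)
from .features.density import density_feature_names
from .segmentation import segment_recording
from .synthetic import Cohort

STATIC_BLOCKS = ("basic", "pupil", "density", "semantic")


@dataclass
class SegmentFeatures:
    """Static feature table plus per-row saccade geometry for fold-time encoding."""

    table: pd.DataFrame
    saccade_geometry: list[tuple[np.ndarray, np.ndarray]] = field(
        default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, rows) -> "SegmentFeatures":
        rows = np.asarray(rows)
        return SegmentFeatures(
            table=self.table.iloc[rows].reset_index(drop=True),
            saccade_geometry=[self.saccade_geometry[i] for i in rows],
        )


def extract_features(
    recordings: list[Recording],
    labels: dict[tuple[str, str], object],
    pixel_stats: dict[tuple[str, str], object],
    t_win: float,
    *,
    density_config: DensityConfig | None = None,
    semantic_adjusted: bool = True,
    geometry: SceneGeometry | None = None,
) -> SegmentFeatures:
    """Segment every recording at ``t_win`` and compute the static blocks.

    ``labels``/``pixel_stats`` are keyed by (subject_id, route_id); labels
    may be a list of FixationSemanticLabel or an index->class dict.
    """
    density_config = density_config or DensityConfig()
    dnames = list(density_feature_names(density_config))
    rows = []
    geometry_list: list[tuple[np.ndarray, np.ndarray]] = []
    for rec in recordings:
        key = (rec.subject_id, rec.route_id)
        rec_labels = labels.get(key, {})
        if not isinstance(rec_labels, dict):
            rec_labels = {lab.fixation_index: lab.class_label
                          for lab in rec_labels}
        for seg in segment_recording(rec, t_win):
            sem = semantic_features_raw(seg, rec_labels)
            if semantic_adjusted and key in pixel_stats:
                sem = adjust_semantic_features(sem, pixel_stats[key])
            row = pd.concat([
                pd.Series({
                    "subject_id": rec.subject_id,
                    "route_id": rec.route_id,
                    "segment_id": seg.segment_index,
                    "window_size": t_win,
                }),
                basic_features(seg),
                pupil_features(seg),
                pd.Series(
                    density_features(seg, density_config,
                                     geometry or rec.geometry),
                    index=dnames),
                sem,
            ])
            rows.append(row)
            geometry_list.append((
                np.array([s.amplitude for s in seg.saccades]),
                np.array([s.direction for s in seg.saccades]),
            ))
    table = (pd.DataFrame(rows).reset_index(drop=True) if rows
             else pd.DataFrame(columns=list(FEATURE_KEY_COLUMNS)))
    return SegmentFeatures(table=table, saccade_geometry=geometry_list)


def cohort_features(cohort: Cohort, t_win: float, **kwargs) -> SegmentFeatures:
    return extract_features(cohort.recordings, cohort.labels,
                            cohort.pixel_stats, t_win, **kwargs)


def export_table(features: SegmentFeatures) -> pd.DataFrame:
    """Full 581-feature table with the encoding block fitted on all rows.

    For export and audit; classifier input refits the encoder per fold.
    """
    enc = SaccadeEncoder().fit(features.saccade_geometry)
    sacc = enc.transform(features.saccade_geometry)
    out = features.table.copy()
    for j, name in enumerate(SACCADE_FEATURE_NAMES):
        out[name] = sacc[:, j] if len(out) else []
    return out


def write_feature_manifest(features: SegmentFeatures, path) -> None:
    """Feature-name manifest (JSON) written next to every feature table."""
    manifest = {
        "keys": list(FEATURE_KEY_COLUMNS),
        "blocks": {name: list(cols) for name, cols in FEATURE_BLOCKS.items()},
        "n_features_total": sum(len(v) for v in FEATURE_BLOCKS.values()),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


__all__ = ["SegmentFeatures", "extract_features", "cohort_features",
           "export_table", "write_feature_manifest", "STATIC_BLOCKS"]
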