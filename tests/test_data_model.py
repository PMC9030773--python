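"""Domain types, CSV round trips, and the tracking-ratio quality filter."""

import numpy as np
import pandas as pd
import pytest

from gazebiom.data_model import (
    FormatError,
    Recording,
    SceneGeometry,
    ValidationError,
    filter_recordings,
    read_feature_table,
    read_recording,
    write_feature_table,
    write_recording,
)
from gazebiom.synthetic import sample_profiles, sample_routes, simulate_recording

from conftest import make_recording


class TestReadRecording:
    def test_events_csv_parses_counts_and_duration(self, tmp_path):
        df = pd.DataFrame([
            dict(type="fixation", onset=0.0, offset=0.3, cx=10, cy=10,
                 dispersion=4, mean_pupil=3.1),
            dict(type="saccade", onset=0.3, offset=0.34, amplitude=50,
                 direction=0.0, mean_vel=1000, peak_vel=2000),
            dict(type="fixation", onset=0.34, offset=0.8, cx=60, cy=10,
                 dispersion=5, mean_pupil=3.2),
            dict(type="saccade", onset=0.8, offset=0.85, amplitude=70,
                 direction=1.0, mean_vel=1200, peak_vel=2100),
            dict(type="fixation", onset=0.85, offset=1.4, cx=40, cy=70,
                 dispersion=6, mean_pupil=3.0),
        ])
        path = tmp_path / "events.csv"
        df.to_csv(path, index=False)
        rec = read_recording(events_table_path=path)
        assert len(rec.fixations) == 3
        assert len(rec.saccades) == 2
        assert rec.duration == 1.4

    def test_tracking_ratio_from_samples(self, tmp_path):
        n, n_valid = 600, 540
        df = pd.DataFrame({
            "t": np.arange(n) / 60.0,
            "x": 100.0, "y": 100.0, "pupil_l": 3.0, "pupil_r": 3.0,
            "valid": np.r_[np.ones(n_valid, bool), np.zeros(n - n_valid, bool)],
        })
        path = tmp_path / "samples.csv"
        df.to_csv(path, index=False)
        rec = read_recording(samples_table_path=path)
        assert rec.tracking_ratio == pytest.approx(0.90)

    def test_empty_events_file_is_validation_error(self, tmp_path):
        path = tmp_path / "events.csv"
        pd.DataFrame(columns=["type", "onset", "offset"]).to_csv(path,
                                                                 index=False)
        with pytest.raises(ValidationError):
            read_recording(events_table_path=path)

    def test_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "events.csv"
        pd.DataFrame({"onset": [0.0]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_recording(events_table_path=path)

    def test_unsorted_timestamps_rejected(self, tmp_path):
        df = pd.DataFrame({
            "t": [0.0, 0.5, 0.2], "x": 0.0, "y": 0.0,
            "pupil_l": 3.0, "pupil_r": 3.0, "valid": True})
        path = tmp_path / "samples.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_recording(samples_table_path=path)

    def test_round_trip_of_simulated_recording(self, tmp_path, profile, route):
        rec, _, _ = simulate_recording(profile, route, seed=3, duration=120.0)
        write_recording(rec, tmp_path / "ev.csv")
        back = read_recording(events_table_path=tmp_path / "ev.csv",
                              subject_id=rec.subject_id,
                              route_id=rec.route_id)
        assert len(back.fixations) == len(rec.fixations)
        assert len(back.saccades) == len(rec.saccades)
        assert len(back.blinks) == len(rec.blinks)
        assert back.tracking_ratio == pytest.approx(rec.tracking_ratio)
        np.testing.assert_allclose(
            [f.cx for f in back.fixations], [f.cx for f in rec.fixations])
        np.testing.assert_allclose(
            [s.peak_velocity for s in back.saccades],
            [s.peak_velocity for s in rec.saccades])


class TestRecordingInvariants:
    def test_overlapping_fixations_rejected(self):
        with pytest.raises(ValidationError):
            make_recording([(0.0, 0.5, 10, 10), (0.4, 0.9, 20, 20)])

    def test_duration_shorter_than_events_rejected(self):
        with pytest.raises(ValidationError):
            make_recording([(0.0, 2.0, 10, 10)], duration=1.0)

    def test_tracking_ratio_bounds(self):
        with pytest.raises(ValidationError):
            make_recording([], tracking_ratio=1.2)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValidationError):
            SceneGeometry(width_px=0)


class TestFilterRecordings:
    def test_strictly_below_70_percent_excluded(self):
        recs = [make_recording([], tracking_ratio=r)
                for r in (0.69, 0.70, 0.95)]
        kept = filter_recordings(recs)
        assert len(kept) == 2
        assert [r.tracking_ratio for r in kept] == [0.70, 0.95]

    def test_all_perfect_kept_and_empty_list(self):
        recs = [make_recording([], tracking_ratio=1.0) for _ in range(3)]
        assert len(filter_recordings(recs)) == 3
        assert filter_recordings([]) == []

    def test_idempotent_and_order_preserving(self):
        recs = [make_recording([], subject=f"S{i}", tracking_ratio=r)
                for i, r in enumerate([0.9, 0.5, 0.8, 0.71])]
        once = filter_recordings(recs)
        assert filter_recordings(once) == once
        assert [r.subject_id for r in once] == ["S0", "S2", "S3"]


class TestFeatureTable:
    def test_round_trip_identity(self, tmp_path, rng):
        n_features = 581
        df = pd.DataFrame(rng.normal(size=(7, n_features)),
                          columns=[f"f{i}" for i in range(n_features)])
        df.insert(0, "subject_id", [f"S{i}" for i in range(7)])
        df.insert(1, "route_id", "R1")
        df.insert(2, "segment_id", range(7))
        df.insert(3, "window_size", 50.0)
        write_feature_table(df, tmp_path / "feat.csv")
        back = read_feature_table(tmp_path / "feat.csv")
        pd.testing.assert_frame_equal(back, df)

    def test_missing_key_column_errors(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["S1"], "f0": [1.0]})
        with pytest.raises(FormatError):
            write_feature_table(df, tmp_path / "feat.csv")
        pd.DataFrame({"a": [1]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError):
            read_feature_table(tmp_path / "bad.csv")

    def test_empty_feature_set_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["subject_id", "route_id", "segment_id",
                                   "window_size"])
        write_feature_table(df, tmp_path / "empty.csv")
        back = read_feature_table(tmp_path / "empty.csv")
        assert len(back) == 0
        assert list(back.columns) == list(df.columns)
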