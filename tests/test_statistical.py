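"""Basic statistical and pupillary features vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gazebiom.features import (
    BASIC_FEATURE_NAMES,
    PUPIL_FEATURE_NAMES,
    basic_features,
    compute_stats8,
    convex_hull_area,
    pupil_features,
    scanpath_length,
)
from gazebiom.segmentation import Segment, segment_recording

from conftest import make_recording


def stats8_oracle(values):
    """Direct-formula reference: scipy/numpy primitives, no shared code path."""
    v = np.asarray(values, float)
    if len(v) == 0:
        return np.zeros(8)
    sd = np.std(v, ddof=1) if len(v) > 1 else 0.0
    skew = sps.skew(v, bias=True) if len(v) >= 3 and np.var(v) > 0 else 0.0
    return np.array([
        np.mean(v), sd, np.median(v), np.max(v), np.min(v),
        np.percentile(v, 25), np.percentile(v, 75), skew])


class TestComputeStats8:
    def test_constant_input(self):
        out = compute_stats8([2, 2, 2, 2])
        assert out[0] == 2 and out[1] == 0 and out[7] == 0

    def test_linear_interpolation_quantiles(self):
        out = compute_stats8([1, 2, 3, 4])
        assert out[0] == pytest.approx(2.5)
        assert out[2] == pytest.approx(2.5)
        assert out[5] == pytest.approx(1.75)
        assert out[6] == pytest.approx(3.25)

    def test_empty_gives_zeros(self):
        np.testing.assert_array_equal(compute_stats8([]), np.zeros(8))

    def test_matches_oracle_on_1000_random_lists(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 40)
            v = rng.normal(0, 10, size=n)
            np.testing.assert_allclose(compute_stats8(v), stats8_oracle(v),
                                       atol=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=0, max_size=50))
    def test_order_statistics_ordered(self, values):
        mean, sd, median, vmax, vmin, q1, q3, _ = compute_stats8(values)
        if values:
            assert vmin <= q1 <= median + 1e-12
            assert median <= q3 + 1e-12 <= vmax + 1e-12
            assert sd >= 0


class TestScanpath:
    def test_345_triangle(self):
        rec = make_recording([(0, 1, 0, 0), (1.5, 2, 3, 4)], duration=2)
        assert scanpath_length(rec.fixations) == pytest.approx(5.0)

    def test_single_fixation_zero(self):
        rec = make_recording([(0, 1, 5, 5)], duration=1)
        assert scanpath_length(rec.fixations) == 0.0

    def test_collinear_sum(self):
        rec = make_recording([(0, 1, 0, 0), (1, 2, 1, 0), (2, 3, 2, 0)],
                             duration=3)
        assert scanpath_length(rec.fixations) == pytest.approx(2.0)


class TestConvexHull:
    def test_unit_square(self):
        rec = make_recording([(i, i + 0.5, x, y) for i, (x, y) in
                              enumerate([(0, 0), (1, 0), (1, 1), (0, 1)])],
                             duration=4)
        assert convex_hull_area(rec.fixations) == pytest.approx(1.0)

    def test_collinear_zero(self):
        rec = make_recording([(0, 1, 0, 0), (1, 2, 1, 1), (2, 3, 2, 2)],
                             duration=3)
        assert convex_hull_area(rec.fixations) == 0.0

    def test_matches_shapely_oracle_on_random_points(self, rng):
        from shapely.geometry import MultiPoint

        for _ in range(100):
            pts = rng.uniform(0, 1000, size=(rng.integers(3, 60), 2))
            rec = make_recording(
                [(i, i + 0.5, x, y) for i, (x, y) in enumerate(pts)],
                duration=len(pts))
            expected = MultiPoint(pts.tolist()).convex_hull.area
            assert convex_hull_area(rec.fixations) == pytest.approx(
                expected, abs=1e-9)

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 500, size=(20, 2))
        mk = lambda p: make_recording(  # noqa: E731
            [(i, i + 0.5, x, y) for i, (x, y) in enumerate(p)],
            duration=len(p)).fixations
        for shift in ([100, 0], [0, -50], [77, 33]):
            shifted = pts + shift
            assert convex_hull_area(mk(shifted)) == pytest.approx(
                convex_hull_area(mk(pts)))
            assert scanpath_length(mk(shifted)) == pytest.approx(
                scanpath_length(mk(pts)))


class TestBasicFeatures:
    def test_empty_segment_gives_93_zeros(self):
        seg = Segment("S", "R", 1, 0.0, 5.0)
        out = basic_features(seg)
        assert len(out) == 93
        assert (out == 0).all()

    def test_fixation_frequency_per_second(self):
        rec = make_recording(
            [(0.4 * i, 0.4 * i + 0.3, 10, 10) for i in range(10)],
            duration=5.0)
        seg = segment_recording(rec, 5.0)[0]
        out = basic_features(seg)
        assert out["fixation_freq"] == pytest.approx(2.0)

    def test_length_and_names_stable(self, small_features):
        assert len(BASIC_FEATURE_NAMES) == 93
        assert len(set(BASIC_FEATURE_NAMES)) == 93
        assert all(n in small_features.table.columns
                   for n in BASIC_FEATURE_NAMES)

    def test_simulated_segment_values_finite(self, small_cohort):
        rec = small_cohort.recordings[0]
        for seg in segment_recording(rec, 25.0):
            out = basic_features(seg)
            assert np.isfinite(out.to_numpy()).all()


class TestPupilFeatures:
    def test_constant_trace(self):
        rec = make_recording([(0, 1, 10, 10), (1.2, 2, 20, 20)], duration=2)
        seg = segment_recording(rec, 2.0)[0]
        out = pupil_features(seg)
        assert len(out) == 8
        assert out["pupil_mean"] == pytest.approx(3.0)
        assert out["pupil_sd"] == 0.0

    def test_no_valid_samples_gives_zeros(self):
        seg = Segment("S", "R", 1, 0.0, 5.0)
        np.testing.assert_array_equal(pupil_features(seg).to_numpy(),
                                      np.zeros(8))

    def test_uses_raw_samples_when_present(self, profile, route):
        from gazebiom.synthetic import simulate_recording

        rec, _, _ = simulate_recording(profile, route, seed=13,
                                       duration=60.0, with_samples=True)
        seg = segment_recording(rec, 30.0)[0]
        out = pupil_features(seg)
        s = seg.samples[seg.samples["valid"]]
        expected = ((s["pupil_l"] + s["pupil_r"]) / 2).mean()
        assert out["pupil_mean"] == pytest.approx(expected)
        assert len(PUPIL_FEATURE_NAMES) == 8
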