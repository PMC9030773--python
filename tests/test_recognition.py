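"""Random-forest identification/verification protocols and leakage guards.

Non-acceptance tests use small forests (the tree count only affects variance
here); the acceptance suite runs the full 500-tree configuration.
"""

import numpy as np
import pandas as pd
import pytest

from gazebiom.feature_table import SegmentFeatures, cohort_features
from gazebiom.recognition import (
    ClassifierConfig,
    experiment_manifest,
    identify_kfold,
    identify_loro,
    verification_mean_accuracy,
    verify_subject,
)
from gazebiom.synthetic import simulate_cohort

FAST = ClassifierConfig(n_estimators=60, seed=7)


def synthetic_table(n_subjects, n_per_subject, n_routes=2, separation=0.0,
                    seed=0, n_features=6):
    """Feature table with controllable class separation (no simulator)."""
    rng = np.random.default_rng(seed)
    rows, geometry = [], []
    for i in range(n_subjects):
        center = separation * rng.normal(size=n_features)
        for j in range(n_per_subject):
            rows.append({
                "subject_id": f"S{i:02d}",
                "route_id": f"R{j % n_routes + 1}",
                "segment_id": j + 1, "window_size": 50.0,
                **{f"basic_{k}": center[k] + rng.normal()
                   for k in range(n_features)},
            })
            n_sacc = rng.integers(3, 10)
            geometry.append((rng.gamma(2.0, 40 + 10 * separation * i,
                                       size=n_sacc),
                             rng.vonmises(0.0, 0.5, size=n_sacc)))
    table = pd.DataFrame(rows)
    return SegmentFeatures(table=table, saccade_geometry=geometry)


@pytest.fixture
def patched_blocks(monkeypatch):
    """Point the 'basic' block at the toy columns for protocol tests."""
    import gazebiom.recognition as rec

    monkeypatch.setattr(rec, "FEATURE_BLOCKS", {
        **rec.FEATURE_BLOCKS, "basic": tuple(f"basic_{k}" for k in range(6))})


@pytest.fixture
def toy_features(patched_blocks):
    return synthetic_table(4, 24, separation=4.0, seed=1)


class TestIdentifyKfold:
    def test_separable_subjects_reach_perfect_accuracy(self, toy_features):
        run = identify_kfold(toy_features, config=FAST, feature_set="basic")
        assert run.accuracy == 1.0
        assert run.scenario == "identification"
        assert len(run.y_true) == len(toy_features)

    def test_shuffled_labels_drop_to_chance(self, patched_blocks):
        feats = synthetic_table(4, 40, separation=4.0, seed=2)
        rng = np.random.default_rng(3)
        shuffled = feats.table.copy()
        shuffled["subject_id"] = rng.permutation(
            shuffled["subject_id"].to_numpy())
        feats_null = SegmentFeatures(shuffled, feats.saccade_geometry)
        run = identify_kfold(feats_null, config=FAST, feature_set="basic")
        # permutation null: accuracy ~ 1/4 within 3 binomial SE
        n = len(run.y_true)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(run.accuracy - 0.25) < 3 * se + 1e-9

    def test_determinism_same_seed(self, toy_features):
        a = identify_kfold(toy_features, config=FAST, feature_set="saccade")
        b = identify_kfold(toy_features, config=FAST, feature_set="saccade")
        np.testing.assert_array_equal(a.y_true, b.y_true)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.fold_ids, b.fold_ids)

    def test_single_subject_errors(self, patched_blocks):
        feats = synthetic_table(1, 20)
        with pytest.raises(ValueError):
            identify_kfold(feats, config=FAST, feature_set="basic")

    def test_warns_when_subject_has_fewer_than_k_segments(
            self, patched_blocks):
        feats = synthetic_table(3, 6, seed=5)
        with pytest.warns(UserWarning):
            identify_kfold(feats, K=10, config=FAST, feature_set="basic")


class TestIdentifyLoro:
    def test_one_fold_per_route(self, toy_features):
        run = identify_loro(toy_features, config=FAST, feature_set="basic")
        assert run.cv_scheme == "loro"
        assert len(np.unique(run.fold_ids)) == 2  # toy table has 2 routes
        assert len(run.y_true) == len(toy_features)

    def test_four_routes_four_folds(self, small_features):
        run = identify_loro(small_features, config=FAST, feature_set="basic")
        assert len(np.unique(run.fold_ids)) == 4

    def test_no_route_effect_loro_close_to_kfold(self, patched_blocks):
        # toy features have no route effect by construction
        feats = synthetic_table(4, 40, separation=3.0, seed=4)
        loro = identify_loro(feats, config=FAST, feature_set="basic")
        kfold = identify_kfold(feats, config=FAST, feature_set="basic")
        assert abs(loro.accuracy - kfold.accuracy) < 0.1

    def test_single_route_errors(self, patched_blocks):
        feats = synthetic_table(3, 10, n_routes=1)
        with pytest.raises(ValueError):
            identify_loro(feats, config=FAST, feature_set="basic")

    def test_subject_absent_from_training_flagged(self, patched_blocks):
        feats = synthetic_table(3, 10, n_routes=2, separation=2.0, seed=6)
        # subject S02 appears only on route R1
        keep = ~((feats.table.subject_id == "S02")
                 & (feats.table.route_id == "R2"))
        feats = feats.subset(np.flatnonzero(keep.to_numpy()))
        run = identify_loro(feats, config=FAST, feature_set="basic")
        assert ("R1", "S02") in run.flags["subjects_absent_from_training"]


class TestVerifySubject:
    def test_impostor_count_balanced_and_split_7_3(self, toy_features):
        run = verify_subject(toy_features, "S00", config=FAST,
                             feature_set="basic")
        n_genuine = int((toy_features.table.subject_id == "S00").sum())
        n_total = 2 * n_genuine
        assert abs(len(run.y_true) - 0.3 * n_total) <= 1
        assert abs(run.y_true.sum() - len(run.y_true) / 2) <= 1

    def test_separable_subject_verified(self, toy_features):
        run = verify_subject(toy_features, "S01", config=FAST,
                             feature_set="basic")
        assert run.accuracy >= 0.9

    def test_identical_distributions_near_half(self, patched_blocks):
        feats = synthetic_table(6, 40, separation=0.0, seed=8)
        accs = [verify_subject(feats, f"S{i:02d}",
                               config=ClassifierConfig(60, "sqrt", 50 + i),
                               feature_set="basic").accuracy
                for i in range(6)]
        n_total = 6 * round(0.3 * 80)
        se = np.sqrt(0.25 / n_total)
        assert abs(np.mean(accs) - 0.5) < 3 * se + 0.05

    def test_too_few_segments_errors(self, patched_blocks):
        feats = synthetic_table(2, 2)
        feats1 = feats.subset([0, 1, 2])  # S00 twice, S01 once
        with pytest.raises(ValueError):
            verify_subject(feats1, "S01", config=FAST, feature_set="basic")


class TestLeakageGuard:
    def test_encoder_leak_changes_loro_scores(self, small_features):
        """Fitting the wordbook/threshold on all data (instead of the
        training folds only) must measurably change LORO outputs."""
        cfg = ClassifierConfig(n_estimators=80, seed=3)
        guarded = identify_loro(small_features, config=cfg,
                                feature_set="saccade")
        leaky = identify_loro(small_features, config=cfg,
                              feature_set="saccade", _leak_encoder=True)
        assert not np.array_equal(guarded.scores, leaky.scores)

    def test_guarded_run_is_deterministic(self, small_features):
        cfg = ClassifierConfig(n_estimators=40, seed=3)
        a = identify_loro(small_features, config=cfg, feature_set="saccade")
        b = identify_loro(small_features, config=cfg, feature_set="saccade")
        np.testing.assert_array_equal(a.scores, b.scores)


class TestExperimentManifest:
    def test_verification_grid_counts(self):
        subjects = [f"S{i}" for i in range(39)]
        runs = experiment_manifest(subjects, list(range(20)), scenario="verification")
        assert len(runs) == 39 * 20 * 6

    def test_identification_grid_counts(self):
        runs = experiment_manifest(["a", "b"], list(range(20)),
                                   scenario="identification")
        # 10 k-fold rounds + 4 LORO routes = 14 CV rounds
        assert len(runs) == 14 * 20 * 6

    def test_restricted_grid_single_entry(self):
        runs = experiment_manifest(["S1"], [50.0], ("combined",),
                                   scenario="verification")
        assert len(runs) == 1

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            experiment_manifest(["S1"], [50.0], scenario="authentication")


def test_combined_uses_all_five_blocks(small_features):
    run = identify_kfold(small_features, config=FAST, feature_set="combined")
    assert run.feature_set == "combined"
    with pytest.raises(ValueError):
        identify_kfold(small_features, config=FAST, feature_set="wavelet")
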