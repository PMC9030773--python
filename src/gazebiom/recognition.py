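"""Random-forest identification and verification under the study protocols.

Identification is multiclass (which enrolled subject produced this
segment?) under either stratified 10-fold cross-validation at the segment
level (segments of all routes pooled) or leave-one-route-out (LORO), which
holds out every segment of one route so train and test stimuli never
overlap.  Verification is per-subject binary: the claimed subject's
segments are genuine, an equal-sized random sample of other subjects'
segments are impostors, split 7:3 into train/test.

The forest uses 500 trees and sqrt(n_features) per split.  Every artifact
fitted on data — the saccade-encoding amplitude threshold and wordbook — is
refit inside each training fold; the ``_leak_encoder`` escape hatch exists
only so tests can demonstrate that the guard matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .feature_table import STATIC_BLOCKS, SegmentFeatures
from .features import FEATURE_BLOCKS, SaccadeEncoder

FEATURE_SETS = ("basic", "pupil", "density", "semantic", "saccade", "combined")


@dataclass(frozen=True)
class ClassifierConfig:
    n_estimators: int = 500
    max_features: str = "sqrt"
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class RunResult:
    """Predictions and ranked candidate scores of one classification run."""

    scenario: str          # identification | verification
    cv_scheme: str         # kfold | loro | holdout
    feature_set: str
    t_win: float
    classes: np.ndarray    # candidate identities (or [0, 1] for verification)
    y_true: np.ndarray     # per test segment
    scores: np.ndarray     # (n_test, n_classes) match probabilities
    fold_ids: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    @property
    def predictions(self) -> np.ndarray:
        # ties broken by class order (argmax returns the first maximum)
        return self.classes[np.argmax(self.scores, axis=1)]

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predictions == self.y_true))


def _block_columns(feature_set: str) -> list[str]:
    if feature_set == "combined":
        names: list[str] = []
        for b in STATIC_BLOCKS:
            names.extend(FEATURE_BLOCKS[b])
        return names
    return list(FEATURE_BLOCKS[feature_set])


def _build_matrices(
    features: SegmentFeatures,
    feature_set: str,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    *,
    _leak_encoder: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices for one fold; encoding artifacts fit on train rows only."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    parts_tr, parts_te = [], []
    if feature_set != "saccade":
        cols = _block_columns(feature_set)
        static = features.table[cols].to_numpy(float)
        parts_tr.append(static[train_rows])
        parts_te.append(static[test_rows])
    if feature_set in ("saccade", "combined"):
        fit_rows = np.arange(len(features)) if _leak_encoder else train_rows
        enc = SaccadeEncoder().fit(
            [features.saccade_geometry[i] for i in fit_rows])
        parts_tr.append(enc.transform(
            [features.saccade_geometry[i] for i in train_rows]))
        parts_te.append(enc.transform(
            [features.saccade_geometry[i] for i in test_rows]))
    return np.hstack(parts_tr), np.hstack(parts_te)


def _forest(config: ClassifierConfig, fold: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        random_state=(config.seed * 1009 + fold) % (2**31),
        n_jobs=config.n_jobs,
    )


def _aggregate_proba(clf, X, all_classes: np.ndarray) -> np.ndarray:
    """Align fold probabilities onto the global class list (zeros for absent)."""
    proba = np.zeros((len(X), len(all_classes)))
    idx = {c: j for j, c in enumerate(all_classes)}
    fold_proba = clf.predict_proba(X)
    for j, c in enumerate(clf.classes_):
        proba[:, idx[c]] = fold_proba[:, j]
    return proba


def identify_kfold(
    features: SegmentFeatures,
    K: int = 10,
    config: ClassifierConfig | None = None,
    feature_set: str = "combined",
    *,
    _leak_encoder: bool = False,
) -> RunResult:
    """Segment-level stratified K-fold multiclass identification."""
    config = config or ClassifierConfig()
    y = features.table["subject_id"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("identification requires at least 2 subjects")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < K:
        warnings.warn(
            f"a subject has fewer than K={K} segments; stratification "
            f"degrades (folds reduced to {counts.min()})", stacklevel=2)
        K = int(counts.min())
        if K < 2:
            raise ValueError("every subject needs at least 2 segments")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=config.seed)
    t_win = float(features.table["window_size"].iloc[0])
    y_true, scores, fold_ids = [], [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        Xtr, Xte = _build_matrices(features, feature_set, tr, te,
                                   _leak_encoder=_leak_encoder)
        clf = _forest(config, fold).fit(Xtr, y[tr])
        scores.append(_aggregate_proba(clf, Xte, classes))
        y_true.append(y[te])
        fold_ids.append(np.full(len(te), fold))
    return RunResult(
        scenario="identification", cv_scheme="kfold", feature_set=feature_set,
        t_win=t_win, classes=classes, y_true=np.concatenate(y_true),
        scores=np.vstack(scores), fold_ids=np.concatenate(fold_ids),
    )


def identify_loro(
    features: SegmentFeatures,
    config: ClassifierConfig | None = None,
    feature_set: str = "combined",
    *,
    _leak_encoder: bool = False,
) -> RunResult:
    """Leave-one-route-out identification: train/test stimuli never overlap."""
    config = config or ClassifierConfig()
    y = features.table["subject_id"].to_numpy()
    routes = features.table["route_id"].to_numpy()
    route_list = np.unique(routes)
    if len(route_list) < 2:
        raise ValueError("LORO requires at least 2 routes")
    if len(np.unique(y)) < 2:
        raise ValueError("identification requires at least 2 subjects")
    classes = np.unique(y)
    t_win = float(features.table["window_size"].iloc[0])
    y_true, scores, fold_ids, flagged = [], [], [], []
    for fold, route in enumerate(route_list):
        te = np.flatnonzero(routes == route)
        tr = np.flatnonzero(routes != route)
        Xtr, Xte = _build_matrices(features, feature_set, tr, te,
                                   _leak_encoder=_leak_encoder)
        clf = _forest(config, fold).fit(Xtr, y[tr])
        scores.append(_aggregate_proba(clf, Xte, classes))
        y_true.append(y[te])
        fold_ids.append(np.full(len(te), fold))
        absent = set(y[te]) - set(y[tr])
        flagged.extend((route, s) for s in sorted(absent))
    return RunResult(
        scenario="identification", cv_scheme="loro", feature_set=feature_set,
        t_win=t_win, classes=classes, y_true=np.concatenate(y_true),
        scores=np.vstack(scores), fold_ids=np.concatenate(fold_ids),
        flags={"subjects_absent_from_training": flagged},
    )


def verify_subject(
    features: SegmentFeatures,
    subject_id: str,
    split: float = 0.7,
    config: ClassifierConfig | None = None,
    feature_set: str = "combined",
) -> RunResult:
    """Binary genuine-vs-impostor verification for one claimed identity.

    Impostors are sampled uniformly without replacement from the other
    subjects' segments to match the genuine count; train/test split is 7:3,
    stratified by label.
    """
    config = config or ClassifierConfig()
    y_subject = features.table["subject_id"].to_numpy()
    genuine = np.flatnonzero(y_subject == subject_id)
    if len(genuine) < 2:
        raise ValueError(f"subject {subject_id!r} has fewer than 2 segments")
    pool = np.flatnonzero(y_subject != subject_id)
    if len(pool) < len(genuine):
        raise ValueError("not enough impostor segments to balance the run")
    rng = np.random.default_rng(config.seed)
    impostors = rng.choice(pool, size=len(genuine), replace=False)
    rows = np.concatenate([genuine, impostors])
    labels = np.concatenate([np.ones(len(genuine), dtype=int),
                             np.zeros(len(impostors), dtype=int)])
    tr_idx, te_idx = train_test_split(
        np.arange(len(rows)), test_size=1.0 - split,
        random_state=config.seed, stratify=labels)
    Xtr, Xte = _build_matrices(features, feature_set,
                               rows[tr_idx], rows[te_idx])
    clf = _forest(config, 0).fit(Xtr, labels[tr_idx])
    proba = _aggregate_proba(clf, Xte, np.array([0, 1]))
    return RunResult(
        scenario="verification", cv_scheme="holdout", feature_set=feature_set,
        t_win=float(features.table["window_size"].iloc[0]),
        classes=np.array([0, 1]), y_true=labels[te_idx], scores=proba,
        flags={"subject_id": subject_id},
    )


def verification_mean_accuracy(
    features: SegmentFeatures,
    config: ClassifierConfig | None = None,
    feature_set: str = "combined",
) -> tuple[float, list[RunResult]]:
    """Unweighted mean verification accuracy over all enrolled subjects."""
    config = config or ClassifierConfig()
    results = []
    for i, sid in enumerate(np.unique(features.table["subject_id"])):
        cfg = ClassifierConfig(config.n_estimators, config.max_features,
                               (config.seed * 613 + i) % (2**31),
                               config.n_jobs)
        results.append(verify_subject(features, sid, config=cfg,
                                      feature_set=feature_set))
    return float(np.mean([r.accuracy for r in results])), results


def experiment_manifest(
    subject_ids,
    t_wins,
    feature_sets=FEATURE_SETS,
    scenario: str = "verification",
    kfold_rounds: int = 10,
    n_routes: int = 4,
) -> list[dict]:
    """Enumerate the experiment grid without executing it.

    Verification: one run per subject x window x feature set.  Identification:
    one run per cross-validation round (K-fold rounds plus LORO routes) x
    window x feature set.
    """
    runs = []
    if scenario == "verification":
        for sid in subject_ids:
            for tw in t_wins:
                for fs in feature_sets:
                    runs.append(dict(scenario=scenario, subject_id=sid,
                                     t_win=tw, feature_set=fs))
    elif scenario == "identification":
        rounds = ([("kfold", k) for k in range(kfold_rounds)]
                  + [("loro", r) for r in range(n_routes)])
        for scheme, rnd in rounds:
            for tw in t_wins:
                for fs in feature_sets:
                    runs.append(dict(scenario=scenario, cv_scheme=scheme,
                                     round=rnd, t_win=tw, feature_set=fs))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return runs


def run_experiment_grid(
    features_by_twin: dict[float, SegmentFeatures],
    feature_sets=FEATURE_SETS,
    scenarios=("identification", "verification"),
    config: ClassifierConfig | None = None,
) -> tuple[list[RunResult], dict]:
    """Execute identification (both CV schemes) and verification over the grid.

    Returns all run results plus a manifest with the enumerated run counts.
    """
    config = config or ClassifierConfig()
    results: list[RunResult] = []
    any_features = next(iter(features_by_twin.values()))
    subject_ids = list(np.unique(any_features.table["subject_id"]))
    n_routes = len(np.unique(any_features.table["route_id"]))
    manifest: dict = {"n_runs": {}}
    for scenario in scenarios:
        manifest["n_runs"][scenario] = len(experiment_manifest(
            subject_ids, list(features_by_twin), feature_sets,
            scenario, n_routes=n_routes))
    for tw, feats in features_by_twin.items():
        for fs in feature_sets:
            if "identification" in scenarios:
                results.append(identify_kfold(feats, config=config,
                                              feature_set=fs))
                if n_routes >= 2:
                    results.append(identify_loro(feats, config=config,
                                                 feature_set=fs))
            if "verification" in scenarios:
                _, runs = verification_mean_accuracy(feats, config=config,
                                                     feature_set=fs)
                results.extend(runs)
    return results, manifest


__all__ = [
    "FEATURE_SETS", "ClassifierConfig", "RunResult",
    "identify_kfold", "identify_loro", "verify_subject",
    "verification_mean_accuracy", "experiment_manifest",
    "run_experiment_grid",
]
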