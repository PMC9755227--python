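"""Spike-rate features and the texture / speed-class classification protocol.

Each trial is summarised by one rate per afferent: spike count divided by
window duration for the 37 tactile afferents (12 SA-I + 24 RA-I + 1 RA-II)
and the time-mean firing rate of the two spindle afferents (MS-Prim,
MS-Sec), giving a 39-dimensional feature vector.  Classification follows a
stratified five-fold cross-validation protocol with KNN (Euclidean on
z-scored features, scaler fit on training folds only) or Random Forest
(1000 trees by default) classifiers; modality ablations reuse the same
folds so subset comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .encoding import IzhikevichParams, SpikeTrain, encode_population, preprocess_proprio
from .innervation import InnervationMap
from .spindle import SpindleConfig, SpindleResponse, spindle_afferents
from .synth_rig import SensorRecording

__all__ = [
    "EncodedTrial",
    "FeatureMatrix",
    "ClassificationResult",
    "MODALITY_GROUPS",
    "encode_trial",
    "spike_rate",
    "build_feature_matrix",
    "crossval_classify",
    "ablate_modalities",
]

MODALITY_GROUPS = ("SA-I", "RA-I", "RA-II", "MS-Prim", "MS-Sec")


@dataclass
class EncodedTrial:
    """Spike trains plus spindle rates of one trial, with its metadata."""

    spike_trains: list[SpikeTrain]
    spindle: SpindleResponse
    meta: dict
    duration: float


@dataclass
class FeatureMatrix:
    """Trials x features rate matrix with texture and speed-class labels."""

    X: np.ndarray
    feature_names: list[str]
    feature_groups: list[str]
    y_texture: np.ndarray
    y_speed_class: np.ndarray
    meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature name count mismatch")
        if np.any(~np.isfinite(self.X)) or np.any(self.X < 0):
            raise ValueError("features must be finite non-negative rates")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def labels(self, target: str) -> np.ndarray:
        if target == "texture":
            return self.y_texture
        if target == "speed_class":
            return self.y_speed_class
        raise ValueError("target must be 'texture' or 'speed_class'")

    def columns_of(self, groups: set[str] | list[str]) -> np.ndarray:
        groups = set(groups)
        unknown = groups - set(MODALITY_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        if not groups:
            raise ValueError("empty feature-group subset")
        return np.array([g in groups for g in self.feature_groups])


@dataclass
class ClassificationResult:
    """Per-fold accuracies and the pooled confusion matrix of one CV run."""

    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray
    classes: np.ndarray
    classifier_config: dict
    seed: int


def encode_trial(recording: SensorRecording, imap: InnervationMap,
                 params: IzhikevichParams | None = None,
                 spindle_cfg: SpindleConfig | None = None,
                 dt: float = 0.25e-3,
                 proprio_filter_mode: str = "smooth_only") -> EncodedTrial:
    """Run one recording through the full encoding chain.

    Tactile channels become spike trains via the innervation map and the
    Izhikevich population; the proprio channel is mapped to fascicle length
    and converted to MS-Prim/MS-Sec rate traces.
    """
    trains = encode_population(recording, imap, params=params, dt=dt)
    L = preprocess_proprio(recording.proprio, recording.sample_rate,
                           filter_mode=proprio_filter_mode)
    spindle = spindle_afferents(L, recording.sample_rate, spindle_cfg)
    return EncodedTrial(trains, spindle, dict(recording.meta),
                        recording.duration)


def spike_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in the half-open window [t0, t1) over its duration."""
    t0, t1 = window
    if t1 <= t0 or t0 < 0:
        raise ValueError("window must satisfy t1 > t0 >= 0")
    count = int(np.count_nonzero(
        (train.spike_times >= t0) & (train.spike_times < t1)))
    return count / (t1 - t0)


def speed_class_labels(speeds: np.ndarray) -> np.ndarray:
    """Assign {low, medium, high} by thirds of the sorted unique speeds."""
    unique = np.unique(speeds)
    groups = np.array_split(unique, 3)
    names = ("low", "medium", "high")
    lookup = {s: names[i] for i, grp in enumerate(groups) for s in grp}
    return np.array([lookup[s] for s in speeds])


def build_feature_matrix(trials: list[EncodedTrial],
                         window_mm: float | None = None) -> FeatureMatrix:
    """One spike-rate feature row per trial.

    With ``window_mm`` set, features are computed over the window covering
    only the first ``window_mm`` millimetres of each scan (window duration
    = window_mm / speed), emulating truncated surface exploration.
    """
    if not trials:
        raise ValueError("no trials")
    layout = [(tr.afferent_type, tr.afferent_id)
              for tr in trials[0].spike_trains]
    names = [aid for _, aid in layout] + ["ms_prim", "ms_sec"]
    groups = [t for t, _ in layout] + ["MS-Prim", "MS-Sec"]

    rows = []
    for trial in trials:
        if [(tr.afferent_type, tr.afferent_id)
                for tr in trial.spike_trains] != layout:
            raise ValueError("heterogeneous afferent layouts across trials")
        if window_mm is None:
            t1 = trial.duration
        else:
            t1 = window_mm / trial.meta["speed"]
            # sample-rounding slack: a scan of X mm may be one sample short
            if t1 > trial.duration + 1.0 / trial.spindle.sample_rate:
                raise ValueError(
                    f"window {window_mm} mm exceeds trial length "
                    f"({trial.meta['speed'] * trial.duration:.1f} mm)")
            t1 = min(t1, trial.duration)
        n_win = max(1, int(round(t1 * trial.spindle.sample_rate)))
        tactile = [spike_rate(tr, (0.0, t1)) for tr in trial.spike_trains]
        prim = float(np.mean(trial.spindle.prim_rate[:n_win]))
        sec = float(np.mean(trial.spindle.sec_rate[:n_win]))
        rows.append(tactile + [prim, sec])

    X = np.asarray(rows, dtype=float)
    y_texture = np.array([t.meta["texture_id"] for t in trials])
    speeds = np.array([t.meta["speed"] for t in trials], dtype=float)
    y_speed = speed_class_labels(speeds)
    return FeatureMatrix(X, names, groups, y_texture, y_speed,
                         [t.meta for t in trials])


def _make_classifier(clf: str, seed: int, k: int = 1,
                     n_estimators: int = 1000):
    if clf == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=k, metric="euclidean")),
        ])
    if clf == "rf":
        return RandomForestClassifier(n_estimators=n_estimators,
                                      random_state=seed)
    raise ValueError("clf must be 'knn' or 'rf'")


def _run_cv(X: np.ndarray, y: np.ndarray, splits, clf: str, seed: int,
            **clf_kwargs) -> ClassificationResult:
    classes = np.unique(y)
    accs: list[float] = []
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    for train_idx, test_idx in splits:
        model = _make_classifier(clf, seed, **clf_kwargs)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        confusion += confusion_matrix(y[test_idx], pred, labels=classes)
    cfg = {"clf": clf, **clf_kwargs}
    return ClassificationResult(accs, float(np.mean(accs)), confusion,
                                classes, cfg, seed)


def cv_splits(y: np.ndarray, folds: int = 5, seed: int = 0):
    """Stratified K-fold index pairs (shuffled, deterministic given seed)."""
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"every class needs >= {folds} trials")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def crossval_classify(fm: FeatureMatrix, target: str = "texture",
                      clf: str = "rf", folds: int = 5, seed: int = 0,
                      groups: list[str] | None = None,
                      **clf_kwargs) -> ClassificationResult:
    """Stratified K-fold cross-validation on the rate features.

    ``clf_kwargs`` pass through to the classifier (``k`` for KNN,
    ``n_estimators`` for RF).  ``groups`` restricts to a modality subset.
    """
    y = fm.labels(target)
    X = fm.X if groups is None else fm.X[:, fm.columns_of(groups)]
    return _run_cv(X, y, cv_splits(y, folds, seed), clf, seed, **clf_kwargs)


def ablate_modalities(fm: FeatureMatrix, subsets: list[list[str]],
                      target: str = "texture", clf: str = "rf",
                      folds: int = 5, seed: int = 0,
                      **clf_kwargs) -> dict[str, ClassificationResult]:
    """CV accuracy per modality subset, using identical folds throughout."""
    y = fm.labels(target)
    splits = cv_splits(y, folds, seed)
    out: dict[str, ClassificationResult] = {}
    for subset in subsets:
        cols = fm.columns_of(subset)
        key = "+".join(sorted(subset))
        out[key] = _run_cv(fm.X[:, cols], y, splits, clf, seed, **clf_kwargs)
    return out
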