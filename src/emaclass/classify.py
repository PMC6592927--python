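"""Multi-class model training: one-vs-all RBF-SVM ensemble and AdaBoost trees.

The evaluation protocol is 10 repeated stratified 70/30 Monte-Carlo splits.
The SVM route trains one binary RBF-SVM per class (one-vs-all coding) with
(C, gamma) chosen per scorer by an inner 10-fold stratified cross-validation
maximizing mean balanced accuracy; features are standardized with statistics
computed on the training rows only.  The boosted route is multi-class
AdaBoost (SAMME exponential-loss updates) over depth-limited decision trees.
A rebalanced run first under-samples the negative class (II) down to the
positive (I) count.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_LENGTH, descriptor_manifest
from .metrics import CLASSES

DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(
    (1.0 / FEATURE_LENGTH) * 10.0**k for k in range(-2, 3)
)


class StratificationError(ValueError):
    """A class has too few samples to stratify."""


@dataclass
class LabeledDataset:
    """Feature rows plus their expert class labels."""

    features: np.ndarray  # (n, p) float
    labels: np.ndarray  # (n,) str, values in CLASSES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels and feature rows differ in length")
        bad = sorted(set(self.labels) - set(CLASSES))
        if bad:
            raise ValueError(f"unknown class labels {bad}; expected {CLASSES}")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=np.int64)
        return LabeledDataset(self.features[idx], self.labels[idx])


@dataclass(frozen=True)
class TrainConfig:
    method: str = "svm_ecoc"  # or "adaboost_trees"
    svm_C_grid: tuple[float, ...] = DEFAULT_C_GRID
    svm_gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    boost_cycles: int = 100
    tree_max_depth: int = 3
    n_repeats: int = 10
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("svm_ecoc", "adaboost_trees"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.boost_cycles < 1:
            raise ValueError("boost_cycles must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class TrainedModel:
    """Per-class one-vs-all scorers with their preprocessing statistics."""

    method: str
    class_order: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_config_digest: str
    svm_scorers: dict | None = None  # class -> fitted SVC (+ chosen params)
    boost_model: object | None = None  # fitted AdaBoostClassifier
    chosen_params: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.scaler_mean.shape[0])


def feature_config_digest(manifest: dict | None = None) -> str:
    """Stable digest tying a model to the descriptor settings it consumed."""
    manifest = manifest if manifest is not None else descriptor_manifest()
    payload = json.dumps(manifest, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_repeated(
    ds: LabeledDataset, cfg: TrainConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """n_repeats independent stratified train/test index splits.

    Per class, ``round_half_up(train_fraction * count)`` rows go to train and
    the remainder to test; splits are disjoint, exhaustive and fully
    determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = ds.class_counts
    present = [c for c in CLASSES if counts[c] > 0]
    for c in present:
        if counts[c] < 2:
            raise StratificationError(
                f"class {c} has {counts[c]} sample(s); stratified splitting "
                "needs at least 2 per class"
            )
    splits = []
    for _ in range(cfg.n_repeats):
        train_idx, test_idx = [], []
        for c in present:
            idx = np.flatnonzero(ds.labels == c)
            perm = rng.permutation(idx)
            n_train = round_half_up(cfg.train_fraction * len(idx))
            n_train = min(max(n_train, 1), len(idx) - 1)  # keep both sides non-empty
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return splits


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = []
    for v in (False, True):
        mask = y_true == v
        if mask.any():
            accs.append(float(np.mean(y_pred[mask] == v)))
    return float(np.mean(accs))


def _check_trainable(train: LabeledDataset) -> None:
    present = [c for c, n in train.class_counts.items() if n > 0]
    if len(present) < 2:
        raise ValueError(
            f"degenerate training set: only class(es) {present} present"
        )


def train_svm_ecoc(train: LabeledDataset, cfg: TrainConfig) -> TrainedModel:
    """One-vs-all RBF-SVM ensemble with inner 10-fold CV hyperparameter search.

    For each class the (C, gamma) pair maximizing mean balanced accuracy over
    a stratified inner CV on the training rows is selected (ties resolved in
    grid order), then a final SVC is fitted on all training rows.  Classes
    absent from the training set get a constant-minus-infinity scorer so the
    model still emits four scores.
    """
    _check_trainable(train)
    mean, scale = _standardize_fit(train.features)
    X = (train.features - mean) / scale
    rng = np.random.default_rng(cfg.seed + 1)
    scorers: dict[str, dict] = {}
    chosen: dict[str, dict] = {}
    for c in CLASSES:
        y = train.labels == c
        n_pos = int(y.sum())
        if n_pos == 0:
            scorers[c] = {"svc": None}
            continue
        n_splits = min(10, n_pos, int((~y).sum()))
        if n_splits >= 2:
            skf = StratifiedKFold(
                n_splits=n_splits, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            folds = list(skf.split(X, y))
            best = None
            for C in cfg.svm_C_grid:
                for gamma in cfg.svm_gamma_grid:
                    accs = []
                    for tr, va in folds:
                        if len(np.unique(y[tr])) < 2:
                            continue
                        clf = SVC(C=C, gamma=gamma, kernel="rbf")
                        clf.fit(X[tr], y[tr])
                        accs.append(_balanced_accuracy(y[va], clf.predict(X[va])))
                    score = float(np.mean(accs)) if accs else -np.inf
                    if best is None or score > best[0]:
                        best = (score, C, gamma)
            _, C, gamma = best
        else:  # too few positives to cross-validate; fall back to grid midpoint
            C, gamma = cfg.svm_C_grid[len(cfg.svm_C_grid) // 2], 1.0 / X.shape[1]
        svc = SVC(C=C, gamma=gamma, kernel="rbf")
        svc.fit(X, y)
        scorers[c] = {"svc": svc}
        chosen[c] = {"C": C, "gamma": gamma}
    return TrainedModel(
        method="svm_ecoc",
        class_order=CLASSES,
        scaler_mean=mean,
        scaler_scale=scale,
        feature_config_digest=feature_config_digest(),
        svm_scorers=scorers,
        chosen_params=chosen,
    )


def adaboost_stage_weight(err: float, n_classes: int = 2) -> float:
    """SAMME stage weight alpha = ln((1 - err) / err) + ln(K - 1).

    A weak learner at chance level for K classes (err = (K-1)/K, i.e. 0.5
    when K = 2) receives weight 0.
    """
    if not 0 < err < 1:
        raise ValueError("err must lie in (0, 1)")
    return math.log((1.0 - err) / err) + math.log(n_classes - 1)


def train_adaboost(train: LabeledDataset, cfg: TrainConfig) -> TrainedModel:
    """Multi-class AdaBoost (SAMME) over depth-limited decision trees."""
    _check_trainable(train)
    mean, scale = _standardize_fit(train.features)
    X = (train.features - mean) / scale
    y = train.labels.astype(str)
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(
            max_depth=cfg.tree_max_depth, random_state=cfg.seed + 2
        ),
        n_estimators=cfg.boost_cycles,
        random_state=cfg.seed + 3,
    )
    model.fit(X, y)
    return TrainedModel(
        method="adaboost_trees",
        class_order=CLASSES,
        scaler_mean=mean,
        scaler_scale=scale,
        feature_config_digest=feature_config_digest(),
        boost_model=model,
    )


def train(train_ds: LabeledDataset, cfg: TrainConfig) -> TrainedModel:
    if cfg.method == "svm_ecoc":
        return train_svm_ecoc(train_ds, cfg)
    return train_adaboost(train_ds, cfg)


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-class one-vs-all scores, columns in class order (I, II, III, IV)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match the model's "
            f"{model.n_features} (descriptor digest {model.feature_config_digest})"
        )
    Xs = (X - model.scaler_mean) / model.scaler_scale
    if model.method == "svm_ecoc":
        cols = []
        for c in model.class_order:
            svc = model.svm_scorers[c]["svc"]
            if svc is None:
                cols.append(np.full(Xs.shape[0], -np.inf))
            else:
                cols.append(svc.decision_function(Xs))
        return np.column_stack(cols)
    raw = model.boost_model.decision_function(Xs)
    classes = list(model.boost_model.classes_)
    if raw.ndim == 1:  # binary: sklearn returns the score of classes_[1]
        raw = np.column_stack([-raw, raw])
    out = np.full((Xs.shape[0], len(model.class_order)), -np.inf)
    for j, c in enumerate(model.class_order):
        if c in classes:
            out[:, j] = raw[:, classes.index(c)]
    return out


def predict(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax of the 4 scores; ties go to the earlier
    class in (I, II, III, IV) order) plus the score matrix for ROC use."""
    scores = decision_scores(model, X)
    idx = np.argmax(scores, axis=1)  # argmax returns the first maximum: tie rule
    labels = np.asarray([model.class_order[i] for i in idx], dtype=object)
    return labels, scores


def undersample(ds: LabeledDataset, seed: int) -> LabeledDataset:
    """Randomly remove negative (II) rows until they match the positive count.

    Sampling is without replacement and seed-determined; classes I, III and
    IV are untouched and the original row order of survivors is preserved.
    """
    counts = ds.class_counts
    n_pos, n_neg = counts["I"], counts["II"]
    if n_neg < n_pos:
        raise ValueError(
            f"negative count {n_neg} is below positive count {n_pos}; "
            "nothing to under-sample"
        )
    if n_neg == n_pos:
        return ds.subset(np.arange(len(ds)))
    rng = np.random.default_rng(seed)
    neg_idx = np.flatnonzero(ds.labels == "II")
    keep_neg = rng.choice(neg_idx, size=n_pos, replace=False)
    keep = np.ones(len(ds), dtype=bool)
    keep[neg_idx] = False
    keep[keep_neg] = True
    return ds.subset(np.flatnonzero(keep))
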