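"""Classification evaluation engine: scale -> PCA -> classifier.

Every model family (random forest, support vector, k-nearest neighbors)
runs through the same estimator: per-feature standardization, principal
component analysis, then the classifier.  Hyperparameters — including the
PCA rank — are tuned by nested stratified k-fold cross-validation confined
to the training portion of each outer split, so no information from a
validation set ever reaches the scaler, the PCA basis, or the
hyperparameter choice.

Three evaluation schemes are provided:

* :func:`run_binary` — repeated stratified shuffle-splits (default 100 at
  80/20) returning the vector of per-split validation accuracies;
* :func:`run_logo` — leave-one-site-out folds, the site-robustness check;
* :func:`run_multiclass` — one-vs-rest decomposition over disjoint,
  size-matched classes with fixed random-forest settings, accumulated into
  a confusion matrix by per-subject majority vote over repeated stratified
  k-fold held-out predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneGroupOut,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError

logger = logging.getLogger(__name__)

FAMILIES = ("random_forest", "support_vector", "k_nearest_neighbors")

# Default tuning grids; "pca_rank" candidates are clipped at fit time to
# what the training fold can support.  All grids are config-overridable.
_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "pca_rank": [10, 25, 50, "max"],
        "max_depth": [None, 5, 10],
        "max_features": ["sqrt", 0.25, 0.5],
    },
    "support_vector": {
        "pca_rank": [10, 25, 50, "max"],
        "C": [0.1, 1.0, 10.0],
        "kernel": ["linear", "rbf"],
    },
    "k_nearest_neighbors": {
        "pca_rank": [10, 25, 50, "max"],
        "n_neighbors": [5, 15, 31],
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan"],
    },
}

_DEFAULT_FIXED: dict[str, dict] = {
    "random_forest": {"n_estimators": 250, "criterion": "gini"},
    "support_vector": {},
    "k_nearest_neighbors": {},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its fixed settings and tuning grid.

    ``tuning_grid`` maps hyperparameter names to candidate lists; the key
    ``pca_rank`` tunes the PCA dimensionality (the sentinel ``"max"``
    resolves to the largest rank the training data supports).  All other
    keys are passed to the classifier.  ``fixed_settings`` are classifier
    constructor arguments held constant (random forests keep 250 trees by
    default).
    """

    family: str
    fixed_settings: Mapping = field(default_factory=dict)
    tuning_grid: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        if any(len(v) == 0 for v in self.tuning_grid.values()):
            raise ConfigError("tuning grid entries must be non-empty")


def make_model(
    family: str,
    fixed_settings: Mapping | None = None,
    tuning_grid: Mapping[str, list] | None = None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` with package defaults filled in."""
    if family not in FAMILIES:
        raise ConfigError(f"unknown model family {family!r}; choose from {FAMILIES}")
    fixed = dict(_DEFAULT_FIXED[family])
    if fixed_settings:
        fixed.update(fixed_settings)
    grid = dict(_DEFAULT_GRIDS[family]) if tuning_grid is None else dict(tuning_grid)
    return ModelSpec(family, fixed, grid)


@dataclass(frozen=True)
class SplitAccuracies:
    """Per-shuffle-split validation accuracies for one evaluation cell."""

    accuracies: np.ndarray
    group: str | None = None
    feature_set: str | None = None
    model: str | None = None

    def __post_init__(self):
        acc = np.asarray(self.accuracies, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ConfigError("split accuracies must lie in [0, 1]")
        object.__setattr__(self, "accuracies", acc)

    @property
    def n_splits(self) -> int:
        return len(self.accuracies)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "feature_set": self.feature_set,
                "model": self.model,
                "split_index": np.arange(self.n_splits),
                "accuracy": self.accuracies,
            }
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """True x predicted counts over an ordered class list."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k) or np.any(counts < 0):
            raise ConfigError("counts must be a square non-negative matrix over labels")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def misclassification_rate(self) -> float:
        return 1.0 - float(np.trace(self.counts)) / self.total

    def row_sums(self) -> dict[str, int]:
        return {lab: int(s) for lab, s in zip(self.labels, self.counts.sum(axis=1))}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"true_label": ti, "predicted_label": pj, "count": int(self.counts[i, j])}
            for i, ti in enumerate(self.labels)
            for j, pj in enumerate(self.labels)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline construction and single-split fitting
# ---------------------------------------------------------------------------

def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c != "id"]
        return features[cols].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _drop_constant(X: np.ndarray) -> np.ndarray:
    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.warning("dropping %d constant feature column(s)", int((~keep).sum()))
        X = X[:, keep]
    if X.shape[1] == 0:
        raise ConfigError("all feature columns are constant")
    return X


def _make_classifier(model: ModelSpec, seed: int):
    if model.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **model.fixed_settings)
    if model.family == "support_vector":
        return SVC(random_state=seed, **model.fixed_settings)
    return KNeighborsClassifier(**model.fixed_settings)


def _resolve_grid(model: ModelSpec, n_train_fit: int, n_features: int) -> dict[str, list]:
    """Translate a user-level grid to pipeline parameter names.

    PCA rank candidates are clipped to the largest rank the smallest inner
    training fold can support, deduplicated, and kept sorted.
    """
    cap = max(1, min(n_features, n_train_fit) - 1)
    out: dict[str, list] = {}
    for key, values in model.tuning_grid.items():
        if key == "pca_rank":
            ranks = sorted({min(cap, cap if v == "max" else int(v)) for v in values})
            out["pca__n_components"] = ranks
        else:
            out[f"clf__{key}"] = list(values)
    return out


def _grid_size(grid: Mapping[str, list]) -> int:
    size = 1
    for v in grid.values():
        size *= len(v)
    return size


def fit_split(
    X_train: np.ndarray,
    y_train: np.ndarray,
    model: ModelSpec,
    inner_folds: int = 5,
    seed: int = 0,
):
    """Fit the scale -> PCA -> classifier estimator on one training set.

    With more than one grid point, hyperparameters are selected by inner
    stratified k-fold CV (accuracy scoring) on the training rows only;
    a single-point grid is fitted directly.  Returns the fitted estimator.
    """
    n_inner_fit = int(np.floor(len(X_train) * (inner_folds - 1) / inner_folds))
    grid = _resolve_grid(model, n_inner_fit, X_train.shape[1])
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("pca", PCA(random_state=0)),
            ("clf", _make_classifier(model, seed)),
        ]
    )
    if _grid_size(grid) == 1:
        pipe.set_params(**{k: v[0] for k, v in grid.items()})
        return pipe.fit(X_train, y_train)
    search = GridSearchCV(
        pipe,
        grid,
        scoring="accuracy",
        cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
        n_jobs=None,
        refit=True,
    )
    search.fit(X_train, y_train)
    return search.best_estimator_


# ---------------------------------------------------------------------------
# Evaluation schemes
# ---------------------------------------------------------------------------

def run_binary(
    features,
    labels: Sequence,
    model: ModelSpec,
    n_splits: int = 100,
    train_fraction: float = 0.8,
    inner_folds: int = 5,
    seed: int = 0,
    group: str | None = None,
    feature_set: str | None = None,
) -> SplitAccuracies:
    """Case-control evaluation over stratified shuffle-splits.

    For each of ``n_splits`` stratified splits (``train_fraction`` of the
    rows for training, the rest for validation), the estimator and its
    hyperparameters are derived from the training rows only and scored once
    on the held-out rows.  Deterministic given ``seed``.
    """
    if n_splits < 2:
        raise ConfigError("n_splits must be at least 2")
    X = _drop_constant(_as_matrix(features))
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ConfigError("labels are not row-aligned with features")
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed
    )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    acc = np.empty(n_splits)
    for i, (tr, va) in enumerate(sss.split(X, y)):
        est = fit_split(X[tr], y[tr], model, inner_folds, int(child_seeds[i]))
        acc[i] = float(np.mean(est.predict(X[va]) == y[va]))
    return SplitAccuracies(acc, group=group, feature_set=feature_set, model=model.family)


def run_logo(
    features,
    labels: Sequence,
    site_labels: Sequence,
    model: ModelSpec,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Leave-one-site-out cross-validation with the same estimator.

    One model is trained per held-out site on all remaining sites; returns
    ``(per-site accuracy map, mean accuracy)``.  A held-out site lacking
    one of the two classes is skipped with a warning.
    """
    X = _drop_constant(_as_matrix(features))
    y = np.asarray(labels)
    sites = np.asarray(site_labels)
    if len(np.unique(sites)) < 2:
        raise ConfigError("leave-one-site-out needs at least 2 sites")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(np.unique(sites))) % (2**31)
    per_site: dict = {}
    for i, (tr, va) in enumerate(LeaveOneGroupOut().split(X, y, groups=sites)):
        site = sites[va][0]
        if len(np.unique(y[va])) < 2:
            logger.warning("site %r lacks one class in the held-out fold; skipped", site)
            continue
        est = fit_split(X[tr], y[tr], model, inner_folds, int(child_seeds[i]))
        per_site[site] = float(np.mean(est.predict(X[va]) == y[va]))
    if not per_site:
        raise ConfigError("every leave-one-site-out fold was degenerate")
    return per_site, float(np.mean(list(per_site.values())))


def build_multiclass_cohort(
    unique_groups: Mapping[str, Iterable[str]],
    control_ids: Iterable[str],
    n_per_class: int | None = None,
    seed: int = 0,
    control_label: str = "control",
) -> tuple[list[str], np.ndarray]:
    """Assemble disjoint, size-matched class labels for run_multiclass.

    ``unique_groups`` must already be pairwise disjoint (the unique case
    list); overlap raises.  Every class, including the control class, is
    subsampled to ``n_per_class`` (default: the smallest class size).
    Returns ``(ids, labels)`` in a deterministic shuffled order.
    """
    sets = {lab: sorted(set(ids)) for lab, ids in unique_groups.items()}
    sets[control_label] = sorted(set(control_ids))
    seen: set = set()
    for lab, ids in sets.items():
        overlap = seen & set(ids)
        if overlap:
            raise ConfigError(
                f"class membership overlaps (e.g. {sorted(overlap)[0]!r} in {lab} and another class)"
            )
        seen.update(ids)
    if n_per_class is None:
        n_per_class = min(len(ids) for ids in sets.values())
    if any(len(ids) < n_per_class for ids in sets.values()):
        small = min(sets, key=lambda lb: len(sets[lb]))
        raise ConfigError(f"class {small} has fewer than {n_per_class} members")
    rng = np.random.default_rng(seed)
    ids_out: list[str] = []
    labels_out: list[str] = []
    for lab in sorted(sets):
        pick = rng.choice(len(sets[lab]), size=n_per_class, replace=False)
        ids_out.extend(sets[lab][i] for i in sorted(pick))
        labels_out.extend([lab] * n_per_class)
    order = rng.permutation(len(ids_out))
    return [ids_out[i] for i in order], np.asarray(labels_out, dtype=object)[order]


def run_multiclass(
    features,
    labels: Sequence,
    seed: int = 0,
    n_repeats: int = 5,
    n_folds: int = 5,
    n_estimators: int = 250,
    pca_rank: int = 50,
    class_order: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """One-vs-rest multiclass classification into a confusion matrix.

    One random forest (``n_estimators`` trees, gini criterion, random
    state 42) is trained per class on each training fold, treating that
    class as positive and all others as negative; a sample's predicted
    class is the one with maximal positive-class probability, ties broken
    by class order.  Held-out predictions are accumulated over
    ``n_repeats`` repetitions of stratified ``n_folds``-fold CV and each
    subject's final label is the majority vote over the folds in which it
    was held out, so every subject contributes exactly one count and row
    sums equal the true class sizes.

    Class sizes must be equal (build them with
    :func:`build_multiclass_cohort`).
    """
    X = _drop_constant(_as_matrix(features))
    y = np.asarray(labels, dtype=object)
    classes = tuple(class_order) if class_order is not None else tuple(sorted(set(y)))
    sizes = {c: int(np.sum(y == c)) for c in classes}
    if len(set(sizes.values())) != 1:
        raise ConfigError(f"class sizes must be equal, got {sizes}")
    k = len(classes)
    votes = np.zeros((len(y), k), dtype=int)
    fold_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    rank = max(1, min(pca_rank, X.shape[1], len(y) - 1))
    for r in range(n_repeats):
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=int(fold_seeds[r]))
        for tr, va in skf.split(X, y):
            pre = Pipeline([("scale", StandardScaler()), ("pca", PCA(n_components=min(rank, len(tr) - 1), random_state=0))])
            Z_tr = pre.fit_transform(X[tr])
            Z_va = pre.transform(X[va])
            scores = np.empty((len(va), k))
            for j, cls in enumerate(classes):
                rf = RandomForestClassifier(
                    n_estimators=n_estimators, criterion="gini", random_state=42
                )
                rf.fit(Z_tr, (y[tr] == cls).astype(int))
                if rf.classes_.size == 1:
                    scores[:, j] = float(rf.classes_[0])
                else:
                    scores[:, j] = rf.predict_proba(Z_va)[:, list(rf.classes_).index(1)]
            pred = scores.argmax(axis=1)  # ties resolve to the earlier class
            votes[va, pred] += 1
    if np.any(votes.sum(axis=1) == 0):
        raise ConfigError("a subject was never held out; increase n_repeats")
    final = votes.argmax(axis=1)
    counts = np.zeros((k, k), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    for yi, pi in zip(y, final):
        counts[class_index[yi], pi] += 1
    return ConfusionMatrix(classes, counts)
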