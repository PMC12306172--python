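"""Random-forest sex-role classifier evaluated by one-vs-one macro-AUC.

Workflow: stratified 70/30 split, random oversampling of training
minority classes to the majority size, features = union of the top
dominant genera of each enterotype cluster, 5-fold cross-validated
hyperparameter selection over an (ntree, mtry) grid, and evaluation on
the held-out test set by pairwise AUC between each pair of the three
sex-role classes, macro-averaged.

The pairwise AUC for classes (a, b) restricts the test set to samples of
those classes, scores each with the renormalised pair probability
p(a) / (p(a) + p(b)), and applies the rank-sum (Mann-Whitney) formulation
with ties counted one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io import RelativeProfileSet

DEFAULT_GRID = {"ntree": (100, 200, 500), "mtry": "auto"}  # mtry grid depends on p


@dataclass
class ClassifierReport:
    pairwise_auc: dict[tuple[str, str], float]
    macro_auc: float
    importances: pd.Series
    best_params: dict[str, int]
    split_seed: int
    oversample_seed: int
    test_sample_ids: list[str]
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairwise_auc": {f"{a}|{b}": v for (a, b), v in self.pairwise_auc.items()},
            "macro_auc": self.macro_auc,
            "importances": self.importances.to_dict(),
            "best_params": self.best_params,
            "split_seed": self.split_seed,
            "oversample_seed": self.oversample_seed,
            "test_sample_ids": list(self.test_sample_ids),
            "features": list(self.features),
        }


def split_train_test(sample_ids, labels, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[list, list]:
    """Stratified deterministic train/test split.

    Each class contributes ``round(n_class * fraction)`` training samples
    (at least one in each side where the class size allows), so class
    proportions in the training set stay within one sample of the ideal.
    """
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"need >= 2 samples per class, too few in: {small}")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(round(len(idx) * train_fraction))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train.extend(sample_ids[i] for i in idx[:n_train])
        test.extend(sample_ids[i] for i in idx[n_train:])
    return sorted(train, key=sample_ids.index), sorted(test, key=sample_ids.index)


def oversample(train_ids, labels: dict | pd.Series, seed: int = 0) -> list:
    """Duplicate minority-class training samples (with replacement) until
    every class matches the majority class count."""
    labels = pd.Series(labels)
    train_ids = list(train_ids)
    y = labels.loc[train_ids]
    counts = y.value_counts()
    if (counts == 0).any():
        raise ValueError("empty class in training labels")
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    out = list(train_ids)
    for c in sorted(counts.index):
        members = [t for t in train_ids if labels[t] == c]
        deficit = target - len(members)
        if deficit > 0:
            out.extend(rng.choice(members, size=deficit, replace=True))
    return out


def select_features(profiles: RelativeProfileSet, enterotype_labels,
                    n_per_cluster: int = 10) -> list[str]:
    """Union of each enterotype cluster's top genera by mean relative
    abundance, ordered by descending overall mean then lexicographically."""
    labels = np.asarray(enterotype_labels)
    chosen: set[str] = set()
    for c in np.unique(labels):
        means = profiles.profiles[labels == c].mean(axis=0)
        k = min(n_per_cluster, len(profiles.genus_ids))
        if k < n_per_cluster:
            warnings.warn(
                f"only {k} genera available (requested {n_per_cluster} per cluster)",
                stacklevel=2,
            )
        top = np.argsort(-means, kind="stable")[:k]
        chosen.update(profiles.genus_ids[i] for i in top)
    overall = profiles.profiles.mean(axis=0)
    mean_of = dict(zip(profiles.genus_ids, overall))
    return sorted(chosen, key=lambda g: (-mean_of[g], g))


def train_rf(X, y, ntree: int = 200, mtry: int = 1, seed: int = 0) -> RandomForestClassifier:
    """Random forest of ``ntree`` trees each splitting on ``mtry`` randomly
    chosen features; per-class probabilities are tree-vote fractions."""
    X = np.asarray(X, dtype=float)
    if mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds feature count {X.shape[1]}")
    model = RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, random_state=seed
    )
    model.fit(X, np.asarray(y))
    return model


def pairwise_auc(prob: np.ndarray, y_true, classes, class_a, class_b,
                 renormalize: bool = True) -> float:
    """AUC for distinguishing ``class_a`` (positive) from ``class_b`` on
    the samples of those two classes.

    Scores are p(a)/(p(a)+p(b)) by default (raw p(a) when
    ``renormalize=False``); AUC via the Mann-Whitney rank formulation,
    ties counted 1/2.
    """
    y_true = np.asarray(y_true)
    classes = list(classes)
    ia, ib = classes.index(class_a), classes.index(class_b)
    mask = (y_true == class_a) | (y_true == class_b)
    if not (y_true == class_a).any() or not (y_true == class_b).any():
        warnings.warn(
            f"class {class_a!r} or {class_b!r} absent: AUC undefined",
            stacklevel=2,
        )
        return float("nan")
    pa, pb = prob[mask, ia], prob[mask, ib]
    denom = pa + pb
    score = np.where(denom > 0, pa / np.where(denom > 0, denom, 1.0), 0.5) \
        if renormalize else pa
    pos = y_true[mask] == class_a
    ranks = rankdata(score)  # average ranks handle ties as 1/2
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def macro_auc(pairwise: dict | list) -> float:
    """Unweighted arithmetic mean of the pairwise AUC values."""
    if isinstance(pairwise, dict):
        missing = [k for k, v in pairwise.items() if v is None or np.isnan(v)]
        if missing:
            raise ValueError(f"missing pairwise AUC for pair(s): {missing}")
        values = list(pairwise.values())
    else:
        values = list(pairwise)
        if any(v is None or np.isnan(v) for v in values):
            raise ValueError("missing pairwise AUC value")
    if not values:
        raise ValueError("no pairwise AUC values")
    return float(np.mean(values))


def _cv_macro_auc(X, y, ntree, mtry, folds, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = sorted(np.unique(y))
    scores = []
    for tr, te in skf.split(X, y):
        model = train_rf(X[tr], y[tr], ntree=ntree, mtry=mtry, seed=seed)
        prob = model.predict_proba(X[te])
        model_classes = list(model.classes_)
        aucs = []
        for a, b in combinations(classes, 2):
            if (y[te] == a).any() and (y[te] == b).any():
                aucs.append(pairwise_auc(prob, y[te], model_classes, a, b))
        if aucs:
            scores.append(np.mean(aucs))
    return float(np.mean(scores))


def cv_tune(X, y, grid: dict | None = None, folds: int = 5, seed: int = 0) -> dict[str, int]:
    """Stratified k-fold selection of (ntree, mtry) maximising mean CV
    macro-AUC; ties go to the smaller ntree then the smaller mtry."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if grid is None:
        grid = DEFAULT_GRID
    ntrees = tuple(grid.get("ntree", DEFAULT_GRID["ntree"]))
    mtrys = grid.get("mtry", "auto")
    if mtrys == "auto":
        mtrys = tuple(sorted({m for m in (1, 2, 3, int(np.sqrt(p))) if 1 <= m <= p}))
    if not ntrees or not mtrys:
        raise ValueError("empty hyperparameter grid")
    best = None
    for ntree in sorted(ntrees):
        for mtry in sorted(mtrys):
            score = _cv_macro_auc(X, y, ntree, mtry, folds, seed)
            if best is None or score > best[0] + 1e-12:
                best = (score, ntree, mtry)
    return {"ntree": best[1], "mtry": best[2]}


def permutation_importance(model, X_test, y_test, classes=None,
                           n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """Mean macro-AUC drop per feature over ``n_repeats`` column shuffles,
    sorted descending."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if classes is None:
        classes = sorted(np.unique(y_test))
    model_classes = list(model.classes_)

    def _score(X):
        prob = model.predict_proba(X)
        return macro_auc([
            pairwise_auc(prob, y_test, model_classes, a, b)
            for a, b in combinations(classes, 2)
        ])

    rng = np.random.default_rng(seed)
    drops = np.zeros(X_test.shape[1])
    if n_repeats <= 0:
        return pd.Series(drops, index=getattr(model, "feature_names", None))
    base = _score(X_test)
    for j in range(X_test.shape[1]):
        for _ in range(n_repeats):
            Xp = X_test.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j] += base - _score(Xp)
    drops /= n_repeats
    out = pd.Series(drops, index=getattr(model, "feature_names", None))
    return out.sort_values(ascending=False)


def run_classifier(profiles: RelativeProfileSet, sex_roles: pd.Series,
                   enterotype_labels, n_per_cluster: int = 10,
                   train_fraction: float = 0.7, grid: dict | None = None,
                   tune: bool = True, ntree: int = 200, mtry: int = 1,
                   n_repeats: int = 10, seed: int = 0) -> ClassifierReport:
    """End-to-end pipeline: features, split, oversample, (optionally) tune,
    fit, pairwise/macro AUC and permutation importance on the test set."""
    features = select_features(profiles, enterotype_labels, n_per_cluster)
    frame = profiles.to_frame()[features]
    sex_roles = pd.Series(sex_roles).loc[frame.index]
    classes = sorted(sex_roles.unique())

    split_seed, oversample_seed = seed, seed + 1
    train_ids, test_ids = split_train_test(
        list(frame.index), sex_roles.to_numpy(), train_fraction, split_seed)
    train_multiset = oversample(train_ids, sex_roles, oversample_seed)
    assert not set(test_ids) & set(train_multiset)  # leakage guard

    X_train = frame.loc[train_multiset].to_numpy()
    y_train = sex_roles.loc[train_multiset].to_numpy()
    X_test = frame.loc[test_ids].to_numpy()
    y_test = sex_roles.loc[test_ids].to_numpy()

    if tune:
        params = cv_tune(X_train, y_train, grid=grid, seed=seed)
    else:
        params = {"ntree": ntree, "mtry": mtry}
    model = train_rf(X_train, y_train, seed=seed, **params)
    model.feature_names = features
    prob = model.predict_proba(X_test)
    model_classes = list(model.classes_)
    pair = {
        (a, b): pairwise_auc(prob, y_test, model_classes, a, b)
        for a, b in combinations(classes, 2)
    }
    importances = permutation_importance(
        model, X_test, y_test, classes=classes, n_repeats=n_repeats, seed=seed)
    return ClassifierReport(
        pairwise_auc=pair,
        macro_auc=macro_auc(pair),
        importances=importances,
        best_params=params,
        split_seed=split_seed,
        oversample_seed=oversample_seed,
        test_sample_ids=list(test_ids),
        features=features,
    )
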