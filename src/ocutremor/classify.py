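"""CFFT-range classification from gaze features.

A decision tree predicts whether a participant detected flicker at the
chosen threshold (positive class = detected, P>f) from the cumulative-
spectrum features of the four velocity components, each evaluated at its
family's best separating frequency f*.

Evaluation is a nested stratified five-fold cross-validation: the outer
folds supply untouched test sets whose pooled confusion counts are
reported; inside each outer training set an inner five-fold CV selects the
feature-family combination and the tree hyperparameters (max depth, max
features, min samples per split, min samples per leaf) by balanced
accuracy.  Because the detecting group is the minority at the higher
threshold, training folds are rebalanced with SMOTE — synthetic minority
samples interpolated between nearest minority neighbours — strictly inside
the training side of every split; test folds keep their natural class
ratio.

The module exposes the pipeline both as functions (:func:`train_eval`,
:func:`metrics_from_counts`) and as the model object :class:`CfftTreeModel`
whose ``fit()`` returns :class:`ClassificationResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations, product

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .group_stats import FStarResult, ParticipantFeatureCurve
from .psychophysics import DetectionLabels

#: Feature families entering the classifier: the four velocity components'
#: cumulative power spectra.
COMPONENT_FAMILIES: tuple[str, ...] = ("C_vx_unit", "C_vy_unit", "C_vx_fix", "C_vy_fix")

DEFAULT_GRID: dict[str, tuple] = {
    "max_depth": (2, 3, 4, 5, None),
    "max_features": (None, "sqrt"),
    "min_samples_split": (2, 4, 8),
    "min_samples_leaf": (1, 2, 4),
}


@dataclass
class FeatureMatrix:
    """Participants x features, each feature evaluated at its family's f*."""

    X: pd.DataFrame  # index: participant_id, columns: families
    y: np.ndarray  # bool, True = detected (P>f)
    threshold_freq: float
    f_star: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            bad = self.X.index[self.X.isna().any(axis=1)].tolist()
            raise ValueError(f"missing feature values for participants {bad}")
        if len(self.y) != len(self.X):
            raise ValueError("label vector length does not match the matrix")


def assemble_features(
    results: dict[str, FStarResult] | list[FStarResult],
    curves: dict[str, list[ParticipantFeatureCurve]],
    labels: DetectionLabels,
    families: tuple[str, ...] = COMPONENT_FAMILIES,
) -> FeatureMatrix:
    """Evaluate each family's curves at its f* and attach detection labels."""
    if not families:
        raise ValueError("families must be non-empty")
    if isinstance(results, list):
        results = {r.family: r for r in results}
    threshold = next(iter(results.values())).threshold_freq
    membership = None
    data: dict[str, dict[str, float]] = {}
    for fam in families:
        if fam not in results:
            raise KeyError(f"no f* result for family {fam!r}")
        f_star = results[fam].f_star
        data[fam] = {c.participant_id: c.at(f_star) for c in curves[fam]}
    pids = sorted(set.intersection(*(set(v) for v in data.values())))
    membership = labels.group(threshold)
    missing = [p for p in pids if p not in membership]
    if missing:
        raise ValueError(f"participants without detection labels: {missing}")
    X = pd.DataFrame({fam: [data[fam][p] for p in pids] for fam in families}, index=pids)
    y = np.array([membership[p] for p in pids], dtype=bool)
    return FeatureMatrix(X, y, float(threshold), {f: results[f].f_star for f in families})


def smote(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary training set by synthetic minority oversampling.

    New minority points are drawn on the segment between a minority sample
    and one of its k nearest minority neighbours (Euclidean).  k shrinks to
    ``n_minority - 1`` when the minority class is small; with a single
    minority sample, plain duplication is all that is possible.
    """
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == n_neg or min(n_pos, n_neg) == 0:
        return X, y
    minority_val = n_pos < n_neg
    Xm = X[y == minority_val]
    n_new = abs(n_pos - n_neg)
    k = min(k_neighbors, len(Xm) - 1)
    synth = np.empty((n_new, X.shape[1]))
    for i in range(n_new):
        j = int(rng.integers(0, len(Xm)))
        if k < 1:
            synth[i] = Xm[j]
            continue
        d = np.linalg.norm(Xm - Xm[j], axis=1)
        nn = np.argsort(d)[1:k + 1]
        m = int(nn[rng.integers(0, len(nn))])
        synth[i] = Xm[j] + rng.random() * (Xm[m] - Xm[j])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority_val)])
    return X_out, y_out


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and precision from confusion counts.

    Undefined rates (zero denominator) come back as None, never as 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / n if n else None,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "precision": tp / (tp + fp) if tp + fp else None,
    }


@dataclass
class EvalReport:
    """Pooled nested-CV evaluation of the CFFT-range classifier."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold_freq: float
    folds: list[dict] = field(default_factory=list)
    selected_features: list[tuple[str, ...]] = field(default_factory=list)
    hyperparams: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def metrics(self) -> dict[str, float | None]:
        return metrics_from_counts(self.tp, self.fp, self.tn, self.fn)

    def to_json(self) -> str:
        d = asdict(self)
        d["metrics"] = self.metrics
        return json.dumps(d, indent=2, default=str)

    def summary(self) -> str:
        m = self.metrics
        fmt = lambda v: "  n/a" if v is None else f"{v:5.2f}"
        lines = [
            f"CFFT-range tree classifier, threshold {self.threshold_freq:g} Hz "
            f"(positive = detected)",
            f"pooled over {len(self.folds)} outer folds, n = {self.n}",
            "",
            f"  True Positives   {self.tp:4d}    False Positives  {self.fp:4d}",
            f"  True Negatives   {self.tn:4d}    False Negatives  {self.fn:4d}",
            "",
            f"  Accuracy     {fmt(m['accuracy'])}",
            f"  Sensitivity  {fmt(m['sensitivity'])}",
            f"  Specificity  {fmt(m['specificity'])}",
            f"  Precision    {fmt(m['precision'])}",
        ]
        return "\n".join(lines)


def _grid_iter(grid: dict[str, tuple]):
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _balanced_folds(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_splits: int,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """SMOTE-balanced training folds with untouched test folds.

    Built once per feature combination: every hyperparameter candidate is
    scored on the same balanced folds (a paired comparison).
    """
    n_per_class = min(int(y.sum()), int((~y).sum()))
    splits = max(2, min(n_splits, n_per_class))
    cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    folds = []
    for tr, te in cv.split(X, y):
        Xb, yb = smote(X[tr], y[tr], rng)
        folds.append((Xb, yb, X[te], y[te]))
    return folds


def _inner_score(folds, params: dict, seed: int, score) -> float:
    scores = []
    for Xb, yb, Xte, yte in folds:
        clf = DecisionTreeClassifier(random_state=seed, **params)
        clf.fit(Xb, yb)
        scores.append(score(yte, clf.predict(Xte)))
    return float(np.mean(scores))


def train_eval(
    matrix: FeatureMatrix,
    seed: int = 0,
    param_grid: dict[str, tuple] | None = None,
    n_splits: int = 5,
    scoring: str = "balanced_accuracy",
) -> EvalReport:
    """Nested stratified CV of the decision-tree classifier.

    Outer ``n_splits``-fold CV supplies untouched test folds; within each
    outer training set, an inner CV scores every non-empty feature-family
    combination crossed with the hyperparameter grid and the best
    (by balanced accuracy, or plain accuracy with ``scoring="accuracy"``)
    configuration is refit on the SMOTE-balanced outer training set.
    Confusion counts are pooled over the outer test folds.
    """
    grid = param_grid or DEFAULT_GRID
    y = matrix.y
    if min(int(y.sum()), int((~y).sum())) < 2:
        raise ValueError("need at least 2 participants in each class")
    if scoring == "balanced_accuracy":
        score = balanced_accuracy_score
    elif scoring == "accuracy":
        score = lambda a, b: float(np.mean(a == b))
    else:
        raise ValueError("scoring must be 'balanced_accuracy' or 'accuracy'")

    families = list(matrix.X.columns)
    combos = [
        c for r in range(1, len(families) + 1) for c in combinations(families, r)
    ]
    outer = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    X_all = matrix.X.to_numpy()
    col = {f: i for i, f in enumerate(families)}

    tp = fp = tn = fn = 0
    folds, chosen_feats, chosen_params = [], [], []
    rng = np.random.default_rng(seed)
    for fold_i, (tr, te) in enumerate(outer.split(X_all, y)):
        best = (-np.inf, None, None)
        for feats in combos:
            Xc = X_all[np.ix_(tr, [col[f] for f in feats])]
            folds_c = _balanced_folds(Xc, y[tr], seed, n_splits)
            for params in _grid_iter(grid):
                if len(feats) == 1 and params["max_features"] == "sqrt":
                    continue  # identical to max_features=None on one column
                s = _inner_score(folds_c, params, seed, score)
                if s > best[0]:
                    best = (s, feats, params)
        _, feats, params = best
        idx = [col[f] for f in feats]
        Xb, yb = smote(X_all[np.ix_(tr, idx)], y[tr], rng)
        clf = DecisionTreeClassifier(random_state=seed, **params)
        clf.fit(Xb, yb)
        pred = clf.predict(X_all[np.ix_(te, idx)])
        truth = y[te]
        f_tp = int(np.sum(pred & truth))
        f_fp = int(np.sum(pred & ~truth))
        f_tn = int(np.sum(~pred & ~truth))
        f_fn = int(np.sum(~pred & truth))
        tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
        folds.append(
            {"fold": fold_i, "tp": f_tp, "fp": f_fp, "tn": f_tn, "fn": f_fn,
             "features": feats, "params": params, "inner_score": best[0]}
        )
        chosen_feats.append(feats)
        chosen_params.append(params)
    return EvalReport(
        tp, fp, tn, fn, matrix.threshold_freq, folds, chosen_feats, chosen_params, seed
    )


class CfftTreeModel:
    """Model: decision-tree prediction of the CFFT range from gaze features."""

    def __init__(
        self,
        matrix: FeatureMatrix,
        param_grid: dict[str, tuple] | None = None,
        n_splits: int = 5,
        scoring: str = "balanced_accuracy",
    ):
        self.matrix = matrix
        self.param_grid = param_grid or DEFAULT_GRID
        self.n_splits = n_splits
        self.scoring = scoring

    def fit(self, seed: int = 0) -> "ClassificationResults":
        report = train_eval(
            self.matrix, seed=seed, param_grid=self.param_grid,
            n_splits=self.n_splits, scoring=self.scoring,
        )
        return ClassificationResults(self, report)


class ClassificationResults:
    """Fitted classifier evaluation; delegates the report surface."""

    def __init__(self, model: CfftTreeModel, report: EvalReport):
        self.model = model
        self.report = report

    @property
    def metrics(self) -> dict[str, float | None]:
        return self.report.metrics

    def summary(self) -> str:
        return self.report.summary()
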