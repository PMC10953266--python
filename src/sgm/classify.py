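"""Random-forest group discrimination with repeated nested stratified CV.

The outer loop is repeated stratified 5-fold cross-validation; inside
each outer training fold a further stratified 5-fold grid search picks
the tree depth by mean AUROC (ties go to the shallowest). Importances
are averaged over every trained outer forest. Threshold-based metrics
use a 0.5 probability cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

__all__ = ["CVConfig", "ClassifierReport", "classify_cohort"]


@dataclass(frozen=True)
class CVConfig:
    n_outer_folds: int = 5
    n_repeats: int = 10  # desk-scale default; the full protocol uses 100
    inner_folds: int = 5
    max_depth_grid: tuple = (None, 2, 3, 4)
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ClassifierReport:
    auroc_mean: float
    auroc_sd: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    feature_importances: dict[str, float]
    confusion_matrix: np.ndarray
    n_forests: int
    config: CVConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "auroc_mean": self.auroc_mean,
            "auroc_sd": self.auroc_sd,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "feature_importances": self.feature_importances,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "n_forests": self.n_forests,
        }


def _depth_sort_key(depth):
    # shallower first; None (unbounded) last so ties prefer shallow trees
    return (depth is None, depth if depth is not None else 0)


def classify_cohort(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: CVConfig | None = None,
    feature_names: list[str] | None = None,
    corrupt_test_rng: np.random.Generator | None = None,
) -> ClassifierReport:
    """Nested stratified cross-validation of a random-forest classifier.

    ``features`` is subjects x features (fitted parameters plus age),
    ``labels`` binary group membership. Returns fold-aggregated AUROC,
    threshold metrics, mean feature importances and the summed confusion
    matrix.

    ``corrupt_test_rng`` replaces each held-out fold's features with
    noise *after* training; fitted forests (and hence importances) must
    be unaffected — a structural no-leakage probe used by the tests.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    y = (y == np.unique(y)[1]).astype(int)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    depth_grid = sorted(cfg.max_depth_grid, key=_depth_sort_key)

    rng = np.random.default_rng(cfg.seed)
    aurocs, accs, precs, recs, f1s = [], [], [], [], []
    importances = np.zeros(X.shape[1])
    conf = np.zeros((2, 2), dtype=int)
    n_forests = 0

    for _ in range(cfg.n_repeats):
        outer_seed = int(rng.integers(2**31 - 1))
        outer = StratifiedKFold(
            n_splits=cfg.n_outer_folds, shuffle=True, random_state=outer_seed
        )
        for train_idx, test_idx in outer.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            Xte, yte = X[test_idx], y[test_idx]
            inner_seed = int(rng.integers(2**31 - 1))
            best_depth, best_score = depth_grid[0], -np.inf
            inner = StratifiedKFold(
                n_splits=cfg.inner_folds, shuffle=True, random_state=inner_seed
            )
            splits = list(inner.split(Xtr, ytr))
            for depth in depth_grid:
                scores = []
                for itr, ite in splits:
                    clf = RandomForestClassifier(
                        n_estimators=cfg.n_estimators,
                        max_depth=depth,
                        random_state=inner_seed,
                    )
                    clf.fit(Xtr[itr], ytr[itr])
                    proba = clf.predict_proba(Xtr[ite])[:, 1]
                    scores.append(roc_auc_score(ytr[ite], proba))
                score = float(np.mean(scores))
                if score > best_score:
                    best_score, best_depth = score, depth
            clf = RandomForestClassifier(
                n_estimators=cfg.n_estimators,
                max_depth=best_depth,
                random_state=inner_seed,
            )
            clf.fit(Xtr, ytr)
            if corrupt_test_rng is not None:
                Xte = corrupt_test_rng.standard_normal(Xte.shape)
            proba = clf.predict_proba(Xte)[:, 1]
            pred = (proba >= 0.5).astype(int)
            aurocs.append(roc_auc_score(yte, proba))
            accs.append(accuracy_score(yte, pred))
            precs.append(precision_score(yte, pred, zero_division=0))
            recs.append(recall_score(yte, pred, zero_division=0))
            f1s.append(f1_score(yte, pred, zero_division=0))
            conf += confusion_matrix(yte, pred, labels=[0, 1])
            importances += clf.feature_importances_
            n_forests += 1

    importances /= n_forests
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return ClassifierReport(
        auroc_mean=float(np.mean(aurocs)),
        auroc_sd=float(np.std(aurocs)),
        accuracy=float(np.mean(accs)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        feature_importances=dict(zip(feature_names, importances.tolist())),
        confusion_matrix=conf,
        n_forests=n_forests,
        config=cfg,
    )
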