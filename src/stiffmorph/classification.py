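"""Correlation-based feature pruning and the random-forest morph classifier.

Pruning removes, iteratively, one member of the most correlated feature pair
(|Pearson r| above the threshold) until no pair exceeds it; the member with
the higher mean absolute correlation to all remaining features is dropped
(tie -> the later column).  The classifier is a random forest tuned by
randomised search with stratified 5-fold cross-validation on a 90% training
split and evaluated by the class-frequency-weighted F1 score on the held-out
10%, reflecting the unequal morph sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import classification_report, confusion_matrix, f1_score
from sklearn.model_selection import RandomizedSearchCV, train_test_split

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.8
TEST_FRACTION = 0.1
CV_FOLDS = 5
SEARCH_DRAWS = 50

#: Randomised-search space of the forest.
SEARCH_SPACE = {
    "n_estimators": [100, 200, 300, 400],
    "max_depth": [None, 8, 12, 16, 24],
    "min_samples_leaf": [1, 2, 4, 8],
    "max_features": ["sqrt", "log2", 0.3, 0.5],
}


@dataclass
class ClassifierReport:
    """Evaluation record of one trained morph classifier."""

    selected_features: list[str]
    best_params: dict
    weighted_f1: float
    per_class: dict
    confusion: np.ndarray
    classes: list[int]
    test_index: list
    train_index: list
    seed: int
    dropped_features: list[str] = field(default_factory=list)


def select_features(
    table: pd.DataFrame, r_threshold: float = R_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop one feature of every |r| > threshold pair.

    Constant columns are removed first (reason logged).  Deterministic and
    idempotent; the result has all pairwise |r| <= threshold.
    Returns (reduced table, excluded column names in drop order).
    """
    X = table.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    excluded: list[str] = []
    const = [c for c in X.columns if X[c].std(ddof=0) == 0]
    if const:
        logger.info("select_features: dropping %d constant columns", len(const))
        excluded += const
        X = X.drop(columns=const)

    corr = X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    cols = list(X.columns)
    while True:
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        mean_i = corr[i].sum() / (corr.shape[0] - 1)
        mean_j = corr[j].sum() / (corr.shape[0] - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: later column order
        excluded.append(cols[drop])
        cols.pop(drop)
        corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
    return table[cols], excluded


def train_rf(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    test_frac: float = TEST_FRACTION,
    seed: int = 0,
    n_iter: int = SEARCH_DRAWS,
) -> tuple[RandomForestClassifier, ClassifierReport]:
    """Train and evaluate the morph classifier on a stratified 90/10 split."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 3:
        raise ValueError("need >= 3 classes")
    if len(table) < 100:
        raise ValueError("need >= 100 rows")
    X = table.to_numpy(dtype=float)
    idx = np.arange(len(table))
    idx_train, idx_test = train_test_split(
        idx, test_size=test_frac, stratify=y, random_state=seed
    )
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=seed),
        SEARCH_SPACE,
        n_iter=n_iter,
        cv=CV_FOLDS,
        scoring="f1_weighted",
        random_state=seed,
        n_jobs=1,
    )
    search.fit(X[idx_train], y[idx_train])
    model: RandomForestClassifier = search.best_estimator_  # refit on full train
    y_pred = model.predict(X[idx_test])
    classes = sorted(int(c) for c in np.unique(y))
    report = ClassifierReport(
        selected_features=list(table.columns),
        best_params=search.best_params_,
        weighted_f1=float(f1_score(y[idx_test], y_pred, average="weighted")),
        per_class=classification_report(
            y[idx_test], y_pred, output_dict=True, zero_division=0
        ),
        confusion=confusion_matrix(y[idx_test], y_pred, labels=classes),
        classes=classes,
        test_index=[int(i) for i in idx_test],
        train_index=[int(i) for i in idx_train],
        seed=seed,
    )
    logger.info(
        "train_rf: weighted F1 = %.4f with %s", report.weighted_f1, report.best_params
    )
    return model, report


def weighted_f1_from_confusion(confusion: np.ndarray) -> float:
    """Closed-form class-frequency-weighted F1 from a confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    support = confusion.sum(axis=1)
    f1s = []
    for k in range(confusion.shape[0]):
        tp = confusion[k, k]
        fp = confusion[:, k].sum() - tp
        fn = support[k] - tp
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float((np.asarray(f1s) * support).sum() / support.sum())


def predict_morphs(
    model: RandomForestClassifier,
    clumped_table: pd.DataFrame,
    selected_features: list[str],
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Predict morphs of clumped cells and summarise their composition.

    Raises a schema error listing missing feature columns.  The composition
    summary (with scene-grouped 95% CIs) is computed when ``metadata`` with a
    ``scene_id`` column is given; for an empty table both outputs are empty.
    """
    missing = [c for c in selected_features if c not in clumped_table.columns]
    if missing:
        raise KeyError(f"clumped table lacks selected features: {missing[:10]}")
    if len(clumped_table) == 0:
        return pd.Series([], dtype=int, name="morph"), None
    pred = pd.Series(
        model.predict(clumped_table[selected_features].to_numpy(dtype=float)),
        index=clumped_table.index,
        name="morph",
    )
    summary = None
    if metadata is not None:
        from .morphotyping import composition_by_condition

        meta = metadata.loc[clumped_table.index]
        summary = composition_by_condition(
            pred, meta.assign(stiffness_kpa=meta["stiffness_kpa"])
        )
    return pred, summary
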