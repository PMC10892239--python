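"""Condition classification from significant metrics, grid-searched CV.

Feature vectors are the baseline-standardized values of every
(metric, band, channel) triple flagged significant for the chosen
band-set; one sample per (subject, window epoch, condition).  Four
classifier families are evaluated with stratified 10-fold
cross-validation and a hyperparameter grid search:

* kNN: Euclidean distance, inverse-distance vote weights,
  k in {1, ..., 10} (zero-distance neighbours take the whole vote);
* linear SVM: hinge loss, C in {0.1, 1, 5, 10, 20, 50, 100};
* RBF SVM: same C grid, kernel width gamma = 1 / (N * sigma^2) with N
  the feature count and sigma^2 the pooled variance of the (scaled)
  training-fold feature matrix;
* gradient-boosted trees (XGBoost): gain threshold gamma = 1, learning
  rate 0.1, L2 penalty lambda in {1, ..., 10}, 100 trees of depth 3.

Features are z-scored with training-fold statistics only (no leakage of
test-fold moments); the reported accuracy is the fold mean +/- standard
error over the 10 folds at the best grid value.  Hyperparameters are
selected on the same folds used for reporting (optimistic variant);
``subject_grouped=True`` keeps all rows of a subject in one fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats import BAND_NAMES, DEFAULT_WINDOW

__all__ = [
    "FeatureMatrix",
    "CVReport",
    "DEFAULT_GRIDS",
    "BAND_SETS",
    "build_features",
    "knn_classifier",
    "linear_svm",
    "rbf_svm",
    "xgboost_classifier",
    "grid_search_cv",
    "run_band_battery",
    "battery_table",
]

CLASSIFIER_FAMILIES: tuple[str, ...] = ("knn", "svm_linear", "svm_rbf", "xgboost")
BAND_SETS: tuple[str, ...] = BAND_NAMES + ("all",)

DEFAULT_GRIDS: dict[str, tuple] = {
    "knn": tuple(range(1, 11)),
    "svm_linear": (0.1, 1, 5, 10, 20, 50, 100),
    "svm_rbf": (0.1, 1, 5, 10, 20, 50, 100),
    "xgboost": tuple(range(1, 11)),
}
_PARAM_NAME = {"knn": "k", "svm_linear": "C", "svm_rbf": "C", "xgboost": "lambda"}


@dataclass
class FeatureMatrix:
    """Samples x flagged-feature matrix with condition labels."""

    X: pd.DataFrame  # index: (subject_id, epoch_group, condition)
    y: np.ndarray  # condition label per row
    subjects: np.ndarray
    band_set: str
    n_dropped: int = 0


@dataclass
class CVReport:
    classifier: str
    band_set: str
    accuracy_mean: float  # percent
    accuracy_se: float  # percent
    best_params: dict
    fold_accuracies: list[float] = field(default_factory=list)
    seed: int = 0


def build_features(
    std_table: pd.DataFrame,
    significance: pd.DataFrame,
    band_set: str = "all",
    window: Sequence[int] = DEFAULT_WINDOW,
) -> FeatureMatrix:
    """Assemble the flagged-triple feature matrix for one band-set.

    ``significance`` either carries a boolean ``significant`` column
    (a computed significance table) or is a bare list of flagged
    (metric, band, channel) triples (the packaged published table).
    Values stay raw standardized ratios; scaling happens per training
    fold at fit time.  Rows with any missing feature are dropped and
    counted.
    """
    if "significant" in significance.columns:
        flagged = significance[significance["significant"].fillna(False)]
    else:
        flagged = significance
    if band_set != "all":
        flagged = flagged[flagged["band"] == band_set]
    flagged = flagged[["metric", "band", "channel"]].drop_duplicates()
    if flagged.empty:
        raise ValueError(f"no significant features for band set {band_set!r}")

    data = std_table[std_table["epoch_group"].isin(list(window))].merge(
        flagged, on=["metric", "band", "channel"]
    )
    data = data.assign(
        feature=data["metric"] + ":" + data["band"] + ":" + data["channel"]
    )
    wide = data.pivot_table(
        index=["subject_id", "epoch_group", "condition"],
        columns="feature",
        values="value_std",
        observed=True,
    )
    expected_cols = len(flagged)
    n_before = len(wide)
    wide = wide.dropna()
    if wide.shape[1] != expected_cols:
        missing = expected_cols - wide.shape[1]
        raise ValueError(f"{missing} flagged features have no data at all")
    y = wide.index.get_level_values("condition").to_numpy()
    subjects = wide.index.get_level_values("subject_id").to_numpy()
    return FeatureMatrix(
        X=wide, y=y, subjects=subjects, band_set=band_set,
        n_dropped=n_before - len(wide),
    )


# --- Model specifications ----------------------------------------------------


def knn_classifier(k: int) -> KNeighborsClassifier:
    """Inverse-distance-weighted Euclidean kNN."""
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    return KNeighborsClassifier(n_neighbors=int(k), weights="distance", metric="euclidean")


def linear_svm(C: float) -> SVC:
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    return SVC(kernel="linear", C=C)


def rbf_svm(C: float, gamma: float) -> SVC:
    if C <= 0 or gamma <= 0:
        raise ValueError(f"C and gamma must be positive, got C={C}, gamma={gamma}")
    return SVC(kernel="rbf", C=C, gamma=gamma)


def xgboost_classifier(reg_lambda: float, seed: int = 0):
    """Boosted trees: gamma=1, learning rate 0.1, 100 trees, depth 3."""
    from xgboost import XGBClassifier

    if reg_lambda <= 0:
        raise ValueError(f"lambda must be positive, got {reg_lambda}")
    return XGBClassifier(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        gamma=1.0,
        reg_lambda=float(reg_lambda),
        subsample=1.0,
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        tree_method="hist",
    )


def _make_model(family: str, param, gamma: float | None, seed: int):
    if family == "knn":
        return knn_classifier(param)
    if family == "svm_linear":
        return linear_svm(param)
    if family == "svm_rbf":
        return rbf_svm(param, gamma)
    if family == "xgboost":
        return xgboost_classifier(param, seed=seed)
    raise ValueError(f"unknown classifier family {family!r}")


def grid_search_cv(
    features: FeatureMatrix,
    family: str,
    grid: Sequence | None = None,
    seed: int = 0,
    n_folds: int = 10,
    subject_grouped: bool = False,
    rbf_gamma: str = "pooled",
) -> CVReport:
    """Grid-searched stratified k-fold CV accuracy for one classifier family.

    For each grid value the mean held-out accuracy over the fixed folds
    is computed (features z-scored from training folds only; the RBF
    gamma = 1/(N * sigma^2) recomputed per training fold, with sigma^2
    pooled over all entries or per feature); the best value's fold
    accuracies are reported as mean +/- SE in percent.
    """
    X = features.X.to_numpy(dtype=float)
    labels = np.unique(features.y)
    if len(X) < 20:
        raise ValueError(f"need >= 20 samples for {n_folds}-fold CV, got {len(X)}")
    if labels.size != 2:
        raise ValueError(f"need both classes present, got {labels}")
    y = (features.y == labels[1]).astype(int)
    grid = tuple(grid if grid is not None else DEFAULT_GRIDS[family])

    if subject_grouped:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(X, y, groups=features.subjects))
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(X, y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a class is absent from a training fold")

    accs = np.zeros((len(grid), len(folds)))
    for gi, param in enumerate(grid):
        for fi, (tr, te) in enumerate(folds):
            scaler = StandardScaler().fit(X[tr])
            Xtr = scaler.transform(X[tr])
            Xte = scaler.transform(X[te])
            gamma = None
            if family == "svm_rbf":
                var = Xtr.var() if rbf_gamma == "pooled" else Xtr.var(axis=0).mean()
                gamma = 1.0 / (X.shape[1] * max(var, 1e-12))
            model = _make_model(family, param, gamma, seed)
            model.fit(Xtr, y[tr])
            accs[gi, fi] = (model.predict(Xte) == y[te]).mean()

    mean_acc = accs.mean(axis=1)
    best = int(np.argmax(mean_acc))
    fold_accs = accs[best]
    return CVReport(
        classifier=family,
        band_set=features.band_set,
        accuracy_mean=float(100.0 * fold_accs.mean()),
        accuracy_se=float(100.0 * fold_accs.std(ddof=1) / np.sqrt(len(folds))),
        best_params={_PARAM_NAME[family]: grid[best]},
        fold_accuracies=[float(100.0 * a) for a in fold_accs],
        seed=seed,
    )


def run_band_battery(
    std_table: pd.DataFrame,
    significance: pd.DataFrame,
    seed: int = 0,
    window: Sequence[int] = DEFAULT_WINDOW,
    families: Sequence[str] = CLASSIFIER_FAMILIES,
    band_sets: Sequence[str] = BAND_SETS,
    subject_grouped: bool = False,
    grids: dict | None = None,
) -> list[CVReport]:
    """Evaluate every classifier on every band-set (default 4 x 6 = 24)."""
    reports: list[CVReport] = []
    for band_set in band_sets:
        features = build_features(std_table, significance, band_set=band_set, window=window)
        for family in families:
            reports.append(
                grid_search_cv(
                    features, family, seed=seed, subject_grouped=subject_grouped,
                    grid=(grids or {}).get(family),
                )
            )
    return reports


def battery_table(reports: Sequence[CVReport]) -> pd.DataFrame:
    """Flatten CV reports into a results table."""
    return pd.DataFrame(
        [
            {
                "classifier": r.classifier,
                "band_set": r.band_set,
                "accuracy_mean": r.accuracy_mean,
                "accuracy_se": r.accuracy_se,
                "best_params": str(r.best_params),
                "seed": r.seed,
            }
            for r in reports
        ]
    )
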