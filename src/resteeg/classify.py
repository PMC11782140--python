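"""Two-round feature screening and cross-validated classification.

Screening follows the two-round scheme: a feature survives round 1 if
its two-sided Mann-Whitney p-value between groups is below alpha, and
round 2 if a linear SVM trained on that feature alone reaches the
accuracy threshold (default 70%) under stratified 10-fold CV. The
surviving set feeds a linear-kernel SVM evaluated by stratified 10-fold
CV, with features standardized inside each training fold to avoid scale
leakage. AD is the positive class for sensitivity.

Screening on the full dataset before CV (the default here) follows the
described two-round protocol but is optimistically biased;
``compare_paradigms(..., nested=True)`` repeats the screening inside
every training fold instead, for an honest error estimate.

Two feature-construction paradigms are compared: features from the
eyes-closed condition alone, versus those combined with eyes-closed
minus eyes-open difference features (alpha reactivity carries group
information of its own).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import DataError, ScreeningError
from .io import FeatureTable, SubjectMeta
from .stats import build_ec_minus_eo, mann_whitney_u, residualize

POSITIVE_GROUP = "AD"


@dataclass
class FeatureSetSpec:
    name: str  # "EC_only" | "EC_plus_ECminusEO" | ad hoc
    features: list[str]
    round1_kept: int = 0
    round2_kept: int = 0

    def __post_init__(self) -> None:
        if not self.features:
            raise ScreeningError(
                f"{self.name}: screening left no features "
                f"(round 1 kept {self.round1_kept}, round 2 kept {self.round2_kept})"
            )


@dataclass
class CVResult:
    fold_assignments: np.ndarray  # per subject, 0..k-1
    y_true: np.ndarray  # 1 = AD
    y_pred: np.ndarray
    decision_values: np.ndarray
    accuracy: float
    sensitivity: float  # TP / (TP + FN), AD positive
    specificity: float  # TN / (TN + FP)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "seed": self.seed,
        }


def labels_from_metas(metas: Sequence[SubjectMeta], subjects: Sequence[str]) -> np.ndarray:
    by_id = {m.subject_id: m for m in metas}
    return np.array([1 if by_id[s].group == POSITIVE_GROUP else 0 for s in subjects])


def roc_auc(decision_values: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (threshold sweep over the scores) and trapezoidal AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(decision_values, float)
    if len(np.unique(labels)) < 2:
        raise DataError("ROC/AUC undefined with a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(sk_auc(fpr, tpr))


def _classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / max(1, tp + tn + fp + fn)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return accuracy, sensitivity, specificity


def _make_estimator(kind: str, seed: int, C: float, n_trees: int):
    if kind == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    if kind == "rf":
        return make_pipeline(
            StandardScaler(),
            RandomForestClassifier(n_estimators=n_trees, random_state=seed),
        )
    raise ValueError(kind)


def _folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds whose training splits contain both classes."""
    if np.bincount(labels, minlength=2).min() < 2:
        raise DataError("need at least 2 subjects per class for CV")
    for attempt in range(100):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(labels.size), labels))
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in splits):
            return splits
    raise DataError("could not draw folds with both classes in every training split")


def _crossval(
    table: FeatureTable,
    labels: np.ndarray,
    feature_names: Sequence[str],
    kind: str,
    k: int,
    seed: int,
    C: float,
    n_trees: int,
    nested_screen: dict | None = None,
) -> CVResult:
    labels = np.asarray(labels, int)
    x_full = table.df[list(feature_names)].to_numpy(float)
    if labels.size != x_full.shape[0]:
        raise DataError("labels and table rows disagree")
    if not np.all(np.isfinite(x_full)):
        raise DataError("non-finite feature values")
    k = min(k, int(np.bincount(labels, minlength=2).min()))
    splits = _folds(labels, k, seed)

    fold_of = np.full(labels.size, -1)
    y_pred = np.zeros(labels.size, int)
    scores = np.zeros(labels.size, float)
    for fold, (tr, te) in enumerate(splits):
        cols = np.arange(x_full.shape[1])
        if nested_screen is not None:
            sub = FeatureTable(table.df.iloc[tr][list(feature_names)])
            kept = _screen_feature_names(sub, labels[tr], **nested_screen)
            if not kept:  # nothing survives in this fold: keep the full pool
                kept = list(feature_names)
            cols = np.array([list(feature_names).index(f) for f in kept])
        est = _make_estimator(kind, seed, C, n_trees)
        est.fit(x_full[np.ix_(tr, cols)], labels[tr])
        x_te = x_full[np.ix_(te, cols)]
        y_pred[te] = est.predict(x_te)
        if kind == "svm":
            scores[te] = est.decision_function(x_te)
        else:
            scores[te] = est.predict_proba(x_te)[:, 1]
        fold_of[te] = fold
    accuracy, sensitivity, specificity = _classification_metrics(labels, y_pred)
    fpr, tpr, auc_value = roc_auc(scores, labels)
    return CVResult(
        fold_assignments=fold_of,
        y_true=labels,
        y_pred=y_pred,
        decision_values=scores,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        fpr=fpr,
        tpr=tpr,
        auc=auc_value,
        seed=seed,
    )


def crossval_svm(
    table: FeatureTable,
    labels: Sequence[int],
    feature_set: FeatureSetSpec | Sequence[str],
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> CVResult:
    """Stratified k-fold linear-kernel SVM; metrics pooled over held-out folds."""
    names = feature_set.features if isinstance(feature_set, FeatureSetSpec) else list(feature_set)
    return _crossval(table, np.asarray(labels), names, "svm", k, seed, C, 0)


def crossval_rf(
    table: FeatureTable,
    labels: Sequence[int],
    feature_set: FeatureSetSpec | Sequence[str],
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> CVResult:
    """Random-forest comparator under the same CV protocol."""
    names = feature_set.features if isinstance(feature_set, FeatureSetSpec) else list(feature_set)
    return _crossval(table, np.asarray(labels), names, "rf", k, seed, 1.0, n_trees)


def _screen_feature_names(
    table: FeatureTable,
    labels: np.ndarray,
    alpha: float = 0.05,
    acc_threshold: float = 0.70,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> list[str]:
    labels = np.asarray(labels, int)
    round1 = []
    for feat in table.feature_names:
        vals = table.df[feat].to_numpy(float)
        _, p = mann_whitney_u(vals[labels == 1], vals[labels == 0])
        if p < alpha:
            round1.append(feat)
    round2 = []
    for feat in round1:
        cv = _crossval(table, labels, [feat], "svm", k, seed, C, 0)
        if cv.accuracy >= acc_threshold:
            round2.append(feat)
    return round2


def screen_features(
    table: FeatureTable,
    labels: Sequence[int],
    alpha: float = 0.05,
    acc_threshold: float = 0.70,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    name: str = "screened",
) -> FeatureSetSpec:
    """Two-round screening: Mann-Whitney p < alpha, then single-feature CV accuracy.

    Raises ScreeningError (with round-wise counts) when nothing survives.
    """
    labels = np.asarray(labels, int)
    round1 = []
    for feat in table.feature_names:
        vals = table.df[feat].to_numpy(float)
        _, p = mann_whitney_u(vals[labels == 1], vals[labels == 0])
        if p < alpha:
            round1.append(feat)
    round2 = []
    for feat in round1:
        cv = _crossval(table, labels, [feat], "svm", k, seed, C, 0)
        if cv.accuracy >= acc_threshold:
            round2.append(feat)
    if not round2:
        raise ScreeningError(
            f"{name}: no features survived screening "
            f"(round 1 kept {len(round1)} of {len(table.feature_names)}, round 2 kept 0)"
        )
    return FeatureSetSpec(
        name=name, features=round2, round1_kept=len(round1), round2_kept=len(round2)
    )


@dataclass
class ParadigmComparison:
    ec_features: FeatureSetSpec
    combined_features: FeatureSetSpec
    ec_result: CVResult
    combined_result: CVResult

    def to_dict(self) -> dict:
        return {
            "EC_only": {
                "features": self.ec_features.features,
                **self.ec_result.to_dict(),
            },
            "EC_plus_ECminusEO": {
                "features": self.combined_features.features,
                **self.combined_result.to_dict(),
            },
        }


def compare_paradigms(
    ec_table: FeatureTable,
    eo_table: FeatureTable,
    metas: Sequence[SubjectMeta],
    seed: int = 0,
    alpha: float = 0.05,
    acc_threshold: float = 0.70,
    k: int = 10,
    C: float = 1.0,
    covariates: Sequence[str] = ("age", "sex", "education"),
    nested: bool = False,
) -> ParadigmComparison:
    """EC-only vs EC + (EC-EO) feature paradigms, screened and cross-validated.

    Both candidate pools are residualized against the covariates before
    screening. If no EC-EO feature survives screening the combined
    paradigm degenerates to the EC-only pool. With ``nested=True`` the
    two-round screening is refit inside every training fold over the
    full candidate pools (the reported feature sets still come from the
    full-data screening, for reference).
    """
    subjects = [s for s in ec_table.subjects if s in set(eo_table.subjects)]
    ec = FeatureTable(ec_table.df.loc[subjects])
    eo = FeatureTable(eo_table.df.loc[subjects])
    labels = labels_from_metas(metas, subjects)

    ec_resid = residualize(ec, metas, covariates)
    fs_ec = screen_features(
        ec_resid, labels, alpha=alpha, acc_threshold=acc_threshold, k=k, seed=seed, C=C,
        name="EC_only",
    )

    diff = build_ec_minus_eo(ec, eo)
    diff_resid = residualize(diff, metas, covariates)
    try:
        fs_diff = screen_features(
            diff_resid, labels, alpha=alpha, acc_threshold=acc_threshold, k=k, seed=seed,
            C=C, name="ECminusEO",
        )
        diff_features = fs_diff.features
    except ScreeningError:
        diff_features = []

    both = FeatureTable(
        ec_resid.df.join(diff_resid.df.loc[ec_resid.df.index])
    )
    fs_combined = FeatureSetSpec(
        name="EC_plus_ECminusEO",
        features=fs_ec.features + diff_features,
        round1_kept=fs_ec.round1_kept,
        round2_kept=len(fs_ec.features) + len(diff_features),
    )

    if nested:
        screen_params = dict(alpha=alpha, acc_threshold=acc_threshold, k=k, seed=seed, C=C)
        cv_ec = _crossval(ec_resid, labels, ec_resid.feature_names, "svm", k, seed, C, 0,
                          nested_screen=screen_params)
        cv_combined = _crossval(both, labels, both.feature_names, "svm", k, seed, C, 0,
                                nested_screen=screen_params)
    else:
        cv_ec = crossval_svm(ec_resid, labels, fs_ec, k=k, seed=seed, C=C)
        cv_combined = crossval_svm(both, labels, fs_combined, k=k, seed=seed, C=C)
    return ParadigmComparison(
        ec_features=fs_ec,
        combined_features=fs_combined,
        ec_result=cv_ec,
        combined_result=cv_combined,
    )
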