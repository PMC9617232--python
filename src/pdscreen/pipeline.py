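"""Feature-table assembly, greedy feature selection and classifier benchmarking.

The diagnostic question is binary: Parkinson's disease (label 1) versus
control (label 0).  Nine classical classifiers are benchmarked; each one also
serves as the base model of a sequential forward selection (SFS) wrapper that
greedily adds the feature maximising the mean out-of-fold AUROC under
stratified k-fold cross-validation.  Performance is always reported from
pooled out-of-fold predicted scores: AUROC (trapezoidal) with a 95% CI
(stratified bootstrap by default, DeLong optionally), plus accuracy,
precision, recall and F1 at the 0.5 score cutoff.

Scale-sensitive models (kNN, SVM, logistic regression) are standardised with
train-fold statistics only; tree ensembles consume raw feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.stats import norm
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import io as pio
from .errors import AssemblyError, InputError, LeakageError
from .types import SubjectRecord

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "Metrics",
    "EvaluationReport",
    "make_classifier",
    "build_table",
    "sequential_forward_selection",
    "selection_coverage",
    "cross_validated_evaluation",
    "run_experiment",
]

CLASSIFIER_NAMES = (
    "decision_tree_c45",
    "knn",
    "svm",
    "naive_bayes",
    "random_forest",
    "logistic_regression",
    "gradient_boosting",
    "adaboost",
    "lightgbm",
)

#: models whose geometry is scale-sensitive and get a train-fold StandardScaler
_SCALED = {"knn", "svm", "logistic_regression"}

FEATURE_SETS = ("face_only", "voice_only", "combined", "combined_plus_demographics")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the nine registered classifiers plus overrides and a seed."""

    name: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise InputError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn/lightgbm estimator for a spec.

    ``decision_tree_c45`` is approximated by an entropy-criterion CART tree
    (no C4.5 rule post-pruning); all other models are library defaults.
    """
    seed = int(spec.seed) % (2**31)
    name = spec.name
    if name == "decision_tree_c45":
        est = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    elif name == "knn":
        est = KNeighborsClassifier()
    elif name == "svm":
        est = SVC(probability=True, random_state=seed)
    elif name == "naive_bayes":
        est = GaussianNB()
    elif name == "random_forest":
        est = RandomForestClassifier(random_state=seed)
    elif name == "logistic_regression":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif name == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed)
    elif name == "adaboost":
        est = AdaBoostClassifier(random_state=seed)
    elif name == "lightgbm":
        est = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    if spec.hyperparameters:
        est.set_params(**dict(spec.hyperparameters))
    if name in _SCALED:
        est = Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """All nine classifiers with per-classifier seeds derived from one seed."""
    states = np.random.SeedSequence(seed).generate_state(len(CLASSIFIER_NAMES))
    return [
        ClassifierSpec(name, seed=int(s) % (2**31))
        for name, s in zip(CLASSIFIER_NAMES, states)
    ]


# ---------------------------------------------------------------- table


def _as_dict(features) -> dict:
    return features.to_dict() if hasattr(features, "to_dict") else dict(features)


def build_table(
    voice: Mapping[str, object] | None,
    face: Mapping[str, object] | None,
    meta: Sequence[SubjectRecord],
    feature_set: str = "combined_plus_demographics",
) -> pd.DataFrame:
    """Assemble the subjects-by-features modelling table.

    Sex is encoded male=1 / female=0 and the label PD=1 / control=0.  The
    optional phonetic score is carried through only when every subject has it.
    """
    if feature_set not in FEATURE_SETS:
        raise InputError(f"feature_set must be one of {FEATURE_SETS}")
    need_face = feature_set != "voice_only"
    need_voice = feature_set != "face_only"
    ids = [r.subject_id for r in meta]
    if len(set(ids)) != len(ids):
        raise AssemblyError("duplicate subject ids in metadata")
    missing = []
    if need_voice:
        missing += [f"voice:{i}" for i in ids if voice is None or i not in voice]
    if need_face:
        missing += [f"face:{i}" for i in ids if face is None or i not in face]
    if missing:
        raise AssemblyError(f"subjects missing a modality: {missing}")

    rows = {}
    for rec in meta:
        row: dict = {}
        if need_face:
            row.update({k: _as_dict(face[rec.subject_id])[k] for k in pio.FACIAL_COLUMNS})
        if need_voice:
            vd = _as_dict(voice[rec.subject_id])
            row.update({k: vd[k] for k in pio.VOICE_COLUMNS})
            if "phonetic_score" in vd:
                row["phonetic_score"] = vd["phonetic_score"]
        if feature_set == "combined_plus_demographics":
            row["age"] = rec.age
            row["sex"] = 1 if rec.sex == "male" else 0
        row["label"] = 1 if rec.label == "PD" else 0
        rows[rec.subject_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    if "phonetic_score" in table.columns and table["phonetic_score"].isna().any():
        table = table.drop(columns="phonetic_score")
    order = [c for c in pio.ALL_COLUMNS if c in table.columns]
    return table[order]


def _split_xy(table: pd.DataFrame, drop_phonetic: bool = False):
    if "label" not in table.columns:
        raise InputError("table has no 'label' column")
    y = table["label"]
    if y.dtype == object:
        y = y.map({"PD": 1, "control": 0})
    y = y.to_numpy(dtype=int)
    cols = [c for c in table.columns if c != "label"]
    if drop_phonetic:
        cols = [c for c in cols if c != "phonetic_score"]
    return table[cols], y


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise InputError("table is single-class; need both PD and control subjects")


# ---------------------------------------------------------------- metrics


def _predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities; non-finite values (a model fitted on an
    all-constant feature carries no ranking information) become 0.5."""
    s = model.predict_proba(X)[:, 1]
    return np.where(np.isfinite(s), s, 0.5)


def _oof_scores(est, X: np.ndarray, y: np.ndarray, folds) -> np.ndarray:
    scores = np.empty(len(y))
    for tr, te in folds:
        model = clone(est)
        model.fit(X[tr], y[tr])
        scores[te] = _predict_scores(model, X[te])
    return scores


def _mean_fold_auroc(est, X: np.ndarray, y: np.ndarray, folds) -> float:
    aucs = []
    for tr, te in folds:
        model = clone(est)
        model.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _predict_scores(model, X[te])))
    return float(np.mean(aucs))


def _delong_ci(y: np.ndarray, scores: np.ndarray, alpha: float = 0.05):
    """DeLong 95% CI for the AUROC via placement values."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def _bootstrap_ci(
    y: np.ndarray, scores: np.ndarray, seed: int, n_boot: int = 2000, alpha: float = 0.05
):
    """Stratified bootstrap 95% CI for the AUROC of pooled scores."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        aucs[b] = roc_auc_score(y[idx], scores[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class Metrics:
    """Pooled-score performance summary for one classifier on one cohort."""

    auroc: float
    auroc_ci: tuple[float, float]
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_fpr: list = field(default_factory=list)
    roc_tpr: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_fpr": self.roc_fpr,
            "roc_tpr": self.roc_tpr,
        }


def _metrics_from_scores(
    y: np.ndarray, scores: np.ndarray, seed: int, ci_method: str, n_boot: int
) -> Metrics:
    auc = float(roc_auc_score(y, scores))
    if ci_method == "delong":
        ci = _delong_ci(y, scores)
    else:
        ci = _bootstrap_ci(y, scores, seed=seed, n_boot=n_boot)
    pred = (scores >= 0.5).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    return Metrics(
        auroc=auc,
        auroc_ci=ci,
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        roc_fpr=[float(v) for v in fpr],
        roc_tpr=[float(v) for v in tpr],
    )


def _folds(X, y, k_folds: int, seed: int):
    counts = np.bincount(y)
    if counts.min() < k_folds:
        raise InputError(
            f"smallest class has {counts.min()} members; cannot stratify into "
            f"{k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(X, y))


# ---------------------------------------------------------------- SFS


def sequential_forward_selection(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    k_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_features: int | None = None,
) -> list[str]:
    """Greedy forward selection maximising mean out-of-fold AUROC.

    Starts from the empty set (baseline AUROC 0.5), always admits the best
    single feature, then keeps adding the best candidate while it improves the
    criterion by more than ``tol``.  Ties go to the earlier table column.
    """
    Xdf, y = _split_xy(table)
    _check_two_classes(y)
    if Xdf.shape[1] < 2:
        raise InputError("feature selection needs at least 2 candidate features")
    folds = _folds(Xdf, y, k_folds, seed)
    est = make_classifier(spec)
    X = Xdf.to_numpy(dtype=float)
    names = list(Xdf.columns)
    selected: list[int] = []
    remaining = list(range(len(names)))
    best = 0.5  # chance-level baseline of the empty model
    while remaining and (max_features is None or len(selected) < max_features):
        cand_best, cand_score = None, -np.inf
        for j in remaining:
            score = _mean_fold_auroc(est, X[:, selected + [j]], y, folds)
            if score > cand_score + 1e-12:  # strict: earlier column wins ties
                cand_best, cand_score = j, score
        if selected and cand_score <= best + tol:
            break
        selected.append(cand_best)
        remaining.remove(cand_best)
        best = max(best, cand_score)
    return [names[j] for j in selected]


def selection_coverage(
    selections: Mapping[str, Sequence[str]], features: Sequence[str] | None = None
) -> list[dict]:
    """Percent of classifiers whose selection includes each feature, ranked
    descending (ties broken by the given feature order)."""
    if len(selections) == 0:
        raise InputError("need at least one classifier selection")
    if features is None:
        seen: dict[str, None] = {}
        for sel in selections.values():
            for f in sel:
                seen.setdefault(f, None)
        features = list(seen)
    n = len(selections)
    cov = [
        {
            "feature": f,
            "coverage_pct": 100.0 * sum(f in sel for sel in selections.values()) / n,
        }
        for f in features
    ]
    return sorted(cov, key=lambda d: -d["coverage_pct"])


# ---------------------------------------------------------------- evaluation


def cross_validated_evaluation(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    k_folds: int = 10,
    seed: int = 0,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
) -> Metrics:
    """Stratified k-fold CV; metrics from the pooled out-of-fold scores."""
    Xdf, y = _split_xy(table)
    _check_two_classes(y)
    folds = _folds(Xdf, y, k_folds, seed)
    scores = _oof_scores(make_classifier(spec), Xdf.to_numpy(dtype=float), y, folds)
    ci_seed = int(np.random.SeedSequence([seed, 0xB007]).generate_state(1)[0]) % (2**31)
    return _metrics_from_scores(y, scores, ci_seed, ci_method, n_boot)


@dataclass
class EvaluationReport:
    """Per-classifier selections and metrics, plus the coverage ranking."""

    entries: dict  # name -> {"selected_features", "train": Metrics, "validation": Metrics|None}
    coverage: list

    def to_dict(self) -> dict:
        out = {"classifiers": {}, "selection_coverage": self.coverage}
        for name, e in self.entries.items():
            out["classifiers"][name] = {
                "selected_features": e["selected_features"],
                "train": e["train"].to_dict(),
                "validation": e["validation"].to_dict() if e["validation"] else None,
            }
        return out

    def best(self, cohort: str = "train") -> tuple[str, Metrics]:
        """Classifier with the highest AUROC on the given cohort."""
        name = max(self.entries, key=lambda k: self.entries[k][cohort].auroc)
        return name, self.entries[name][cohort]


def run_experiment(
    train_table: pd.DataFrame,
    validation_table: pd.DataFrame | None,
    specs: Sequence[ClassifierSpec] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    select: bool = True,
    sfs_tol: float = 1e-4,
    max_features: int | None = None,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
) -> EvaluationReport:
    """SFS + CV per classifier on the training cohort, then refit on the full
    training table and score the held-out validation cohort.

    Mirrors a train-on-medicated ("on" phase) / validate-on-unmedicated
    ("off" phase) design: the cohorts must be subject-disjoint.
    """
    if validation_table is not None:
        overlap = train_table.index.intersection(validation_table.index)
        if len(overlap):
            raise LeakageError(f"train/validation cohorts share subjects: {list(overlap[:5])}")
        if list(validation_table.columns) != list(train_table.columns):
            raise InputError("train and validation tables must share the same columns")
    specs = list(specs) if specs is not None else default_specs(seed)
    feature_cols = [c for c in train_table.columns if c != "label"]
    entries: dict = {}
    for i, spec in enumerate(specs):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]) % (2**31)
        if select:
            sel = sequential_forward_selection(
                train_table, spec, k_folds=k_folds, seed=sub_seed,
                tol=sfs_tol, max_features=max_features,
            )
        else:
            sel = list(feature_cols)
        cols = sel + ["label"]
        train_metrics = cross_validated_evaluation(
            train_table[cols], spec, k_folds=k_folds, seed=sub_seed,
            ci_method=ci_method, n_boot=n_boot,
        )
        val_metrics = None
        if validation_table is not None:
            est = make_classifier(spec)
            Xtr, ytr = _split_xy(train_table[cols])
            est.fit(Xtr.to_numpy(dtype=float), ytr)
            Xva, yva = _split_xy(validation_table[cols])
            sc = _predict_scores(est, Xva.to_numpy(dtype=float))
            ci_seed = int(
                np.random.SeedSequence([sub_seed, 0x7A11]).generate_state(1)[0]
            ) % (2**31)
            val_metrics = _metrics_from_scores(yva, sc, ci_seed, ci_method, n_boot)
        entries[spec.name] = {
            "selected_features": sel,
            "train": train_metrics,
            "validation": val_metrics,
        }
    coverage = selection_coverage(
        {n: e["selected_features"] for n, e in entries.items()}, features=feature_cols
    )
    return EvaluationReport(entries=entries, coverage=coverage)
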