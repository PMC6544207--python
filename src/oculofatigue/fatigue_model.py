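"""Fatigue classification: dichotomization, person-wise CV, feature
selection and chance-level testing.

The evaluation unit is the *participant*: leave-one-person-out (LOPO)
folds train on all participants but one and test on the held-out
participant, so identity never leaks across the train/test split.
Imputation (per-feature training-fold median) is fitted inside each
fold.  The selection criterion is Youden's J (TPR + TNR - 1) computed
via LOPO; chance level is quantified by a label-permutation test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from oculofatigue.boosting import RobustBoostClassifier
from oculofatigue.errors import ValidationError
from oculofatigue.io_gaze import (
    LABEL_ALERT,
    LABEL_FATIGUED,
    LabeledDataset,
)
from oculofatigue.oculometrics import FEATURE_COLUMNS, SegmentFeatures

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = FEATURE_COLUMNS + ["age", "sex"]

#: The five features used by the deployed model.
SELECTED_FEATURES = ["BF", "PERCLOS", "SF", "SVA", "PDIR"]


# --------------------------------------------------------------------------
# confusion / criteria
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Confusion:
    """2x2 confusion counts; fatigued is the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def tpr(self) -> float:
        return self.tp / self.p if self.p else np.nan

    @property
    def tnr(self) -> float:
        return self.tn / self.n if self.n else np.nan

    @property
    def accuracy(self) -> float:
        total = self.p + self.n
        return (self.tp + self.tn) / total if total else np.nan

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(self.tp + other.tp, self.tn + other.tn,
                         self.fp + other.fp, self.fn + other.fn)


def dichotomize_kss(kss: int, threshold: int = 5) -> str:
    """Fatigued iff KSS >= threshold (default 5)."""
    if not 1 <= kss <= 10:
        raise ValidationError(f"KSS {kss} outside [1, 10]")
    return LABEL_FATIGUED if kss >= threshold else LABEL_ALERT


def youden_index(c: Confusion) -> float:
    """J = TPR + TNR - 1, in [-1, 1]."""
    if c.p == 0 or c.n == 0:
        raise ValidationError("Youden's J undefined when a class is absent")
    return c.tpr + c.tnr - 1.0


# --------------------------------------------------------------------------
# classifier specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """Pluggable classifier contract; ``dt_ensemble`` is the native kind."""

    kind: str = "dt_ensemble"
    hyperparameters: dict = field(default_factory=dict)

    KNOWN = ("dt_ensemble", "gentle_boost", "random_forest", "tree")

    def __post_init__(self) -> None:
        if self.kind not in self.KNOWN:
            raise ValidationError(
                f"unknown classifier kind {self.kind!r}; choose from {self.KNOWN}"
            )


def make_classifier(spec: ClassifierSpec, seed: int | None = None):
    hp = dict(spec.hyperparameters)
    if spec.kind == "dt_ensemble":
        hp.setdefault("n_learners", 50)
        hp.setdefault("max_splits", 5)
        hp.setdefault("error_goal", 0.25)
        hp.setdefault("max_margin", 1.0)
        return RobustBoostClassifier(random_state=seed, **hp)
    if spec.kind == "gentle_boost":
        n = hp.pop("n_learners", 50)
        splits = hp.pop("max_splits", 5)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_leaf_nodes=splits + 1),
            n_estimators=n, random_state=seed, **hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 51)
        hp.setdefault("max_leaf_nodes", 6)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.kind == "tree":
        hp.setdefault("max_leaf_nodes", 6)
        return DecisionTreeClassifier(random_state=seed, **hp)
    raise ValidationError(f"unknown classifier kind {spec.kind!r}")


# --------------------------------------------------------------------------
# trained model container
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted classifier with its feature schema and imputation constants."""

    classifier: object
    features: list[str]
    impute_medians: dict[str, float]
    kss_threshold: int = 5
    posterior_threshold: float = 0.5
    seed: int | None = None
    version: str = "1"

    def prepare(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValidationError(f"feature vector missing columns {missing}")
        X = X[self.features].copy()
        for col in self.features:
            X[col] = X[col].fillna(self.impute_medians.get(col, 0.0))
        return X.to_numpy(dtype=float)

    def posterior(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.classifier.predict_proba(self.prepare(X))
        classes = list(self.classifier.classes_)
        return proba[:, classes.index(LABEL_FATIGUED)]


def _fit_imputer(X: pd.DataFrame) -> dict[str, float]:
    med = X.median(numeric_only=True)
    # a feature missing everywhere in the training fold imputes to 0
    return {c: (float(med[c]) if c in med and np.isfinite(med[c]) else 0.0)
            for c in X.columns}


def train_ensemble(
    dataset: LabeledDataset,
    spec: ClassifierSpec = ClassifierSpec("dt_ensemble"),
    features: Sequence[str] | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Fit a classifier on the whole dataset (deployment-style training)."""
    features = list(features) if features is not None else list(DEFAULT_FEATURES)
    y = dataset.labels
    if np.unique(y).size < 2:
        raise ValidationError("training data must contain both classes")
    X = dataset.feature_matrix(features)
    medians = _fit_imputer(X)
    Xf = X.fillna(pd.Series(medians)).to_numpy(dtype=float)
    clf = make_classifier(spec, seed)
    clf.fit(Xf, y)
    return TrainedModel(classifier=clf, features=features,
                        impute_medians=medians,
                        kss_threshold=dataset.kss_threshold, seed=seed)


def predict_segment(
    model: TrainedModel, features: SegmentFeatures | pd.DataFrame
) -> tuple[str, float]:
    """Classify one segment; ties at the posterior threshold are fatigued."""
    if isinstance(features, SegmentFeatures):
        row = features.as_row()
        row["sex"] = 0.0 if row["sex"] == "F" else 1.0
        X = pd.DataFrame([row])
    else:
        X = features.copy()
        if "sex" in X.columns and X["sex"].dtype == object:
            X["sex"] = X["sex"].map({"F": 0.0, "M": 1.0})
    post = float(model.posterior(X)[0])
    label = LABEL_FATIGUED if post >= model.posterior_threshold else LABEL_ALERT
    return label, post


# --------------------------------------------------------------------------
# leave-one-person-out evaluation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold confusions and pooled metrics from a LOPO run."""

    fold_participants: list[str]
    fold_confusions: list[Confusion]
    posteriors: pd.DataFrame            # participant_id, label, posterior
    skipped_folds: list[str] = field(default_factory=list)

    @property
    def mean_tpr(self) -> float:
        return float(np.nanmean([c.tpr for c in self.fold_confusions]))

    @property
    def mean_tnr(self) -> float:
        return float(np.nanmean([c.tnr for c in self.fold_confusions]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean([c.accuracy for c in self.fold_confusions]))

    @property
    def pooled(self) -> Confusion:
        total = Confusion()
        for c in self.fold_confusions:
            total = total + c
        return total

    def roc_points(self, n_thresholds: int = 101) -> pd.DataFrame:
        """Mean TPR/FPR across participants for posterior thresholds in [0, 1].

        Endpoints are forced to (0,0) / (1,1) by including thresholds
        just outside the score range.
        """
        thresholds = np.linspace(0.0, 1.0, n_thresholds)
        rows = []
        groups = list(self.posteriors.groupby("participant_id"))
        for thr in thresholds:
            tprs, fprs = [], []
            for _, g in groups:
                yhat = g["posterior"].to_numpy() >= thr
                ytrue = g["label"].to_numpy() == LABEL_FATIGUED
                p, n = ytrue.sum(), (~ytrue).sum()
                if p:
                    tprs.append((yhat & ytrue).sum() / p)
                if n:
                    fprs.append((yhat & ~ytrue).sum() / n)
            rows.append((thr, float(np.mean(tprs)) if tprs else np.nan,
                         float(np.mean(fprs)) if fprs else np.nan))
        df = pd.DataFrame(rows, columns=["threshold", "tpr", "fpr"])
        head = pd.DataFrame([(-np.inf, 1.0, 1.0)], columns=df.columns)
        tail = pd.DataFrame([(np.inf, 0.0, 0.0)], columns=df.columns)
        return pd.concat([head, df, tail], ignore_index=True)


def lopo_evaluate(
    dataset: LabeledDataset,
    spec: ClassifierSpec = ClassifierSpec("dt_ensemble"),
    features: Sequence[str] | None = None,
    seed: int | None = None,
    posterior_threshold: float = 0.5,
    _labels_override: np.ndarray | None = None,
) -> CVResult:
    """One fold per participant; imputation fitted on the training fold only."""
    participants = dataset.participants
    if len(participants) < 2:
        raise ValidationError("LOPO needs at least 2 participants")
    features = list(features) if features is not None else list(DEFAULT_FEATURES)
    frame = dataset.frame
    y_all = (_labels_override if _labels_override is not None
             else frame["label"].to_numpy())
    X_all = dataset.feature_matrix(features)
    pid = frame["participant_id"].to_numpy()

    fold_parts, fold_confs, skipped = [], [], []
    post_rows = []
    for k, part in enumerate(participants):
        test = pid == part
        train = ~test
        y_train = y_all[train]
        if np.unique(y_train).size < 2:
            logger.warning("fold %s skipped: training fold has one class", part)
            skipped.append(part)
            continue
        X_train = X_all[train]
        medians = _fit_imputer(X_train)
        Xt = X_train.fillna(pd.Series(medians)).to_numpy(dtype=float)
        Xs = X_all[test].fillna(pd.Series(medians)).to_numpy(dtype=float)
        clf = make_classifier(spec, None if seed is None else seed + k)
        clf.fit(Xt, y_train)
        proba = clf.predict_proba(Xs)
        classes = list(clf.classes_)
        post = proba[:, classes.index(LABEL_FATIGUED)]
        yhat = np.where(post >= posterior_threshold, LABEL_FATIGUED, LABEL_ALERT)
        ytrue = y_all[test]
        fold_parts.append(part)
        fold_confs.append(Confusion(
            tp=int(np.sum((yhat == LABEL_FATIGUED) & (ytrue == LABEL_FATIGUED))),
            tn=int(np.sum((yhat == LABEL_ALERT) & (ytrue == LABEL_ALERT))),
            fp=int(np.sum((yhat == LABEL_FATIGUED) & (ytrue == LABEL_ALERT))),
            fn=int(np.sum((yhat == LABEL_ALERT) & (ytrue == LABEL_FATIGUED))),
        ))
        for lbl, ps in zip(ytrue, post):
            post_rows.append((part, lbl, float(ps)))
    if not fold_confs:
        raise ValidationError("every LOPO fold was skipped (single-class folds)")
    return CVResult(
        fold_participants=fold_parts,
        fold_confusions=fold_confs,
        posteriors=pd.DataFrame(post_rows,
                                columns=["participant_id", "label", "posterior"]),
        skipped_folds=skipped,
    )


# --------------------------------------------------------------------------
# SFFS feature selection
# --------------------------------------------------------------------------

def _default_criterion(spec: ClassifierSpec, seed: int | None):
    def criterion(dataset: LabeledDataset, subset: list[str]) -> float:
        result = lopo_evaluate(dataset, spec, features=subset, seed=seed)
        return youden_index(result.pooled)
    return criterion


def sffs_select(
    dataset: LabeledDataset,
    base_learner: ClassifierSpec = ClassifierSpec("random_forest"),
    criterion: Callable[[LabeledDataset, list[str]], float] | None = None,
    candidates: Sequence[str] | None = None,
    max_size: int = 5,
    seed: int | None = None,
) -> tuple[list[str], list[tuple[list[str], float]]]:
    """Sequential floating forward selection under a LOPO-Youden criterion.

    Returns the best subset found (by criterion, smallest size on ties)
    and the trace of (subset, criterion) evaluations at each accepted
    step.
    """
    candidates = list(candidates) if candidates is not None else list(DEFAULT_FEATURES)
    if len(candidates) < 2:
        raise ValidationError("SFFS needs at least 2 candidate features")
    crit = criterion if criterion is not None else _default_criterion(base_learner, seed)

    best_by_size: dict[int, tuple[list[str], float]] = {}
    trace: list[tuple[list[str], float]] = []
    current: list[str] = []
    current_score = -np.inf

    def evaluate(subset: list[str]) -> float:
        return float(crit(dataset, subset))

    while len(current) < max_size:
        # forward: best single inclusion
        best_feat, best_score = None, -np.inf
        for f in candidates:
            if f in current:
                continue
            score = evaluate(current + [f])
            if score > best_score:
                best_feat, best_score = f, score
        if best_feat is None or not np.isfinite(best_score):
            if not current:
                warnings.warn(
                    "no improving first inclusion; returning best single feature"
                )
                scores = {f: evaluate([f]) for f in candidates}
                best = max(scores, key=scores.get)
                return [best], [([best], scores[best])]
            break
        current = current + [best_feat]
        current_score = best_score
        trace.append((list(current), current_score))
        if (len(current) not in best_by_size
                or current_score > best_by_size[len(current)][1]):
            best_by_size[len(current)] = (list(current), current_score)

        # floating backward: drop while dropping improves on the best
        # subset previously seen at the smaller size
        while len(current) > 2:
            drop_feat, drop_score = None, -np.inf
            for f in current:
                subset = [g for g in current if g != f]
                score = evaluate(subset)
                if score > drop_score:
                    drop_feat, drop_score = f, score
            smaller = len(current) - 1
            prev_best = best_by_size.get(smaller, (None, -np.inf))[1]
            if drop_score > prev_best and drop_score > current_score:
                current = [g for g in current if g != drop_feat]
                current_score = drop_score
                best_by_size[smaller] = (list(current), current_score)
                trace.append((list(current), current_score))
            else:
                break

    if not best_by_size:
        # max_size 1 or nothing accepted: exhaustive best single feature
        scores = {f: evaluate([f]) for f in candidates}
        best = max(scores, key=scores.get)
        return [best], [([best], scores[best])]
    best_subset, _ = max(
        best_by_size.values(), key=lambda kv: (kv[1], -len(kv[0]))
    )
    return best_subset, trace


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------

def permutation_test(
    dataset: LabeledDataset,
    spec: ClassifierSpec = ClassifierSpec("dt_ensemble"),
    features: Sequence[str] | None = None,
    n_permutations: int = 100,
    seed: int | None = None,
    within_participant: bool = False,
) -> tuple[float, np.ndarray, float]:
    """Chance-level test: LOPO accuracy vs. label-permuted replicates.

    Returns (observed mean ACC, null distribution, p-value) with
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = lopo_evaluate(dataset, spec, features=features, seed=seed).mean_accuracy
    labels = dataset.labels.copy()
    pid = dataset.frame["participant_id"].to_numpy()
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        if within_participant:
            perm = labels.copy()
            for part in dataset.participants:
                m = pid == part
                perm[m] = rng.permutation(perm[m])
        else:
            perm = rng.permutation(labels)
        try:
            null[i] = lopo_evaluate(
                dataset, spec, features=features, seed=seed,
                _labels_override=perm,
            ).mean_accuracy
        except ValidationError:
            null[i] = np.nan
    finite = null[np.isfinite(null)]
    p = (1.0 + float(np.sum(finite >= observed))) / (1.0 + finite.size)
    return observed, null, p
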