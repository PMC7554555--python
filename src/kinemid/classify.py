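"""Multiclass movement-pattern classification with a linear-kernel SVM.

Four task designs on the per-kick feature vectors:

* participant — who kicked (16 classes with the full protocol), at K-80 or
  K-100 intensity, one leg at a time;
* block — which of the n_sets*blocks_per_set chronological blocks a kick
  belongs to (27 classes), within one subject;
* set — which set (9 classes), within one subject;
* block_within_set — which within-set block index (3 classes), within one
  subject.

Cross-validation is coverage-complete: the test folds partition the task
matrix, so every kick appears in the test set exactly once, and each fold's
test rows are evenly distributed across classes.  Participant tasks and the
block-within-set task leave one set (or K-100 time point) out per fold; the
block and set tasks hold out the f-th kick of every block in fold f.

Each fold z-normalizes and (-1, 1)-scales features on its training rows,
selects the SVM cost C by grid search over C = 2^-5, 2^-4.75, ..., 2^15
(81 candidates, inner stratified CV, ties -> smallest C), fits a
one-vs-rest linear SVM, and predicts the held-out rows.  Results aggregate
to fold-wise mean +- SD of accuracy and macro F1/precision/recall, a
row-normalized confusion matrix over the pooled predictions and, for
chronologically ordered tasks, a distance-to-true-class profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .errors import ParameterError, SplitError, TaskError
from .preprocess import FeatureMatrix, fit_normalizer, apply_normalizer

logger = logging.getLogger("kinemid.classify")

TASK_KINDS = ("participant", "block", "set", "block_within_set")
ORDERED_KINDS = ("block", "set", "block_within_set")


# ---------------------------------------------------------------------------
# Tasks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationTask:
    """One classification design applied to one (intensity, leg) slice.

    Intra-individual kinds (block, set, block_within_set) additionally
    require ``subject``.  Block classes are ordered chronologically,
    set-major: class = blocks_per_set*(set-1) + (block-1).
    """

    kind: str
    intensity: str = "K80"
    leg: str = "left"
    subject: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ParameterError(f"unknown task kind {self.kind!r}; expected one of {TASK_KINDS}")
        if self.kind != "participant" and self.subject is None:
            raise ParameterError(f"intra-individual task {self.kind!r} requires a subject")
        if self.kind != "participant" and self.intensity != "K80":
            raise ParameterError("intra-individual tasks are defined on K-80 kicks")

    @property
    def ordered(self) -> bool:
        return self.kind in ORDERED_KINDS

    def describe(self) -> str:
        who = "" if self.subject is None else f" subject={self.subject}"
        return f"{self.kind} {self.intensity} {self.leg}{who}"


def class_labels(task: ClassificationTask, labels: pd.DataFrame, blocks_per_set: int) -> np.ndarray:
    """Integer class per row of the (already filtered) task labels."""
    if task.kind == "participant":
        codes, _ = pd.factorize(labels["subject"], sort=True)
        return codes.astype(int)
    if task.kind == "block":
        return (blocks_per_set * (labels["set"].to_numpy() - 1) + labels["block"].to_numpy() - 1).astype(int)
    if task.kind == "set":
        return (labels["set"].to_numpy() - 1).astype(int)
    return (labels["block"].to_numpy() - 1).astype(int)  # block_within_set


def build_task_matrix(
    features: FeatureMatrix, task: ClassificationTask, blocks_per_set: int = 3
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray]:
    """Filter the feature matrix to the task's rows.

    Returns (X, y, labels, row_ids) where row_ids index the original
    feature matrix.
    """
    lab = features.labels
    mask = (lab["intensity"] == task.intensity) & (lab["leg"] == task.leg)
    if task.subject is not None:
        mask &= lab["subject"] == task.subject
    row_ids = np.nonzero(mask.to_numpy())[0]
    if len(row_ids) == 0:
        raise TaskError(
            f"no rows match task filter (intensity={task.intensity}, leg={task.leg}, "
            f"subject={task.subject})"
        )
    sub = lab.iloc[row_ids].reset_index(drop=True)
    y = class_labels(task, sub, blocks_per_set)
    logger.info("task [%s]: %d rows x %d features, %d classes",
                task.describe(), len(row_ids), features.n_features, len(np.unique(y)))
    return features.values[row_ids], y, sub, row_ids


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Coverage-complete fold assignment: test sets partition all rows."""

    task: ClassificationTask
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train_idx, test_idx) pairs
    strata: str

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def validate(self, n_rows: int) -> None:
        all_test = np.concatenate([t for _, t in self.folds])
        if len(all_test) != n_rows or len(np.unique(all_test)) != n_rows:
            raise SplitError("test folds must partition the rows (each kick tested exactly once)")
        for train, test in self.folds:
            if np.intersect1d(train, test).size:
                raise SplitError("train and test overlap within a fold")
            if len(np.union1d(train, test)) != n_rows:
                raise SplitError("each fold must use every row exactly once")


def make_split_plan(task: ClassificationTask, labels: pd.DataFrame) -> SplitPlan:
    """Build the task's fold structure from the protocol labels.

    participant (K-80) and block_within_set: leave one set out per fold;
    participant (K-100): leave one time point out; block and set: fold f
    tests the f-th kick of every block (kicks_per_block folds).
    """
    n = len(labels)
    idx = np.arange(n)
    if task.kind == "participant" or task.kind == "block_within_set":
        groups = labels["set"].to_numpy()
        levels = np.unique(groups)
        if len(levels) < 2:
            raise SplitError(
                f"leave-one-{'set' if task.intensity == 'K80' else 'timepoint'}-out "
                f"needs >= 2 groups, found {len(levels)}"
            )
        folds = tuple(
            (idx[groups != g], idx[groups == g]) for g in levels
        )
        strata = "set" if task.intensity == "K80" else "timepoint"
    else:  # block, set: f-th kick of every block
        kicks = labels["kick"].to_numpy()
        levels = np.unique(kicks)
        if len(levels) < 2:
            raise SplitError(f"kick-wise folding needs >= 2 kicks per block, found {len(levels)}")
        folds = tuple(
            (idx[kicks != f], idx[kicks == f]) for f in levels
        )
        strata = "kick-within-block"
    plan = SplitPlan(task=task, folds=folds, strata=strata)
    plan.validate(n)
    return plan


# ---------------------------------------------------------------------------
# Cost grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSearchSpec:
    """Log2-spaced SVM cost grid with inner stratified-CV selection.

    The default grid is C = 2^-5 .. 2^15 in steps of 0.25 (81 candidates);
    selection maximizes inner-CV accuracy, ties break to the smallest cost.
    """

    exponent_range: tuple[float, float] = (-5.0, 15.0)
    exponent_step: float = 0.25
    base: float = 2.0
    inner_folds: int = 3
    max_iter: int = 20000
    tol: float = 1e-4

    def __post_init__(self) -> None:
        lo, hi = self.exponent_range
        if hi < lo or self.exponent_step <= 0:
            raise ParameterError("invalid grid: need exponent_range[0] <= [1] and step > 0")

    def costs(self) -> np.ndarray:
        lo, hi = self.exponent_range
        exps = np.arange(lo, hi + self.exponent_step / 2, self.exponent_step)
        return self.base ** exps


def _make_svm(cost: float, spec: GridSearchSpec, seed: int) -> LinearSVC:
    # one-vs-rest linear SVM; liblinear is deterministic given data order
    return LinearSVC(C=cost, max_iter=spec.max_iter, tol=spec.tol, random_state=seed)


def grid_search_cost(
    X: np.ndarray, y: np.ndarray, spec: GridSearchSpec = GridSearchSpec(), seed: int = 0
) -> float:
    """Select the cost C maximizing inner stratified-CV accuracy on (X, y)."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TaskError("grid search needs >= 2 classes in the training rows")
    n_splits = int(min(spec.inner_folds, counts.min()))
    if n_splits < 2:
        raise TaskError("grid search needs >= 2 samples of every class for inner CV")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    costs = spec.costs()
    scores = np.empty(len(costs))
    for i, c in enumerate(costs):
        correct = 0
        for tr, te in splits:
            clf = _make_svm(c, spec, seed)
            clf.fit(X[tr], y[tr])
            correct += int((clf.predict(X[te]) == y[te]).sum())
        scores[i] = correct / len(y)
    best = int(np.argmax(scores))  # first max -> smallest cost on ties
    return float(costs[best])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def chance_accuracy(n_classes: int) -> float:
    """Random-baseline accuracy of a balanced n-class task, in percent."""
    if n_classes < 1:
        raise ParameterError("n_classes must be >= 1")
    return 100.0 / n_classes


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> dict[str, float]:
    """Accuracy and macro-averaged F1/precision/recall, in percent.

    Classes absent from ``y_true`` are excluded from the macro average (and
    the event logged): with coverage-complete folds this only happens on
    degenerate inputs.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise TaskError("cannot compute metrics on empty predictions")
    present = np.unique(y_true)
    if len(present) < n_classes:
        logger.warning("%d of %d classes absent from the test labels; excluded from macro averages",
                       n_classes - len(present), n_classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    acc = float(np.mean(y_true == y_pred))
    return {
        "accuracy": 100.0 * acc,
        "f1": 100.0 * float(f1),
        "precision": 100.0 * float(prec),
        "recall": 100.0 * float(rec),
    }


def normalized_confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """Row-normalized confusion matrix (rows = true classes, sum to 1)."""
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes)).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, row_sums, out=np.zeros_like(cm), where=row_sums > 0)


# ---------------------------------------------------------------------------
# Distance-to-true-class profiles
# ---------------------------------------------------------------------------

def distance_availability(n_classes: int) -> np.ndarray:
    """avail[c, d] = number of classes at ordinal distance d from class c."""
    avail = np.zeros((n_classes, n_classes), dtype=int)
    for c in range(n_classes):
        for p in range(n_classes):
            avail[c, abs(p - c)] += 1
    return avail


def distance_profile(y_true: np.ndarray, y_pred: np.ndarray, task: ClassificationTask,
                     n_classes: int) -> pd.DataFrame:
    """Prediction proportion as a function of |predicted - true| class distance.

    For each distance d, the per-true-class proportion of predictions landing
    at distance d is averaged over the classes for which d exists ("raw"),
    alongside an availability-corrected variant that divides each class's
    proportion by the number of classes at that distance (so a uniform random
    classifier is flat).  d = 0 equals per-class accuracy.
    """
    if not task.ordered:
        raise TaskError(f"distance profile requires a chronologically ordered task, not {task.kind!r}")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    avail = distance_availability(n_classes)
    # per-class proportion mass at each distance
    prop = np.full((n_classes, n_classes), np.nan)
    for c in np.unique(y_true):
        mask = y_true == c
        d = np.abs(y_pred[mask] - c)
        prop[c] = np.bincount(d, minlength=n_classes) / mask.sum()
    rows = []
    for d in range(n_classes):
        eligible = (avail[:, d] > 0) & ~np.isnan(prop[:, 0])
        if not eligible.any():
            continue
        raw = prop[eligible, d]
        corrected = prop[eligible, d] / avail[eligible, d]
        rows.append({
            "distance": d,
            "mean": raw.mean(),
            "sd": raw.std(ddof=1) if len(raw) > 1 else 0.0,
            "mean_corrected": corrected.mean(),
            "sd_corrected": corrected.std(ddof=1) if len(corrected) > 1 else 0.0,
            "n_classes_available": int(eligible.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Task runner
# ---------------------------------------------------------------------------

@dataclass
class TaskResult:
    """Per-fold predictions and aggregated metrics for one task run."""

    task: ClassificationTask
    n_classes: int
    fold_costs: list[float]
    fold_metrics: pd.DataFrame            # one row per fold: the four metrics in %
    metrics_summary: pd.DataFrame         # mean/sd rows x metric columns
    y_true: np.ndarray                    # pooled over folds, original row order
    y_pred: np.ndarray
    fold_of_row: np.ndarray
    confusion: np.ndarray                 # row-normalized, pooled
    classes: np.ndarray
    profile: pd.DataFrame | None = None
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(self.metrics_summary.loc["mean", "accuracy"])

    @property
    def chance(self) -> float:
        return chance_accuracy(self.n_classes)


def run_task(
    features: FeatureMatrix,
    task: ClassificationTask,
    plan: SplitPlan | None = None,
    grid: GridSearchSpec = GridSearchSpec(),
    normalize_scope: str = "fold",
    blocks_per_set: int = 3,
    seed: int = 0,
) -> TaskResult:
    """Run one classification task end to end.

    ``normalize_scope='fold'`` fits the z + (-1, 1) normalizer on each
    fold's training rows only (leakage-safe); ``'global'`` fits it once on
    the whole task matrix before splitting.
    """
    if features.state != "raw":
        raise TaskError("run_task expects a raw FeatureMatrix; it normalizes per fold")
    X, y, labels, _ = build_task_matrix(features, task, blocks_per_set)
    if not np.all(np.isfinite(X)):
        raise TaskError("non-finite feature values")
    if plan is None:
        plan = make_split_plan(task, labels)
    plan.validate(len(y))
    n_classes = int(y.max()) + 1

    global_stats = fit_normalizer(X) if normalize_scope == "global" else None
    y_pred = np.full(len(y), -1, dtype=int)
    fold_of_row = np.full(len(y), -1, dtype=int)
    fold_costs: list[float] = []
    fold_rows = []
    for f, (train, test) in enumerate(plan.folds):
        if normalize_scope == "fold":
            stats = fit_normalizer(X[train])
        elif normalize_scope == "global":
            stats = global_stats
        else:
            raise ParameterError(f"normalize_scope must be 'fold' or 'global', got {normalize_scope!r}")
        Xtr = apply_normalizer(X[train], stats)
        Xte = apply_normalizer(X[test], stats)
        cost = grid_search_cost(Xtr, y[train], grid, seed=seed + f)
        clf = _make_svm(cost, grid, seed)
        clf.fit(Xtr, y[train])
        pred = clf.predict(Xte)
        y_pred[test] = pred
        fold_of_row[test] = f
        fold_costs.append(cost)
        fold_rows.append(compute_metrics(y[test], pred, n_classes))
        logger.info("task [%s] fold %d/%d: C=%g, accuracy %.1f%% (train %d / test %d)",
                    task.describe(), f + 1, plan.n_folds, cost,
                    fold_rows[-1]["accuracy"], len(train), len(test))
    fold_metrics = pd.DataFrame(fold_rows)
    summary = pd.DataFrame(
        {m: [fold_metrics[m].mean(), fold_metrics[m].std(ddof=1)] for m in fold_metrics.columns},
        index=["mean", "sd"],
    )
    confusion = normalized_confusion(y, y_pred, n_classes)
    profile = distance_profile(y, y_pred, task, n_classes) if task.ordered else None
    return TaskResult(
        task=task, n_classes=n_classes, fold_costs=fold_costs,
        fold_metrics=fold_metrics, metrics_summary=summary,
        y_true=y, y_pred=y_pred, fold_of_row=fold_of_row,
        confusion=confusion, classes=np.arange(n_classes), profile=profile, seed=seed,
    )
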