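"""Evaluation measures and the repeated cross-validation harness.

Implements the five measures used to compare discretization methods —
accuracy, (multi-class) AUC, robustness, selected-variable stability and
interval-count statistics — together with stratified R x F cross-validation
and the paired Wilcoxon signed-rank comparison.

Discretization doubles as variable selection: a variable discretized to a
single interval is "trivial" and effectively dropped, so the set of
non-trivially discretized variables per training fold is the selected set
whose consistency across folds the stability index measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .core import DiscretizationModel, EBDParams, SortedSample, ebd_discretize
from .fi import fi_discretize
from .io import RawDataset, transform
from .nb import NaiveBayesClassifier

__all__ = [
    "SelectedVariableSet",
    "FoldPlan",
    "EvaluationReport",
    "accuracy",
    "predict_labels",
    "binary_auc",
    "hand_till_auc",
    "robustness",
    "set_similarity",
    "pairwise_similarities",
    "stability",
    "interval_stats",
    "wilcoxon_signed_rank",
    "make_fold_plans",
    "fit_discretizers",
    "run_cv",
    "compare_reports",
]


@dataclass(frozen=True)
class SelectedVariableSet:
    """Variables with a non-trivial discretization in one training fold."""

    variables: frozenset
    n_vars: int

    def __post_init__(self) -> None:
        if len(self.variables) > self.n_vars:
            raise ValueError("selected set larger than the variable pool")

    @property
    def k(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class FoldPlan:
    """One train/test split of a stratified repeated cross-validation."""

    replicate: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def predict_labels(proba: np.ndarray) -> np.ndarray:
    """Maximum-posterior labels; ties go to the lowest class index."""
    return np.argmax(np.atleast_2d(proba), axis=1)


def accuracy(predicted: Sequence[int], true: Sequence[int]) -> float:
    """Proportion of correct predictions."""
    p = np.asarray(predicted)
    t = np.asarray(true)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted and true labels must be equal-length, non-empty")
    return float(np.mean(p == t))


def binary_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score of a random positive > random negative).

    ``labels`` are 0/1 with 1 the positive class; tied scores count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    z = np.asarray(labels)
    if s.shape != z.shape:
        raise ValueError("scores and labels must be equal length")
    pos = z == 1
    n_pos = int(pos.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def hand_till_auc(proba: np.ndarray, labels: Sequence[int]) -> float:
    """Multi-class AUC as the average of all pairwise class comparisons.

    For each unordered class pair (i, j), A(i|j) is the binary AUC of the
    class-i probability column restricted to instances of classes i and j;
    the pair contributes (A(i|j) + A(j|i)) / 2, and the overall value is the
    mean over the J(J-1)/2 pairs.  Reduces exactly to :func:`binary_auc`
    when J = 2.
    """
    p = np.atleast_2d(np.asarray(proba, dtype=float))
    z = np.asarray(labels)
    j = p.shape[1]
    if j < 2:
        raise ValueError("need at least two classes")
    present = np.unique(z)
    if not np.array_equal(present, np.arange(j)):
        missing = sorted(set(range(j)) - set(present.tolist()))
        raise ValueError(f"classes absent from labels: {missing}")
    total = 0.0
    n_pairs = 0
    for a in range(j):
        for b in range(a + 1, j):
            mask = (z == a) | (z == b)
            a_given_b = binary_auc(p[mask, a], (z[mask] == a).astype(int))
            b_given_a = binary_auc(p[mask, b], (z[mask] == b).astype(int))
            total += (a_given_b + b_given_a) / 2
            n_pairs += 1
    return total / n_pairs


def robustness(test_accuracy: float, train_accuracy: float) -> float:
    """Test accuracy as a percentage of training accuracy (may exceed 100)."""
    if train_accuracy <= 0:
        raise ValueError("robustness undefined for zero training accuracy")
    return 100.0 * test_accuracy / train_accuracy


def set_similarity(v_i: SelectedVariableSet, v_j: SelectedVariableSet) -> float:
    """Chance-corrected overlap of two selected-variable sets, in [-1, 1].

    With k_i, k_j the set sizes, n the variable pool size and r the overlap,

        Sim = (r - k_i * k_j / n) / (min(k_i, k_j) - max(0, k_i + k_j - n))

    i.e. the overlap minus its hypergeometric expectation, scaled by the
    distance between the largest and smallest overlap the set sizes permit.
    0 means the overlap is what random selection would give.  Degenerate
    cases where the index is undefined (an empty set, or set sizes that
    force the overlap) return 0 by convention.
    """
    if v_i.n_vars != v_j.n_vars:
        raise ValueError("selected sets must come from the same variable pool")
    n = v_i.n_vars
    k_i, k_j = v_i.k, v_j.k
    if k_i == 0 or k_j == 0:
        return 0.0
    denom = min(k_i, k_j) - max(0, k_i + k_j - n)
    if denom == 0:  # includes both sets covering every variable
        return 0.0
    r = len(v_i.variables & v_j.variables)
    return (r - k_i * k_j / n) / denom


def pairwise_similarities(fold_sets: Sequence[SelectedVariableSet]) -> list[float]:
    """Similarities of all F(F-1)/2 fold pairs of one replicate."""
    if len(fold_sets) < 2:
        raise ValueError("need at least two folds")
    sims = []
    for a in range(len(fold_sets)):
        for b in range(a + 1, len(fold_sets)):
            sims.append(set_similarity(fold_sets[a], fold_sets[b]))
    return sims


def stability(
    fold_sets: Sequence[SelectedVariableSet] | Sequence[Sequence[SelectedVariableSet]],
) -> float:
    """Mean pairwise similarity of selected sets across folds.

    Accepts either one replicate (a flat list of per-fold sets, averaged
    over all fold pairs — 45 pairs for 10 folds) or several replicates (a
    list of such lists, whose per-replicate stabilities are then averaged).
    """
    if len(fold_sets) == 0:
        raise ValueError("empty input")
    if isinstance(fold_sets[0], SelectedVariableSet):
        return float(np.mean(pairwise_similarities(fold_sets)))
    return float(np.mean([np.mean(pairwise_similarities(rep)) for rep in fold_sets]))


def interval_stats(
    models: Iterable[DiscretizationModel | int],
) -> tuple[float, float, float]:
    """(fraction of variables with 1 interval, mean W among W>1, mean W).

    The middle statistic is NaN when every variable is trivial.
    """
    ws = np.array(
        [m.W if isinstance(m, DiscretizationModel) else int(m) for m in models]
    )
    if ws.size == 0:
        raise ValueError("empty input")
    nontrivial = ws[ws > 1]
    mean_nontrivial = float(nontrivial.mean()) if nontrivial.size else math.nan
    return float(np.mean(ws == 1)), mean_nontrivial, float(ws.mean())


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are discarded, absolute differences receive mid-ranks,
    and the Z statistic uses the tie-corrected variance; returns (Z,
    two-sided p).  Positive Z means the first member of each pair tends to
    be larger.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) values")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero")
    if m < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = m * (m + 1) / 4
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24 - np.sum(tie_counts**3 - tie_counts) / 48
    z = (w_plus - mu) / math.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)


def make_fold_plans(
    y: Sequence[int], n_folds: int = 10, n_repeats: int = 10, seed: int = 0
) -> list[FoldPlan]:
    """Seeded stratified fold plans for R repeats of F-fold cross-validation.

    Replicate r shuffles with seed ``seed + r``; within a replicate the test
    folds partition all instances.
    """
    y = np.asarray(y, dtype=np.int64)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        small = int(np.argmin(counts))
        raise ValueError(
            f"class {small} has only {counts[small]} instances; "
            f"use --folds <= {counts.min()}"
        )
    plans: list[FoldPlan] = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
            plans.append(
                FoldPlan(
                    replicate=r + 1,
                    fold=f + 1,
                    train_idx=tr,
                    test_idx=te,
                    seed=seed + r,
                )
            )
    return plans


def fit_discretizers(
    X: pd.DataFrame,
    y: Sequence[int],
    method: str = "ebd",
    params: EBDParams | None = None,
    n_classes: int | None = None,
) -> dict[str, DiscretizationModel]:
    """Learn one discretization model per column from training data only."""
    if method not in ("ebd", "fi"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=np.int64)
    models: dict[str, DiscretizationModel] = {}
    for col in X.columns:
        sample = SortedSample.from_arrays(X[col].to_numpy(), y, n_classes=n_classes)
        if method == "ebd":
            models[col] = ebd_discretize(sample, params)
        else:
            models[col] = fi_discretize(sample)
    return models


@dataclass
class EvaluationReport:
    """Per-fold measures plus replicate-level stability for one method."""

    method: str
    folds: pd.DataFrame
    selected: list[tuple[int, int, SelectedVariableSet]]
    stability_per_replicate: np.ndarray
    n_vars: int

    def summary(self) -> dict[str, float]:
        """Aggregate means over all train/test pairs (and replicates)."""
        f = self.folds
        return {
            "train_accuracy": float(f["train_accuracy"].mean()),
            "test_accuracy": float(f["test_accuracy"].mean()),
            "train_auc": float(f["train_auc"].mean()),
            "test_auc": float(f["test_auc"].mean()),
            "robustness": float(f["robustness"].mean()),
            "stability": float(self.stability_per_replicate.mean()),
            "frac_trivial": float(f["frac_trivial"].mean()),
            "mean_intervals_nontrivial": float(f["mean_intervals_nontrivial"].mean()),
            "mean_intervals": float(f["mean_intervals"].mean()),
        }


def run_cv(
    dataset: RawDataset | tuple[pd.DataFrame, Sequence[int]],
    method: str = "ebd",
    params: EBDParams | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    classifier=None,
) -> EvaluationReport:
    """Repeated stratified cross-validation of one discretization method.

    For every train/test pair: discretize each variable on the training fold
    only, record the selected (non-trivially discretized) variable set,
    train the plugged classifier on the coded training fold, and measure
    accuracy and AUC on both folds; robustness is the per-pair test/train
    accuracy ratio.  Defaults give 10 x 10 = 100 train/test pairs.  The same
    seed always yields an identical report.
    """
    if isinstance(dataset, RawDataset):
        X, y = dataset.X, dataset.y
        j = dataset.n_classes
    else:
        X, y = dataset
        y = np.asarray(y, dtype=np.int64)
        j = int(y.max()) + 1
    classifier = classifier or NaiveBayesClassifier()
    plans = make_fold_plans(y, n_folds=n_folds, n_repeats=n_repeats, seed=seed)

    rows = []
    selected: list[tuple[int, int, SelectedVariableSet]] = []
    for plan in plans:
        X_tr, y_tr = X.iloc[plan.train_idx], y[plan.train_idx]
        X_te, y_te = X.iloc[plan.test_idx], y[plan.test_idx]
        models = fit_discretizers(X_tr, y_tr, method=method, params=params, n_classes=j)
        sel = SelectedVariableSet(
            frozenset(v for v, m in models.items() if m.W > 1), len(X.columns)
        )
        selected.append((plan.replicate, plan.fold, sel))

        table_tr = transform(X_tr, models, y=y_tr, n_classes=j)
        table_te = transform(X_te, models, y=y_te, n_classes=j)
        clf = classifier.train(table_tr)
        proba_tr = np.atleast_2d(classifier.predict_proba(clf, table_tr.codes))
        proba_te = np.atleast_2d(classifier.predict_proba(clf, table_te.codes))
        acc_tr = accuracy(predict_labels(proba_tr), y_tr)
        acc_te = accuracy(predict_labels(proba_te), y_te)
        frac_trivial, mean_nontrivial, mean_w = interval_stats(models.values())
        rows.append(
            {
                "replicate": plan.replicate,
                "fold": plan.fold,
                "train_accuracy": acc_tr,
                "test_accuracy": acc_te,
                "train_auc": hand_till_auc(proba_tr, y_tr),
                "test_auc": hand_till_auc(proba_te, y_te),
                "robustness": robustness(acc_te, acc_tr),
                "n_selected": sel.k,
                "frac_trivial": frac_trivial,
                "mean_intervals_nontrivial": mean_nontrivial,
                "mean_intervals": mean_w,
            }
        )

    folds = pd.DataFrame(rows)
    per_rep = []
    for r in sorted({rep for rep, _, _ in selected}):
        sets = [s for rep, _, s in selected if rep == r]
        per_rep.append(float(np.mean(pairwise_similarities(sets))))
    return EvaluationReport(
        method=method,
        folds=folds,
        selected=selected,
        stability_per_replicate=np.asarray(per_rep),
        n_vars=len(X.columns),
    )


def compare_reports(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    measure: str = "test_accuracy",
) -> tuple[float, float]:
    """Paired Wilcoxon comparison of two reports on a per-fold measure.

    Both reports must come from the same fold plans (same data, folds,
    repeats and seed) so the per-fold values pair up.
    """
    a = report_a.folds[measure].to_numpy()
    b = report_b.folds[measure].to_numpy()
    if a.size != b.size:
        raise ValueError("reports have different numbers of folds")
    return wilcoxon_signed_rank(list(zip(a, b)))
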