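"""Discrete-input naive Bayes with add-one smoothing.

The classifier used to score discretizations end to end: predictors are
interval codes, assumed conditionally independent given the class.
Variables discretized to a single interval carry no information and are
dropped at training time, which is how discretization doubles as variable
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DiscretizedTable

__all__ = ["NBModel", "nb_train", "nb_predict_proba", "NaiveBayesClassifier"]


@dataclass
class NBModel:
    class_counts: np.ndarray
    cond_counts: list[np.ndarray]  # per retained variable: (W, J)
    var_indices: list[int]  # columns of the table that were retained
    variables: list[str]
    smoothing: float = 1.0

    @property
    def n_classes(self) -> int:
        return int(self.class_counts.size)


def nb_train(table: DiscretizedTable, smoothing: float = 1.0) -> NBModel:
    """Tally class priors and per-variable conditional count tables.

    Variables with a single interval (W = 1) are filtered out; a model with
    no retained variables predicts the (smoothed) class prior.
    """
    if table.y is None:
        raise ValueError("training table must carry target labels")
    if table.n == 0:
        raise ValueError("cannot train on an empty table")
    y = np.asarray(table.y, dtype=np.int64)
    j = table.n_classes or int(y.max()) + 1
    class_counts = np.bincount(y, minlength=j)
    retained = [i for i, w in enumerate(table.widths) if w > 1]
    cond: list[np.ndarray] = []
    for i in retained:
        w = table.widths[i]
        tab = np.zeros((w, j), dtype=np.int64)
        np.add.at(tab, (table.codes[:, i], y), 1)
        cond.append(tab)
    return NBModel(
        class_counts=class_counts,
        cond_counts=cond,
        var_indices=retained,
        variables=[table.variables[i] for i in retained],
        smoothing=float(smoothing),
    )


def nb_predict_proba(model: NBModel, codes: np.ndarray) -> np.ndarray:
    """Posterior class distribution(s) for instance code vectors.

    ``codes`` is a length-V vector or (n, V) matrix over *all* table
    variables; only the retained columns are consulted.  Add-``smoothing``
    counts regularize both the prior and every conditional, so no posterior
    is ever exactly zero; rows sum to 1.
    """
    c = np.atleast_2d(np.asarray(codes, dtype=np.int64))
    s = model.smoothing
    n_total = model.class_counts.sum()
    j = model.n_classes
    logpost = np.broadcast_to(
        np.log(model.class_counts + s) - np.log(n_total + s * j), (c.shape[0], j)
    ).copy()
    for tab, col in zip(model.cond_counts, model.var_indices):
        col_codes = c[:, col]
        if np.any(col_codes < 0) or np.any(col_codes >= tab.shape[0]):
            raise ValueError(
                f"interval code out of range for variable column {col}"
            )
        w = tab.shape[0]
        logpost += np.log(tab[col_codes, :] + s) - np.log(
            model.class_counts + s * w
        )
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if np.asarray(codes).ndim == 1 else post


class NaiveBayesClassifier:
    """Default plug-in honouring the train / predict-distribution contract.

    Any object with the same two methods (an external tree learner, say) can
    stand in for it in the cross-validation harness.
    """

    def __init__(self, smoothing: float = 1.0):
        self.smoothing = smoothing

    def train(self, table: DiscretizedTable) -> NBModel:
        return nb_train(table, smoothing=self.smoothing)

    def predict_proba(self, model: NBModel, codes: np.ndarray) -> np.ndarray:
        return nb_predict_proba(model, codes)
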