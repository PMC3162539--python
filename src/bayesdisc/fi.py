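"""Recursive entropy-minimization discretization with an MDL stopping rule.

The classic greedy baseline: pick the cut point minimizing the
class-weighted entropy of the two resulting sub-intervals, accept it if the
information gain clears the minimum-description-length (MDLPC) threshold,
and recurse into both halves.  Operates on the same duplicate-aggregated
:class:`~bayesdisc.core.SortedSample` as the Bayesian method and emits the
same model type with midpoint cut values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DiscretizationModel, SortedSample, model_from_boundaries

__all__ = [
    "Segment",
    "class_entropy",
    "split_entropy",
    "mdl_accepts",
    "fi_discretize",
]


def class_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy (bits) of the class distribution given by ``counts``."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy of an empty count vector is undefined")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class Segment:
    """A contiguous run of distinct values, 1-based inclusive [start, end]."""

    sample: SortedSample
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end <= self.sample.n_distinct:
            raise ValueError(
                f"invalid segment [{self.start}, {self.end}] "
                f"for n'={self.sample.n_distinct}"
            )

    @property
    def counts(self) -> np.ndarray:
        return self.sample.counts[self.start - 1 : self.end].sum(axis=0)

    @property
    def size(self) -> int:
        """Number of instances (not distinct values) in the segment."""
        return int(self.counts.sum())


def _halves(segment: Segment, cut: int) -> tuple[np.ndarray, np.ndarray]:
    if not segment.start <= cut < segment.end:
        raise ValueError(
            f"cut {cut} must be an interior gap of [{segment.start}, {segment.end}]"
        )
    c = segment.sample.counts
    left = c[segment.start - 1 : cut].sum(axis=0)
    right = c[cut : segment.end].sum(axis=0)
    return left, right


def split_entropy(cut: int, segment: Segment) -> float:
    """Instance-weighted entropy of the two halves induced by gap ``cut``.

    ``cut`` is the 1-based gap index after distinct value ``cut``; both
    halves are non-empty by construction.
    """
    left, right = _halves(segment, cut)
    n = segment.size
    return (
        left.sum() / n * class_entropy(left)
        + right.sum() / n * class_entropy(right)
    )


def mdl_accepts(segment: Segment, best_cut: int) -> bool:
    """MDLPC decision: is the information gain of ``best_cut`` worth a cut?

    With N instances, k classes present in the segment and k_l, k_r classes
    present in each half, the cut is accepted iff

        Gain > log2(N - 1) / N + Delta / N,
        Delta = log2(3**k - 2) - (k*Ent(S) - k_l*Ent(S_l) - k_r*Ent(S_r)).
    """
    left, right = _halves(segment, best_cut)
    whole = segment.counts
    n = segment.size
    ent = class_entropy(whole)
    gain = ent - split_entropy(best_cut, segment)
    k = int(np.count_nonzero(whole))
    k_l = int(np.count_nonzero(left))
    k_r = int(np.count_nonzero(right))
    delta = math.log2(3**k - 2) - (
        k * ent - k_l * class_entropy(left) - k_r * class_entropy(right)
    )
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def _is_boundary_gap(sample: SortedSample, cut: int) -> bool:
    """A gap flanked by two values pure in the same class is never useful."""
    lo = sample.counts[cut - 1]
    hi = sample.counts[cut]
    lo_nz = np.flatnonzero(lo)
    hi_nz = np.flatnonzero(hi)
    if lo_nz.size == 1 and hi_nz.size == 1 and lo_nz[0] == hi_nz[0]:
        return False
    return True


def fi_discretize(
    sample: SortedSample, boundary_only: bool = False
) -> DiscretizationModel:
    """Greedy top-down entropy discretization with MDL stopping.

    At each segment, scans every interior gap (or, with ``boundary_only``,
    only class-boundary gaps — an equivalent optimization), picks the
    entropy-minimizing cut (leftmost on ties), keeps it if :func:`mdl_accepts`
    and recurses into both halves.
    """
    cuts: list[int] = []

    def recurse(start: int, end: int) -> None:
        if end - start < 1:
            return
        segment = Segment(sample, start, end)
        candidates = np.arange(start, end)
        if boundary_only:
            candidates = np.array(
                [c for c in candidates if _is_boundary_gap(sample, int(c))],
                dtype=np.int64,
            )
            if candidates.size == 0:
                return
        # vectorized split entropies over all candidate gaps
        seg_counts = sample.counts[start - 1 : end].astype(float)
        prefix = np.cumsum(seg_counts, axis=0)
        total = prefix[-1]
        n = total.sum()
        left = prefix[candidates - start]  # gap c keeps values start..c on the left
        right = total - left

        def _ent_rows(rows: np.ndarray) -> np.ndarray:
            tot = rows.sum(axis=1, keepdims=True)
            p = np.divide(rows, tot, out=np.zeros_like(rows), where=tot > 0)
            logp = np.zeros_like(p)
            np.log2(p, out=logp, where=p > 0)
            return -(p * logp).sum(axis=1)

        ents = (left.sum(axis=1) * _ent_rows(left) + right.sum(axis=1) * _ent_rows(right)) / n
        best = int(candidates[int(np.argmin(ents))])  # argmin is leftmost on ties
        if mdl_accepts(segment, best):
            cuts.append(best)
            recurse(start, best)
            recurse(best + 1, end)

    recurse(1, sample.n_distinct)
    ends = tuple(sorted(cuts)) + (sample.n_distinct,)
    return model_from_boundaries(ends, sample, log_score=None, method="fi")
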