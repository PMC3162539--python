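"""Bayesian scoring and exact search for supervised univariate discretization.

A discretization of a sorted continuous predictor is scored by the product of

* a *structure prior* over the number and placement of cut points — a Poisson
  process over the predictor's observed value range whose total mean ``lam``
  is the expected number of cut points, allocated to each inter-value gap in
  proportion to its width; and
* the *Dirichlet-multinomial marginal likelihood* of the class labels inside
  each interval, with the per-interval multinomial parameters integrated out
  against a Dirichlet prior with hyperparameters ``alpha``.

Both factors decompose over intervals, so the highest-scoring discretization
can be found exactly by dynamic programming over prefixes of the sorted
distinct values in O(J * n'**2) time, where n' is the number of distinct
predictor values and J the number of classes.  All arithmetic is carried out
in natural-log space; a brute-force enumerator over all 2**(n'-1) cut
patterns is provided as an independent oracle for the optimality guarantee.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SortedSample",
    "EBDParams",
    "DiscretizationModel",
    "DPState",
    "build_sorted_sample",
    "model_from_boundaries",
    "prior_cut",
    "interval_log_prior",
    "interval_log_marginal",
    "ebd_log_score",
    "ebd_discretize",
    "brute_force_discretize",
    "enumerate_cut_patterns",
    "pattern_log_prior",
]

#: two composite log scores closer than this are treated as tied and broken
#: deterministically (fewer intervals first, then the longer final interval).
TIE_TOL = 1e-12


@dataclass(frozen=True)
class SortedSample:
    """Duplicate-aggregated, ascending-sorted view of one predictor.

    ``values`` holds the n' strictly increasing distinct predictor values and
    ``counts`` the (n', J) matrix of per-value class tallies.  Cut points can
    only fall in the n'-1 gaps between consecutive distinct values.
    """

    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if not np.all(np.isfinite(values)):
            raise ValueError("predictor values must be finite")
        if np.any(np.diff(values) <= 0):
            raise ValueError("values must be strictly increasing")
        if counts.ndim != 2 or counts.shape[0] != values.size:
            raise ValueError("counts must be (n_distinct, n_classes)")
        if counts.shape[1] < 1:
            raise ValueError("need at least one class column")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(counts.sum(axis=1) == 0):
            raise ValueError("every distinct value needs at least one instance")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "counts", counts)

    @property
    def n_distinct(self) -> int:
        """Number of distinct predictor values (n')."""
        return int(self.values.size)

    @property
    def n_classes(self) -> int:
        """Number of target classes (J)."""
        return int(self.counts.shape[1])

    @property
    def n(self) -> int:
        """Total instance count."""
        return int(self.counts.sum())

    @property
    def gaps(self) -> np.ndarray:
        """Widths of the n'-1 interior gaps between consecutive values."""
        return np.diff(self.values)

    @property
    def value_range(self) -> float:
        """Distance between the smallest and largest distinct value."""
        return float(self.values[-1] - self.values[0])

    @staticmethod
    def from_arrays(
        values: Sequence[float],
        labels: Sequence[int],
        n_classes: int | None = None,
    ) -> "SortedSample":
        """Sort, merge duplicates and tally class counts per distinct value."""
        v = np.asarray(values, dtype=float)
        z = np.asarray(labels)
        if v.size == 0:
            raise ValueError("empty input")
        if v.shape != z.shape or v.ndim != 1:
            raise ValueError("values and labels must be equal-length 1-d")
        if not np.all(np.isfinite(v)):
            raise ValueError("predictor values must be finite")
        if not np.issubdtype(z.dtype, np.integer):
            zf = np.asarray(z, dtype=float)
            if np.any(zf != np.round(zf)):
                raise ValueError("labels must be integers")
            z = zf.astype(np.int64)
        if np.any(z < 0):
            raise ValueError("labels must be non-negative class indices")
        j = int(z.max()) + 1
        if n_classes is not None:
            if n_classes < j:
                raise ValueError("label index out of range for n_classes")
            j = int(n_classes)
        distinct, inverse = np.unique(v, return_inverse=True)
        counts = np.zeros((distinct.size, j), dtype=np.int64)
        np.add.at(counts, (inverse, z), 1)
        return SortedSample(distinct, counts)


def build_sorted_sample(
    pairs: Iterable[tuple[float, int]], n_classes: int | None = None
) -> SortedSample:
    """Build a :class:`SortedSample` from (value, class-index) pairs.

    Pairs are sorted ascending by value and equal values are merged into a
    single position with summed class counts, so cut points are only ever
    considered between distinct values.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty input")
    values = [p[0] for p in pairs]
    labels = [p[1] for p in pairs]
    return SortedSample.from_arrays(values, labels, n_classes=n_classes)


@dataclass(frozen=True)
class EBDParams:
    """Hyperparameters of the Bayesian discretization score.

    ``lam`` is the expected total number of cut points over the predictor's
    full value range (structure prior); ``alpha`` gives the Dirichlet prior
    counts per class within each interval, either a positive scalar shared by
    all classes or one positive value per class.  The defaults (``lam=0.5``,
    ``alpha=1``) encode a mild preference for few cut points and a uniform
    prior over each interval's class distribution.
    """

    lam: float = 0.5
    alpha: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError("lam must be a positive finite real")
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if a.ndim != 1 or np.any(~np.isfinite(a)) or np.any(a <= 0):
            raise ValueError("alpha entries must be positive finite reals")

    def alpha_vector(self, n_classes: int) -> np.ndarray:
        """Dirichlet hyperparameters as a length-J vector."""
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if a.size == 1:
            return np.full(n_classes, float(a[0]))
        if a.size != n_classes:
            raise ValueError(
                f"alpha has length {a.size} but the sample has {n_classes} classes"
            )
        return a.copy()


@dataclass(frozen=True)
class DiscretizationModel:
    """A discretization: interval boundaries, cut values and class tallies.

    ``boundaries`` are 1-based end indices into the distinct-value sequence
    (the last is always n'); ``cut_values`` are the W-1 midpoints between the
    distinct values flanking each boundary.  ``log_score`` is the natural-log
    Bayesian score for models learned by the Bayesian search and ``None`` for
    the entropy/MDL baseline, which does not define one.
    """

    boundaries: tuple[int, ...]
    cut_values: np.ndarray
    interval_counts: np.ndarray
    log_score: float | None
    method: str = "ebd"

    @property
    def W(self) -> int:
        """Number of intervals."""
        return len(self.boundaries)

    @property
    def interval_totals(self) -> np.ndarray:
        """Instances per interval (n_i)."""
        return self.interval_counts.sum(axis=1)


@dataclass
class DPState:
    """Dynamic-programming byproducts of the optimal-discretization search.

    ``V[a]`` is the log score of the best discretization of the first ``a``
    distinct values (``V[0] = 0``), ``back[a]`` the start index of the last
    interval of that prefix optimum, and ``W[a]`` its interval count.  One
    prefix-optimal discretization is stored per prefix, so ``n_prefix_optima``
    equals n'; ``n_cell_evaluations`` counts candidate (start, end) interval
    evaluations, the n'(n'+1)/2 inner-loop work driving the quadratic cost.
    """

    V: np.ndarray
    back: np.ndarray
    W: np.ndarray
    n_cell_evaluations: int

    @property
    def n_prefix_optima(self) -> int:
        return int(self.V.size - 1)


def _validate_boundaries(boundaries: Sequence[int], n_distinct: int) -> tuple[int, ...]:
    ends = tuple(int(b) for b in boundaries)
    if len(ends) == 0:
        raise ValueError("boundaries must contain at least one interval end")
    if any(e2 <= e1 for e1, e2 in zip(ends, ends[1:])):
        raise ValueError("boundaries must be strictly increasing")
    if ends[0] < 1 or ends[-1] != n_distinct:
        raise ValueError(
            f"boundaries must partition 1..{n_distinct} (got {ends})"
        )
    return ends


def model_from_boundaries(
    boundaries: Sequence[int],
    sample: SortedSample,
    log_score: float | None = None,
    method: str = "ebd",
) -> DiscretizationModel:
    """Assemble a :class:`DiscretizationModel` from interval end indices.

    Cut values are placed at the midpoint of the two distinct values flanking
    each boundary, the usual convention for interval thresholds.
    """
    ends = _validate_boundaries(boundaries, sample.n_distinct)
    cuts = np.array(
        [(sample.values[e - 1] + sample.values[e]) / 2.0 for e in ends[:-1]],
        dtype=float,
    )
    csum = np.vstack(
        [np.zeros((1, sample.n_classes), dtype=np.int64), np.cumsum(sample.counts, axis=0)]
    )
    starts = (0,) + ends[:-1]
    interval_counts = np.array([csum[e] - csum[s] for s, e in zip(starts, ends)])
    return DiscretizationModel(
        boundaries=ends,
        cut_values=cuts,
        interval_counts=interval_counts,
        log_score=log_score,
        method=method,
    )


def prior_cut(k: int, sample: SortedSample, lam: float) -> float:
    """Probability of at least one cut point in gap ``k``.

    ``k`` is a 1-based gap index: gap k separates distinct values k and k+1.
    The two virtual boundary gaps k=0 (below the smallest value) and k=n'
    (above the largest) always carry a cut, so ``prior_cut`` is 1 there.  For
    interior gaps the cut count follows a Poisson process whose mean over the
    whole range is ``lam``, spread proportionally to gap width:

        P(cut in gap k) = 1 - exp(-lam * d(k, k+1) / d(1, n'))
    """
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError("lam must be a positive finite real")
    nd = sample.n_distinct
    if not 0 <= k <= nd:
        raise ValueError(f"gap index {k} outside 0..{nd}")
    if k == 0 or k == nd:
        return 1.0
    # interior gap: nd >= 2 here, so the range is positive
    gap = float(sample.values[k] - sample.values[k - 1])
    return float(-math.expm1(-lam * gap / sample.value_range))


def _gap_log_terms(sample: SortedSample, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-interior-gap (log(1-P), log(P)) arrays, index k-1 for gap k."""
    if sample.n_distinct == 1:
        empty = np.empty(0)
        return empty, empty
    rate = lam * sample.gaps / sample.value_range
    p = -np.expm1(-rate)
    return np.log1p(-p), np.log(p)


def interval_log_prior(b: int, a: int, sample: SortedSample, lam: float) -> float:
    """Log structure prior of one interval spanning distinct values b..a.

    The interval contributes "no cut" factors for each of its internal gaps
    b..a-1 and one "cut" factor for the gap at its right end a (which is 1
    when a = n', the virtual boundary above the data).
    """
    nd = sample.n_distinct
    if not 1 <= b <= a <= nd:
        raise ValueError(f"invalid interval [{b}, {a}] for n'={nd}")
    ln_keep, ln_cut = _gap_log_terms(sample, lam)
    inner = float(ln_keep[b - 1 : a - 1].sum())
    tail = 0.0 if a == nd else float(ln_cut[a - 1])
    return inner + tail


def interval_log_marginal(
    counts: Sequence[float], alpha: float | Sequence[float]
) -> float:
    """Log Dirichlet-multinomial marginal likelihood of one interval.

    With class counts n_ij, totals n_i and hyperparameters a_ij (a_i their
    sum) the interval contributes

        Gamma(a_i) / Gamma(a_i + n_i) * prod_j Gamma(a_ij + n_ij) / Gamma(a_ij)

    which for all-1 hyperparameters reduces to the familiar factorial ratio
    (J-1)! / (n_i + J - 1)! * prod_j n_ij!.  Evaluated with log-gamma for
    numerical stability.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-d class-count vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("interval must contain at least one instance")
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    if a.size == 1:
        a = np.full(c.size, float(a[0]))
    if a.size != c.size:
        raise ValueError("alpha and counts length mismatch")
    if np.any(a <= 0):
        raise ValueError("alpha entries must be positive")
    a0 = a.sum()
    return float(
        gammaln(a0) - gammaln(a0 + total) + np.sum(gammaln(a + c) - gammaln(a))
    )


def ebd_log_score(
    model: DiscretizationModel | Sequence[int],
    sample: SortedSample,
    params: EBDParams | None = None,
) -> float:
    """Log Bayesian score of a discretization (structure prior x marginal).

    Decomposes exactly as the sum over intervals of ``interval_log_prior`` +
    ``interval_log_marginal``; the virtual cut below the data has probability
    1 and contributes nothing.
    """
    params = params or EBDParams()
    ends = (
        model.boundaries
        if isinstance(model, DiscretizationModel)
        else _validate_boundaries(model, sample.n_distinct)
    )
    _validate_boundaries(ends, sample.n_distinct)
    alpha = params.alpha_vector(sample.n_classes)
    csum = np.vstack(
        [np.zeros((1, sample.n_classes), dtype=np.int64), np.cumsum(sample.counts, axis=0)]
    )
    total = 0.0
    start = 1
    for end in ends:
        counts = csum[end] - csum[start - 1]
        total += interval_log_prior(start, end, sample, params.lam)
        total += interval_log_marginal(counts, alpha)
        start = end + 1
    return total


def ebd_discretize(
    sample: SortedSample,
    params: EBDParams | None = None,
    return_state: bool = False,
) -> DiscretizationModel | tuple[DiscretizationModel, DPState]:
    """Globally optimal discretization by dynamic programming.

    Solves the recurrence (log space, V[0] = 0)

        V[a] = max_{1<=b<=a} V[b-1] + logprior(b, a) + logmarglik(counts b..a)

    over prefixes a = 1..n' of the sorted distinct values, storing one
    prefix-optimal discretization per prefix; back-pointers recover the
    global optimum.  Score ties within :data:`TIE_TOL` prefer fewer
    intervals, then the candidate whose final interval is longer.
    """
    params = params or EBDParams()
    nd, j = sample.n_distinct, sample.n_classes
    alpha = params.alpha_vector(j)
    a0 = alpha.sum()
    gl_alpha = float(np.sum(gammaln(alpha)))
    csum = np.vstack([np.zeros((1, j)), np.cumsum(sample.counts, axis=0)]).astype(float)

    ln_keep, ln_cut = _gap_log_terms(sample, params.lam)
    # G[m] = sum of "no cut" log terms over gaps 1..m
    G = np.concatenate([[0.0], np.cumsum(ln_keep)])
    # log prior_cut at the right end of an interval finishing at a (1 if a=n')
    ln_end = np.concatenate([ln_cut, [0.0]])

    V = np.zeros(nd + 1)
    back = np.zeros(nd + 1, dtype=np.int64)
    W = np.zeros(nd + 1, dtype=np.int64)
    n_cells = 0
    for a in range(1, nd + 1):
        nb = csum[a] - csum[:a]  # row b-1: counts of interval b..a
        totals = nb.sum(axis=1)
        ml = gammaln(a0) - gammaln(a0 + totals) + gammaln(alpha + nb).sum(axis=1) - gl_alpha
        lp = (G[a - 1] - G[:a]) + ln_end[a - 1]
        comp = V[:a] + lp + ml
        n_cells += a
        best_score = comp.max()
        cand = np.flatnonzero(comp >= best_score - TIE_TOL)
        # ties: fewer total intervals first, then smaller b (longer final interval)
        order = np.lexsort((cand, W[cand]))
        best = int(cand[order[0]])
        V[a] = comp[best]
        back[a] = best + 1
        W[a] = W[best] + 1

    ends: list[int] = []
    a = nd
    while a > 0:
        ends.append(a)
        a = int(back[a]) - 1
    ends.reverse()
    model = model_from_boundaries(tuple(ends), sample, log_score=float(V[nd]))
    if return_state:
        return model, DPState(V=V, back=back, W=W, n_cell_evaluations=n_cells)
    return model


def enumerate_cut_patterns(n_distinct: int) -> Iterator[tuple[int, ...]]:
    """Yield every cut-point pattern over the n'-1 interior gaps once.

    A pattern is a sorted tuple of 1-based gap indices carrying a cut; the
    total number of patterns is 2**(n'-1).  Yields in order of increasing
    cut count, lexicographically within each count.
    """
    if n_distinct < 1:
        raise ValueError("n_distinct must be at least 1")
    gaps = range(1, n_distinct)
    for r in range(n_distinct):
        yield from itertools.combinations(gaps, r)


def pattern_log_prior(
    cuts: Sequence[int], sample: SortedSample, lam: float
) -> float:
    """Log structure prior of a full cut pattern (marginal likelihood ignored).

    Summing ``exp`` of this over all 2**(n'-1) patterns gives exactly 1: each
    interior gap independently either carries a cut or does not.
    """
    ends = tuple(sorted(int(c) for c in cuts)) + (sample.n_distinct,)
    _validate_boundaries(ends, sample.n_distinct)
    total = 0.0
    start = 1
    for end in ends:
        total += interval_log_prior(start, end, sample, lam)
        start = end + 1
    return total


def brute_force_discretize(
    sample: SortedSample,
    params: EBDParams | None = None,
    max_distinct: int = 16,
) -> DiscretizationModel:
    """Exhaustive-search oracle for the optimal discretization.

    Scores every one of the 2**(n'-1) cut patterns and returns the maximum
    under the same tie-break rule as :func:`ebd_discretize`.  Guarded by
    ``max_distinct`` because the search space doubles with every additional
    distinct value.
    """
    params = params or EBDParams()
    nd = sample.n_distinct
    if nd > max_distinct:
        raise ValueError(
            f"n'={nd} exceeds the brute-force cap of {max_distinct} distinct values"
        )
    alpha = params.alpha_vector(sample.n_classes)
    csum = np.vstack(
        [np.zeros((1, sample.n_classes), dtype=np.int64), np.cumsum(sample.counts, axis=0)]
    )
    # precompute the score of every candidate single interval [b, a]
    term = np.full((nd + 1, nd + 1), -np.inf)
    for b in range(1, nd + 1):
        for a in range(b, nd + 1):
            term[b, a] = interval_log_prior(b, a, sample, params.lam) + interval_log_marginal(
                csum[a] - csum[b - 1], alpha
            )

    patterns = list(enumerate_cut_patterns(nd))
    scores = np.empty(len(patterns))
    for i, cuts in enumerate(patterns):
        ends = cuts + (nd,)
        s = 0.0
        start = 1
        for end in ends:
            s += term[start, end]
            start = end + 1
        scores[i] = s

    best_score = scores.max()
    tied = np.flatnonzero(scores >= best_score - TIE_TOL)
    # fewer intervals first, then longer final interval (smaller last cut),
    # then earlier preceding cuts — compare the cut tuple from the right.
    def _key(i: int) -> tuple:
        cuts = patterns[i]
        return (len(cuts), tuple(reversed(cuts)))

    winner = min(tied, key=_key)
    ends = patterns[winner] + (nd,)
    return model_from_boundaries(
        ends, sample, log_score=float(scores[winner]), method="ebd"
    )
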