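"""Independent oracles used by the test suite.

Everything here is deliberately written the slow, obvious way — pure-Python
factorial ratios, explicit pair counting, exhaustive sign-pattern
enumeration — so it shares no code path with the implementation it checks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np

from bayesdisc import build_sorted_sample


def make_random_sample(rng, n_distinct, n_classes, spread=10.0):
    """Random sorted sample with the requested distinct-value count."""
    values = np.sort(rng.uniform(0, spread, size=n_distinct))
    while np.any(np.diff(values) <= 0):  # astronomically unlikely collision
        values = np.sort(rng.uniform(0, spread, size=n_distinct))
    pairs = []
    for v in values:
        for _ in range(int(rng.integers(1, 4))):
            pairs.append((float(v), int(rng.integers(0, n_classes))))
    return build_sorted_sample(pairs, n_classes=n_classes)


def naive_log_score(boundaries, sample, lam):
    """Non-incremental Bayesian log score, all-1 hyperparameters only.

    Marginal likelihoods via exact Fraction factorial ratios, priors via the
    closed form per gap; no shared scaffolding with the library scorer.
    """
    counts = np.asarray(sample.counts)
    values = np.asarray(sample.values)
    nd, j = counts.shape
    rng_width = values[-1] - values[0]

    def p_cut(k):  # 1-based interior gap
        return -math.expm1(-lam * (values[k] - values[k - 1]) / rng_width)

    total = 0.0
    start = 1
    for end in boundaries:
        # prior: no cut inside, cut at the right end (prob 1 at the top)
        for k in range(start, end):
            total += math.log(1 - p_cut(k))
        if end < nd:
            total += math.log(p_cut(end))
        # marginal likelihood: (J-1)! / (n_i+J-1)! * prod n_ij!
        n_ij = counts[start - 1 : end].sum(axis=0)
        n_i = int(n_ij.sum())
        ml = Fraction(math.factorial(j - 1), math.factorial(n_i + j - 1))
        for c in n_ij:
            ml *= math.factorial(int(c))
        total += math.log(ml)
        start = end + 1
    return total


def hand_till_oracle(proba, labels):
    """Multi-class AUC by explicit instance-pair counting per class pair."""
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    j = proba.shape[1]

    def pair_auc(score_col, pos, neg):
        wins = 0.0
        n = 0
        for a in np.flatnonzero(labels == pos):
            for b in np.flatnonzero(labels == neg):
                if proba[a, score_col] > proba[b, score_col]:
                    wins += 1.0
                elif proba[a, score_col] == proba[b, score_col]:
                    wins += 0.5
                n += 1
        return wins / n

    vals = []
    for a, b in itertools.combinations(range(j), 2):
        vals.append((pair_auc(a, a, b) + pair_auc(b, b, a)) / 2)
    return float(np.mean(vals))


def exact_wilcoxon_two_sided_p(diffs):
    """Two-sided p by enumerating all 2^m sign patterns of the rank sums."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = m * (m + 1) / 4
    dev = abs(w_obs - mu)
    hits = 0
    for signs in itertools.product([0, 1], repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev - 1e-12:
            hits += 1
    return hits / 2**m


def fi_recursion_oracle(sample):
    """Plain-loop replay of the greedy entropy/MDL recursion."""
    from bayesdisc import Segment, class_entropy, mdl_accepts, split_entropy

    cuts = []

    def recurse(start, end):
        if end <= start:
            return
        seg = Segment(sample, start, end)
        best, best_ent = None, None
        for c in range(start, end):
            e = split_entropy(c, seg)
            if best_ent is None or e < best_ent - 1e-12:
                best, best_ent = c, e
        if best is not None and mdl_accepts(seg, best):
            cuts.append(best)
            recurse(start, best)
            recurse(best + 1, end)

    recurse(1, sample.n_distinct)
    return sorted(cuts)
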