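"""Bayesian score components and the exact dynamic-programming search."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bayesdisc import (
    EBDParams,
    SortedSample,
    brute_force_discretize,
    build_sorted_sample,
    ebd_discretize,
    ebd_log_score,
    enumerate_cut_patterns,
    interval_log_marginal,
    interval_log_prior,
    model_from_boundaries,
    pattern_log_prior,
    prior_cut,
)
from helpers import make_random_sample, naive_log_score

TOY_PAIRS = [(1.2, 0), (1.4, 0), (1.6, 0), (3.7, 1), (3.9, 1), (4.1, 1)]


class TestBuildSortedSample:
    def test_six_instance_example(self, toy):
        assert toy.n_distinct == 6
        assert toy.n == 6
        assert toy.n_classes == 2
        # each distinct value holds exactly one instance of one class
        assert np.all(toy.counts.sum(axis=1) == 1)
        assert np.array_equal(toy.counts[:3, 0], [1, 1, 1])
        assert np.array_equal(toy.counts[3:, 1], [1, 1, 1])

    def test_duplicates_merge(self):
        s = build_sorted_sample([(2.0, 0), (2.0, 1)])
        assert s.n_distinct == 1
        assert s.n == 2
        assert np.array_equal(s.counts, [[1, 1]])

    def test_matches_groupby_tally(self, rng):
        import pandas as pd

        distinct = np.linspace(0, 9, 10)
        values = rng.choice(distinct, size=50)
        labels = rng.integers(0, 3, size=50)
        s = build_sorted_sample(list(zip(values, labels)), n_classes=3)
        assert s.n_distinct == np.unique(values).size
        oracle = (
            pd.DataFrame({"v": values, "z": labels})
            .groupby("v")["z"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=range(3), fill_value=0)
            .sort_index()
        )
        assert np.array_equal(s.counts, oracle.to_numpy())
        assert s.n == 50

    @pytest.mark.parametrize(
        "pairs", [[], [(float("nan"), 0)], [(float("inf"), 1)]]
    )
    def test_rejects_bad_input(self, pairs):
        with pytest.raises(ValueError):
            build_sorted_sample(pairs)

    def test_rejects_label_outside_range(self):
        with pytest.raises(ValueError):
            build_sorted_sample([(1.0, 3)], n_classes=2)


class TestPriorCut:
    def test_boundary_gaps_are_certain(self, toy):
        assert prior_cut(0, toy, 0.5) == 1.0
        assert prior_cut(6, toy, 0.5) == 1.0

    def test_wide_gap(self, toy):
        # the 1.6 -> 3.7 gap: width 2.1 of a 2.9 range
        expected = 1 - math.exp(-0.5 * 2.1 / 2.9)
        assert prior_cut(3, toy, 0.5) == pytest.approx(expected, abs=1e-12)
        assert prior_cut(3, toy, 0.5) == pytest.approx(0.3038, abs=1e-4)

    def test_narrow_gap(self, toy):
        expected = 1 - math.exp(-0.5 * 0.2 / 2.9)
        for k in (1, 2, 4, 5):
            assert prior_cut(k, toy, 0.5) == pytest.approx(expected, abs=1e-12)
        assert prior_cut(1, toy, 0.5) == pytest.approx(0.033895, abs=5e-7)

    def test_single_value_sample(self):
        s = build_sorted_sample([(2.0, 0), (2.0, 1)])
        assert prior_cut(0, s, 0.5) == 1.0
        assert prior_cut(1, s, 0.5) == 1.0
        with pytest.raises(ValueError):
            prior_cut(2, s, 0.5)

    def test_rejects_bad_lambda(self, toy):
        with pytest.raises(ValueError):
            prior_cut(1, toy, -1.0)


class TestIntervalLogPrior:
    def test_final_single_value_interval(self, toy):
        # empty no-cut product times the certain top boundary cut
        assert interval_log_prior(6, 6, toy, 0.5) == 0.0

    def test_prefix_interval_composition(self, toy):
        p_narrow = prior_cut(1, toy, 0.5)
        p_wide = prior_cut(3, toy, 0.5)
        expected = 2 * math.log(1 - p_narrow) + math.log(p_wide)
        assert interval_log_prior(1, 3, toy, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_whole_range_interval(self, toy):
        expected = sum(
            math.log(1 - prior_cut(k, toy, 0.5)) for k in range(1, 6)
        )
        assert interval_log_prior(1, 6, toy, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_rejects_reversed_interval(self, toy):
        with pytest.raises(ValueError):
            interval_log_prior(4, 2, toy, 0.5)


class TestIntervalLogMarginal:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 0), 0.5),
            ((3, 0), 0.25),
            ((3, 3), 36 / 5040),
        ],
    )
    def test_factorial_arithmetic(self, counts, expected):
        assert interval_log_marginal(counts, 1.0) == pytest.approx(
            math.log(expected), rel=1e-12
        )

    def test_matches_direct_factorials(self, rng):
        # log-space evaluation vs. exact factorial-ratio arithmetic, n <= 30
        from fractions import Fraction

        for _ in range(100):
            j = int(rng.integers(2, 5))
            counts = rng.multinomial(int(rng.integers(1, 31)), np.ones(j) / j)
            n_i = int(counts.sum())
            exact = Fraction(math.factorial(j - 1), math.factorial(n_i + j - 1))
            for c in counts:
                exact *= math.factorial(int(c))
            assert math.exp(interval_log_marginal(counts, 1.0)) == pytest.approx(
                float(exact), rel=1e-9
            )

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            interval_log_marginal((0, 0), 1.0)
        with pytest.raises(ValueError):
            interval_log_marginal((1, 2), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            interval_log_marginal((1, 2), 0.0)


class TestEbdLogScore:
    def test_single_interval_decomposition(self, toy):
        expected = interval_log_prior(1, 6, toy, 0.5) + interval_log_marginal(
            toy.counts.sum(axis=0), 1.0
        )
        assert ebd_log_score([6], toy) == pytest.approx(expected, abs=1e-12)

    def test_class_boundary_split_beats_merge(self, toy):
        split = ebd_log_score([3, 6], toy)
        merged = ebd_log_score([6], toy)
        # marginal-likelihood ratio 8.75 outweighs the prior cost of the cut
        p = prior_cut(3, toy, 0.5)
        assert split - merged == pytest.approx(
            math.log(8.75) + math.log(p / (1 - p)), rel=1e-10
        )
        assert split > merged

    def test_decomposes_over_intervals(self, rng):
        for _ in range(20):
            s = make_random_sample(rng, int(rng.integers(3, 10)), 3)
            nd = s.n_distinct
            n_cuts = int(rng.integers(0, nd))
            cuts = sorted(rng.choice(np.arange(1, nd), size=n_cuts, replace=False))
            ends = [*cuts, nd]
            total = 0.0
            start = 1
            for end in ends:
                counts = s.counts[start - 1 : end].sum(axis=0)
                total += interval_log_prior(start, end, s, 0.5)
                total += interval_log_marginal(counts, 1.0)
                start = end + 1
            assert ebd_log_score(ends, s) == pytest.approx(total, abs=1e-12)

    def test_matches_nonincremental_oracle(self, rng):
        for _ in range(20):
            s = make_random_sample(rng, int(rng.integers(2, 9)), 2)
            nd = s.n_distinct
            cuts = [k for k in range(1, nd) if rng.random() < 0.5]
            ends = [*cuts, nd]
            assert ebd_log_score(ends, s) == pytest.approx(
                naive_log_score(ends, s, 0.5), rel=1e-10, abs=1e-10
            )

    def test_rejects_non_partition(self, toy):
        with pytest.raises(ValueError):
            ebd_log_score([3, 5], toy)  # does not end at n'
        with pytest.raises(ValueError):
            ebd_log_score([4, 3, 6], toy)


class TestEbdDiscretize:
    def test_worked_example(self, toy):
        model = ebd_discretize(toy)
        assert model.boundaries == (3, 6)
        assert model.W == 2
        assert model.cut_values == pytest.approx([2.65])
        assert np.array_equal(model.interval_counts, [[3, 0], [0, 3]])

    def test_constant_target_collapses(self, rng):
        for _ in range(10):
            nd = int(rng.integers(1, 15))
            values = np.sort(rng.uniform(0, 5, size=nd))
            pairs = [(float(v), 0) for v in values for _ in range(int(rng.integers(1, 3)))]
            model = ebd_discretize(build_sorted_sample(pairs, n_classes=2))
            assert model.W == 1

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            nd = int(rng.integers(2, 13))
            j = int(rng.integers(2, 5))
            lam = float(rng.uniform(0.05, 3.0))
            s = make_random_sample(rng, nd, j)
            params = EBDParams(lam=lam)
            dp = ebd_discretize(s, params)
            bf = brute_force_discretize(s, params)
            assert dp.log_score == pytest.approx(bf.log_score, abs=1e-9)
            assert dp.boundaries == bf.boundaries

    def test_deterministic(self, rng):
        s = make_random_sample(rng, 8, 2)
        a = ebd_discretize(s)
        b = ebd_discretize(s)
        assert a.boundaries == b.boundaries
        assert a.log_score == b.log_score

    def test_score_consistent_with_scorer(self, rng):
        s = make_random_sample(rng, 9, 3)
        model = ebd_discretize(s)
        assert model.log_score == pytest.approx(
            ebd_log_score(model, s), abs=1e-9
        )

    def test_quadratic_inner_loop_growth(self, rng):
        def cells(nd):
            s = make_random_sample(rng, nd, 2)
            _, state = ebd_discretize(s, return_state=True)
            assert state.n_prefix_optima == nd
            return state.n_cell_evaluations

        ratio = cells(40) / cells(20)
        assert 3.5 < ratio < 4.5  # ~4x work when n' doubles

    @given(st.integers(0, 2**31 - 1))
    def test_dp_never_beaten_by_random_pattern(self, seed):
        rng = np.random.default_rng(seed)
        s = make_random_sample(rng, int(rng.integers(2, 10)), 2)
        nd = s.n_distinct
        model = ebd_discretize(s)
        cuts = sorted(
            rng.choice(np.arange(1, nd), size=int(rng.integers(0, nd)), replace=False)
        )
        assert model.log_score >= ebd_log_score([*cuts, nd], s) - 1e-9


class TestBruteForce:
    def test_single_distinct_value(self):
        s = build_sorted_sample([(1.0, 0), (1.0, 1)])
        model = brute_force_discretize(s)
        assert model.boundaries == (1,)
        assert model.W == 1

    def test_cap_guard(self, rng):
        s = make_random_sample(rng, 18, 2)
        with pytest.raises(ValueError):
            brute_force_discretize(s, max_distinct=16)


class TestCutPatterns:
    @pytest.mark.parametrize("nd,count", [(1, 1), (4, 8), (6, 32)])
    def test_counts(self, nd, count):
        patterns = list(enumerate_cut_patterns(nd))
        assert len(patterns) == count
        assert len(set(patterns)) == count

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            list(enumerate_cut_patterns(0))


class TestStructurePriorNormalization:
    @pytest.mark.parametrize("nd", [2, 5, 9])
    def test_prior_sums_to_one(self, rng, nd):
        s = make_random_sample(rng, nd, 2)
        total = sum(
            math.exp(pattern_log_prior(cuts, s, 0.7))
            for cuts in enumerate_cut_patterns(nd)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestModelAssembly:
    def test_cut_values_are_flanking_midpoints(self, rng):
        s = make_random_sample(rng, 7, 2)
        model = model_from_boundaries([2, 5, 7], s)
        for cut, end in zip(model.cut_values, (2, 5)):
            lo, hi = s.values[end - 1], s.values[end]
            assert lo < cut < hi
            assert cut == pytest.approx((lo + hi) / 2)

    def test_interval_counts_partition_total(self, rng):
        s = make_random_sample(rng, 7, 3)
        model = model_from_boundaries([3, 7], s)
        assert model.interval_totals.sum() == s.n
        assert np.array_equal(model.interval_counts.sum(axis=0), s.counts.sum(axis=0))
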