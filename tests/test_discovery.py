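"""Stable/reversal REO discovery and stepwise signature selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from reograde import (
    GenePairREO,
    ReversalPair,
    Signature,
    bh_adjust,
    binomial_reo_pvalue,
    classify_sample,
    confusion_f_score,
    find_reversal_pairs,
    find_stable_pairs,
    forward_stepwise_select,
    intersect_reversal_pairs,
)
from reograde.discovery import A_GT_B, A_LT_B

from conftest import make_matrix


def enumeration_tail(s: int, n: int) -> float:
    """Oracle: P(X >= s) by counting all 2^n equiprobable orderings."""
    counts = np.bincount(
        [bin(outcome).count("1") for outcome in range(2**n)], minlength=n + 1
    )
    return counts[s:].sum() / 2**n


class TestBinomialReoPvalue:
    @pytest.mark.parametrize(
        "s, n, expected",
        [
            (10, 10, 0.5**10),
            (8, 10, 56 / 1024),  # C(10,8)+C(10,9)+C(10,10) over 2^10
            (0, 7, 1.0),
        ],
    )
    def test_known_tails(self, s, n, expected):
        assert binomial_reo_pvalue(s, n) == pytest.approx(expected, abs=1e-15)

    def test_matches_enumeration_small_n(self):
        for n in range(1, 9):
            for s in range(n + 1):
                assert binomial_reo_pvalue(s, n) == pytest.approx(
                    enumeration_tail(s, n), abs=1e-12
                )

    @given(st.integers(1, 40), st.data())
    def test_monotone_nonincreasing_in_s(self, n, data):
        s = data.draw(st.integers(1, n))
        assert binomial_reo_pvalue(s, n) <= binomial_reo_pvalue(s - 1, n) + 1e-15

    @pytest.mark.parametrize("s, n", [(5, 4), (0, 0), (-1, 3)])
    def test_domain_errors(self, s, n):
        with pytest.raises(ValueError):
            binomial_reo_pvalue(s, n)


def stepup_oracle(p):
    """Literal BH step-up: sort, cumulative min of p*(m/rank) from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adjusted[order[rank - 1]] = running
    return adjusted


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_literal_stepup(self, p):
        np.testing.assert_allclose(bh_adjust(p), stepup_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    def test_permutation_invariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        direct = bh_adjust(p)
        via_perm = bh_adjust(shuffled)
        np.testing.assert_allclose([via_perm[perm.index(i)] for i in range(len(p))], direct)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFindStablePairs:
    def test_unanimous_pair_returned_with_direction(self):
        # g1 > g2 in all 6 samples; sole candidate
        m = make_matrix(np.array([[5.0] * 6, [1.0] * 6]))
        (pair,) = find_stable_pairs(m, candidate_pairs=[("g1", "g2")])
        assert pair.direction == A_GT_B
        assert (pair.s, pair.n) == (6, 6)
        assert pair.p_value == pytest.approx(0.5**6)
        assert pair.fdr == pytest.approx(0.5**6)

    def test_coin_flip_pair_excluded(self):
        vals = np.array([[5.0, 5, 5, 1, 1, 1], [1.0, 1, 1, 5, 5, 5]])
        assert find_stable_pairs(make_matrix(vals), candidate_pairs=[("g1", "g2")]) == []
        # direction split 3/6 -> p = P(X>=3) = 0.65625, fdr above threshold
        assert binomial_reo_pvalue(3, 6) == pytest.approx(0.65625)

    def test_tie_reduces_evaluable_count(self):
        vals = np.array([[5.0, 5, 5, 5, 5, 3], [1.0, 1, 1, 1, 1, 3]])
        (pair,) = find_stable_pairs(make_matrix(vals), candidate_pairs=[("g1", "g2")])
        assert (pair.s, pair.n) == (5, 5)

    def test_missing_value_reduces_evaluable_count(self):
        vals = np.array([[5.0, 5, 5, 5, 5, np.nan], [1.0, 1, 1, 1, 1, 3]])
        (pair,) = find_stable_pairs(make_matrix(vals), candidate_pairs=[("g1", "g2")])
        assert (pair.s, pair.n) == (5, 5)

    def test_all_pairs_default_matches_candidate_enumeration(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(8, 10)))
        all_pairs = list(itertools.combinations(sorted(m.gene_ids), 2))
        by_default = {p.key: p for p in find_stable_pairs(m)}
        by_candidates = {p.key: p for p in find_stable_pairs(m, candidate_pairs=all_pairs)}
        assert by_default == by_candidates

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(10, 12)))
        transformed = make_matrix(np.exp(m.data.to_numpy() * 2.0) + 1.0)
        assert find_stable_pairs(m) == find_stable_pairs(transformed)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            find_stable_pairs(make_matrix([[1.0], [2.0]]))


def _reo(a, b, direction, s=10, n=10):
    p = binomial_reo_pvalue(s, n)
    return GenePairREO(a, b, direction, s, n, p, p)


class TestReversalPairs:
    def test_opposite_directions_make_reversal(self):
        rev = find_reversal_pairs([_reo("g1", "g2", A_GT_B)], [_reo("g1", "g2", A_LT_B)])
        assert len(rev) == 1
        assert rev[0].hg1_direction == A_GT_B
        assert rev[0].oriented == ("g1", "g2")

    def test_same_direction_excluded(self):
        assert find_reversal_pairs(
            [_reo("g1", "g2", A_GT_B)], [_reo("g1", "g2", A_GT_B)]
        ) == []

    def test_one_sided_stability_excluded(self):
        assert find_reversal_pairs([_reo("g1", "g2", A_GT_B)], []) == []

    def _rev(self, a, b, hg1_dir=A_GT_B, margin=1.0):
        other = A_LT_B if hg1_dir == A_GT_B else A_GT_B
        return ReversalPair(a, b, hg1_dir, other, _reo(a, b, hg1_dir), _reo(a, b, other), margin)

    def test_intersection_requires_presence_and_orientation(self):
        sets = [[self._rev("g1", "g2"), self._rev("g3", "g4")] for _ in range(6)]
        sets.append([self._rev("g1", "g2"), self._rev("g3", "g4", hg1_dir=A_LT_B)])
        out = intersect_reversal_pairs(sets)
        assert [r.key for r in out] == [("g1", "g2")]  # g3/g4 flipped in one set

    def test_pair_absent_from_one_set_dropped(self):
        sets = [[self._rev("g1", "g2")]] * 6 + [[]]
        assert intersect_reversal_pairs(sets) == []

    def test_commutative_and_associative(self):
        s1 = [self._rev("g1", "g2", margin=2.0)]
        s2 = [self._rev("g1", "g2", margin=3.0), self._rev("g3", "g4")]
        s3 = [self._rev("g1", "g2", margin=4.0)]
        keys = lambda sets: [r.key for r in intersect_reversal_pairs(sets)]
        assert keys([s1, s2, s3]) == keys([s3, s1, s2]) == keys([s2, s3, s1])
        # margins accumulate over datasets regardless of order
        assert intersect_reversal_pairs([s1, s2, s3])[0].margin == 9.0


class TestConfusionFScore:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [(0.8699, 0.9077, 0.8884), (1.0, 1.0, 1.0), (0.0, 0.9, 0.0)],
    )
    def test_values(self, sens, spec, expected):
        assert confusion_f_score(sens, spec) == pytest.approx(expected, abs=5e-5)

    def test_zero_denominator_defined(self):
        assert confusion_f_score(0.0, 0.0) == 0.0


def exhaustive_best_f(candidates, matrix, labels):
    """Oracle: the best F-score over ALL non-empty candidate subsets,
    scoring each subset with the per-sample dict classifier."""
    best = -1.0
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            sig = Signature.from_pairs([c.oriented for c in subset])
            tp = fn = tn = fp = 0
            for sample in matrix.sample_ids:
                call = classify_sample(
                    matrix.data[sample].to_dict(), sig, min_evaluable_fraction=0.0
                ).call
                if labels[sample] == "pHG3":
                    tp += call == "HG3"
                    fn += call != "HG3"
                else:
                    tn += call == "HG1"
                    fp += call != "HG1"
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            best = max(best, confusion_f_score(sens, spec))
    return best


def _noisy_candidates(rng, n_pairs, n_per_group, flip_rate):
    """Build a cohort where each planted pair is individually imperfect."""
    genes, rows = [], []
    n = 2 * n_per_group
    labels = {}
    sample_ids = [f"s{i}" for i in range(n)]
    for i, s in enumerate(sample_ids):
        labels[s] = "pHG1" if i < n_per_group else "pHG3"
    is_hg3 = np.array([labels[s] == "pHG3" for s in sample_ids])
    for k in range(n_pairs):
        hi = 5.0 + rng.normal(0, 0.1, n)
        lo = 3.0 + rng.normal(0, 0.1, n)
        flip = rng.random(n) < flip_rate
        a = np.where(is_hg3 ^ flip, np.minimum(hi, lo), np.maximum(hi, lo))
        b = np.where(is_hg3 ^ flip, np.maximum(hi, lo), np.minimum(hi, lo))
        rows += [a, b]
        genes += [f"p{k}a", f"p{k}b"]
    matrix = make_matrix(np.array(rows), gene_ids=genes, sample_ids=sample_ids)
    candidates = [
        ReversalPair(
            *sorted((f"p{k}a", f"p{k}b")),
            A_GT_B, A_LT_B,
            _reo(f"p{k}a", f"p{k}b", A_GT_B), _reo(f"p{k}a", f"p{k}b", A_LT_B),
            margin=1.0,
        )
        for k in range(n_pairs)
    ]
    return candidates, matrix, labels


class TestForwardStepwiseSelect:
    def test_perfect_single_pair_stops_at_size_one(self, small_cohort):
        matrix, clinical, truth = small_cohort
        a, b = truth.planted_pairs[0]
        cand = [
            ReversalPair(*sorted((a, b)), A_GT_B if a < b else A_LT_B,
                         A_LT_B if a < b else A_GT_B,
                         _reo(*sorted((a, b)), A_GT_B if a < b else A_LT_B),
                         _reo(*sorted((a, b)), A_LT_B if a < b else A_GT_B), 1.0)
        ]
        sig, trace = forward_stepwise_select(cand, matrix, clinical["grade"])
        assert len(sig) == 1 and trace[-1].f_score == 1.0

    def test_trace_nondecreasing_and_final_f_at_most_exhaustive(self):
        rng = np.random.default_rng(17)
        candidates, matrix, labels = _noisy_candidates(rng, 5, 20, flip_rate=0.25)
        sig, trace = forward_stepwise_select(candidates, matrix, labels)
        scores = [t.f_score for t in trace]
        assert scores == sorted(scores)
        best = exhaustive_best_f(candidates, matrix, labels)
        assert scores[-1] <= best + 1e-12

    def test_equals_exhaustive_on_separable_cohort(self, small_cohort):
        matrix, clinical, truth = small_cohort
        candidates = []
        for a, b in truth.planted_pairs[:4]:
            ca, cb = sorted((a, b))
            d1 = A_GT_B if (ca, cb) == (a, b) else A_LT_B
            d3 = A_LT_B if d1 == A_GT_B else A_GT_B
            candidates.append(
                ReversalPair(ca, cb, d1, d3, _reo(ca, cb, d1), _reo(ca, cb, d3), 1.0)
            )
        sig, trace = forward_stepwise_select(candidates, matrix, clinical["grade"])
        assert trace[-1].f_score == exhaustive_best_f(candidates, matrix, clinical["grade"]) == 1.0

    def test_deterministic_rerun_identical(self):
        rng = np.random.default_rng(23)
        candidates, matrix, labels = _noisy_candidates(rng, 6, 15, flip_rate=0.3)
        out1 = forward_stepwise_select(candidates, matrix, labels)
        out2 = forward_stepwise_select(candidates, matrix, labels)
        assert out1[0].pairs == out2[0].pairs
        assert out1[1] == out2[1]

    def test_tie_broken_by_lexicographic_order(self):
        # two identical perfect pairs: identical incremental F, equal margin
        vals = np.array([[5.0, 1.0], [1.0, 5.0], [5.0, 1.0], [1.0, 5.0]])
        matrix = make_matrix(vals, gene_ids=["a1", "a2", "b1", "b2"], sample_ids=["x", "y"])
        labels = {"x": "pHG1", "y": "pHG3"}
        cands = [
            ReversalPair("b1", "b2", A_GT_B, A_LT_B, _reo("b1", "b2", A_GT_B),
                         _reo("b1", "b2", A_LT_B), 1.0),
            ReversalPair("a1", "a2", A_GT_B, A_LT_B, _reo("a1", "a2", A_GT_B),
                         _reo("a1", "a2", A_LT_B), 1.0),
        ]
        sig, _ = forward_stepwise_select(cands, matrix, labels)
        assert sig.pairs[0] == ("a1", "a2")

    def test_requires_both_classes(self, small_cohort):
        matrix, clinical, _ = small_cohort
        labels = pd.Series("pHG1", index=matrix.sample_ids)
        with pytest.raises(ValueError):
            forward_stepwise_select(
                [ReversalPair("g01", "g02", A_GT_B, A_LT_B,
                              _reo("g01", "g02", A_GT_B), _reo("g01", "g02", A_LT_B), 1.0)],
                matrix, labels,
            )
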