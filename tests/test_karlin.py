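import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plasmidshot.seqio import random_plasmid, reverse_complement
from plasmidshot.karlin import (
    KarlinParams,
    MSP,
    NoPositiveRootError,
    ScoringScheme,
    dot_matrix,
    estimate_K,
    estimate_lambda,
    find_msp,
    karlin_evalue,
)


def brute_msp(a, b, match, mismatch):
    """Exhaustive all-segment-pairs oracle with the library's tie-break
    (score, smaller a_start, smaller b_start, forward orientation)."""
    best = None
    for orient, bb in (("+", b), ("-", reverse_complement(b))):
        for i in range(len(a)):
            for j in range(len(bb)):
                score = 0
                for k in range(min(len(a) - i, len(bb) - j)):
                    score += match if a[i + k] == bb[j + k] else mismatch
                    b_start = j if orient == "+" else len(b) - j - (k + 1)
                    cand = (score, -i, -b_start, orient == "+", k + 1, orient)
                    if best is None or cand[:4] > best[:4]:
                        best = cand
    return MSP(score=best[0], length=best[4], a_start=-best[1], b_start=-best[2], orientation=best[5])


class TestEstimateLambda:
    def test_plus5_minus4_uniform_rounds_to_019(self):
        lam = estimate_lambda(ScoringScheme(5, -4))
        assert round(lam, 2) == 0.19

    def test_plus1_minus1_closed_form_ln3(self):
        lam = estimate_lambda(ScoringScheme(1, -1))
        assert lam == pytest.approx(math.log(3), abs=1e-9)

    def test_normalization_residual_below_tolerance(self):
        scheme = ScoringScheme(5, -4, composition=(0.3, 0.2, 0.28, 0.22))
        lam = estimate_lambda(scheme)
        q = scheme.p_match
        residual = q * math.exp(lam * 5) + (1 - q) * math.exp(-lam * 4) - 1.0
        assert abs(residual) <= 1e-9

    def test_invariant_under_base_relabeling(self):
        comp = (0.4, 0.1, 0.3, 0.2)
        lams = {
            estimate_lambda(ScoringScheme(5, -4, composition=perm))
            for perm in [(0.4, 0.1, 0.3, 0.2), (0.1, 0.3, 0.2, 0.4), (0.2, 0.4, 0.1, 0.3)]
        }
        assert max(lams) - min(lams) < 1e-12

    def test_positive_expected_score_has_no_root(self):
        with pytest.raises(NoPositiveRootError):
            estimate_lambda(ScoringScheme(1, 1))

    def test_no_positive_score_has_no_root(self):
        with pytest.raises(NoPositiveRootError):
            estimate_lambda(ScoringScheme(-1, -2))


class TestEstimateK:
    def test_plus5_minus4_matches_classical_value(self):
        scheme = ScoringScheme(5, -4)
        K = estimate_K(scheme, estimate_lambda(scheme))
        assert 0.15 <= K <= 0.20

    @pytest.mark.parametrize("match,mismatch", [(1, -1), (5, -4), (2, -3), (1, -2)])
    def test_K_positive_and_below_one(self, match, mismatch):
        scheme = ScoringScheme(match, mismatch)
        K = estimate_K(scheme, estimate_lambda(scheme))
        assert 0.0 < K < 1.0

    def test_plus1_minus1_matches_random_walk_simulation(self):
        # Monte-Carlo oracle: per-step rate of Smith-Waterman-style
        # excursions whose peak reaches S is K*exp(-lambda*S)
        scheme = ScoringScheme(1, -1)
        lam = estimate_lambda(scheme)
        K = estimate_K(scheme, lam)
        S, n_walks, walk_len = 8, 1_000_000, 120
        rng = np.random.default_rng(20240917)
        W = np.zeros(n_walks)
        hits = np.zeros(n_walks, dtype=np.int64)
        counted = np.zeros(n_walks, dtype=bool)
        for _ in range(walk_len):
            W += np.where(rng.random(n_walks) < scheme.p_match, 1, -1)
            reset = W <= 0
            W[reset] = 0.0
            newly = (W >= S) & ~counted
            hits[newly] += 1
            counted[newly] = True
            counted[reset] = False
        rate = hits.sum() / (n_walks * walk_len)
        K_mc = rate / math.exp(-lam * S)
        assert K == pytest.approx(K_mc, rel=0.10)


class TestFindMsp:
    def test_identical_sequences(self):
        seq = random_plasmid(40, 0.5, seed=2).sequence
        msp = find_msp(seq, seq, ScoringScheme(5, -4))
        assert msp.score == 5 * 40 and msp.length == 40
        assert msp.a_start == 0 and msp.b_start == 0 and msp.orientation == "+"

    def test_half_matching_pair(self):
        msp = find_msp("AAAATTTT", "AAAACCCC", ScoringScheme(1, -1))
        assert msp.score == 4 and msp.length == 4

    def test_planted_shared_segment_is_found(self):
        rng = np.random.default_rng(3)
        planted = "".join(rng.choice(list("ACGT"), 30))
        a = "".join(rng.choice(list("ACGT"), 100)) + planted + "".join(rng.choice(list("ACGT"), 50))
        b = "".join(rng.choice(list("ACGT"), 40)) + planted + "".join(rng.choice(list("ACGT"), 80))
        msp = find_msp(a, b, ScoringScheme(5, -4))
        assert msp.score >= 150

    def test_reverse_orientation_reported_on_forward_coordinates(self):
        seq = random_plasmid(60, 0.5, seed=4).sequence
        msp = find_msp(seq, reverse_complement(seq), ScoringScheme(5, -4))
        assert msp.orientation == "-"
        assert msp.score == 5 * 60 and msp.a_start == 0 and msp.b_start == 0

    @given(
        st.text(alphabet="ACGT", min_size=2, max_size=30),
        st.text(alphabet="ACGT", min_size=2, max_size=30),
    )
    def test_agrees_with_exhaustive_oracle(self, a, b):
        scheme = ScoringScheme(5, -4)
        got = find_msp(a, b, scheme)
        expected = brute_msp(a, b, 5, -4)
        assert (got.score, got.length, got.a_start, got.b_start, got.orientation) == (
            expected.score,
            expected.length,
            expected.a_start,
            expected.b_start,
            expected.orientation,
        )

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            find_msp("", "ACGT")


class TestKarlinEvalue:
    def test_printed_formula_on_reference_statistics(self):
        # K=0.17, lambda=0.19, m=213, n=1, S=39.03
        E = karlin_evalue(KarlinParams(lambda_=0.19, K=0.17), m=213, n=1, S=39.03)
        assert E == pytest.approx(2.18e-2, rel=1e-3)

    def test_monotone_decreasing_in_score(self):
        params = KarlinParams(lambda_=0.19, K=0.17)
        values = [karlin_evalue(params, 100, 1, S) for S in (0, 10, 20, 40, 80)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] > 0

    def test_linear_in_search_space(self):
        params = KarlinParams(lambda_=0.5, K=0.2)
        base = karlin_evalue(params, 100, 1, 10)
        assert karlin_evalue(params, 200, 1, 10) == pytest.approx(2 * base)
        assert karlin_evalue(params, 100, 3, 10) == pytest.approx(3 * base)

    def test_zero_K_gives_zero(self):
        assert karlin_evalue(KarlinParams(lambda_=0.19, K=0.0), 10, 1, 5.0) == 0.0

    def test_domain_errors(self):
        params = KarlinParams(lambda_=0.19, K=0.17)
        with pytest.raises(ValueError):
            karlin_evalue(params, 0, 1, 1.0)
        with pytest.raises(ValueError):
            karlin_evalue(params, 1, 0, 1.0)


class TestDotMatrix:
    def test_self_comparison_marks_main_diagonal(self):
        seq = random_plasmid(120, 0.5, seed=6).sequence
        plot = dot_matrix(seq, seq, window=25, cutoff=25 * 5)
        forward = [(i, j) for i, j, s in plot.hits if s == "+"]
        assert [(i, i) for i in range(120 - 25 + 1)] == sorted(forward)

    def test_self_hit_set_is_symmetric(self):
        seq = random_plasmid(150, 0.5, seed=7).sequence
        plot = dot_matrix(seq, seq, window=15, cutoff=40)
        forward = {(i, j) for i, j, s in plot.hits if s == "+"}
        assert forward == {(j, i) for i, j in forward}

    def test_reverse_complement_gives_negative_slope_line(self):
        seq = random_plasmid(100, 0.5, seed=8).sequence
        plot = dot_matrix(seq, reverse_complement(seq), window=25, cutoff=25 * 5)
        reverse = [(i, j) for i, j, s in plot.hits if s == "-"]
        assert len(reverse) == 100 - 25 + 1
        assert all(j == 100 - i - 25 for i, j in reverse)

    def test_independent_random_sequences_give_no_hits(self):
        a = random_plasmid(1000, 0.5, seed=9).sequence
        b = random_plasmid(1000, 0.5, seed=10).sequence
        plot = dot_matrix(a, b, window=25, cutoff=25 * 5)
        assert plot.n_dots == 0

    def test_window_longer_than_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            dot_matrix("ACGT", "ACGTACGT", window=5)


def test_scoring_scheme_composition_estimation():
    scheme = ScoringScheme.from_sequences("GGCC", "GGGG")
    assert scheme.composition == pytest.approx((0.0, 0.25, 0.75, 0.0))
    assert ScoringScheme.from_sequences("").composition == (0.25, 0.25, 0.25, 0.25)
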