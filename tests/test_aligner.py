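"""Seed-and-extend engine: correctness against brute-force oracles,

e-value arithmetic, strand handling and the low-complexity filter.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transposcan.aligner import (AlignmentConfig, SubjectIndex, evalue,
                                 is_low_complexity, local_align,
                                 min_repeat_score, reverse_complement)

from conftest import random_seq


def longest_common_substring(a: str, b: str):
    """Brute-force diagonal-scan oracle: (length, a_start, b_start)."""
    best = (0, 0, 0)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for d in range(-(len(b) - 1), len(a)):
        ai = max(0, d)
        bi = ai - d
        n = min(len(a) - ai, len(b) - bi)
        eq = aa[ai : ai + n] == bb[bi : bi + n]
        run = 0
        for k in range(n):
            run = run + 1 if eq[k] else 0
            if run > best[0]:
                best = (run, ai + k - run + 1, bi + k - run + 1)
    return best


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_basic(self):
        assert reverse_complement("AAAC") == "GTTT"

    def test_rejects_bad_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_involution(self, seed):
        s = random_seq(np.random.default_rng(seed), 500)
        assert reverse_complement(reverse_complement(s)) == s


class TestEvalue:
    def test_score_zero_closed_form(self):
        cfg = AlignmentConfig()
        assert evalue(0, 100, 200, cfg) == pytest.approx(cfg.karlin_k * 100 * 200)

    def test_linear_in_search_space(self):
        cfg = AlignmentConfig()
        assert evalue(10, 2000, 500, cfg) == pytest.approx(2 * evalue(10, 1000, 500, cfg))

    def test_strictly_decreasing_in_score(self):
        cfg = AlignmentConfig()
        vals = [evalue(s, 1000, 1000, cfg) for s in range(0, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_min_repeat_score_identity_scoring(self):
        assert min_repeat_score(AlignmentConfig(match=1), 500, 500) == 15

    def test_min_repeat_score_scales_with_match(self):
        cfg = AlignmentConfig(match=2, mismatch=-3)
        assert min_repeat_score(cfg, 500, 500) == 30

    def test_near_match_scores_below_threshold(self):
        # a 14/15 hit under +1/-3 scores 14 - 3 = 11 < 15
        cfg = AlignmentConfig()
        score = 14 * cfg.match + 1 * cfg.mismatch
        assert score < min_repeat_score(cfg, 500, 500)


class TestLowComplexity:
    @pytest.mark.parametrize("seq", ["A" * 50, "AT" * 25, "ACG" * 17])
    def test_short_period_repeats(self, seq):
        assert is_low_complexity(seq)

    def test_random_sequence_passes(self):
        assert not is_low_complexity(random_seq(np.random.default_rng(11), 50))

    def test_long_random_sequence_passes(self):
        assert not is_low_complexity(random_seq(np.random.default_rng(12), 5000))


class TestLocalAlign:
    def test_self_alignment_full_cover(self):
        s = random_seq(np.random.default_rng(0), 100)
        hsps = local_align(s, s)
        top = hsps[0]
        assert (top.q_start, top.q_end, top.s_start, top.s_end) == (0, 100, 0, 100)
        assert top.identity == 1.0 and top.orientation == "forward"

    def test_reverse_complement_subject(self):
        s = random_seq(np.random.default_rng(1), 120)
        top = local_align(s, reverse_complement(s))[0]
        assert top.orientation == "reverse"
        assert top.identity == 1.0
        assert (top.q_start, top.q_end) == (0, 120)
        assert (top.s_start, top.s_end) == (0, 120)  # forward-strand coords

    def test_planted_substring_matches_oracle(self):
        rng = np.random.default_rng(42)
        common = random_seq(rng, 30)
        a = random_seq(rng, 500) + common + random_seq(rng, 470)
        b = random_seq(rng, 200) + common + random_seq(rng, 770)
        length, a0, b0 = longest_common_substring(a, b)
        assert length >= 30
        top = local_align(a, b)[0]
        assert top.q_start <= a0 and top.q_end >= a0 + length
        assert top.s_start <= b0 and top.s_end >= b0 + length

    @pytest.mark.parametrize("seed,length", [(0, 15), (1, 22), (2, 40), (3, 120)])
    def test_planted_exact_match_covered(self, seed, length):
        """Any planted exact common substring of length >= word+8 is found

        and covered at >= 90% by some HSP.
        """
        rng = np.random.default_rng(seed)
        cfg = AlignmentConfig()
        common = random_seq(rng, length)
        if is_low_complexity(common):
            common = random_seq(rng, length)
        q = random_seq(rng, 300) + common + random_seq(rng, 300)
        s = random_seq(rng, 900) + common + random_seq(rng, 100)
        hsps = local_align(q, s, cfg)
        cover = 0
        for h in hsps:
            if h.orientation != "forward":
                continue
            cover = max(cover, min(h.q_end, 300 + length) - max(h.q_start, 300))
        assert cover >= 0.9 * length

    def test_all_hsps_within_evalue_cutoff(self):
        rng = np.random.default_rng(9)
        q = random_seq(rng, 800)
        s = q[:400] + random_seq(rng, 400)
        cfg = AlignmentConfig(evalue_cutoff=0.1)
        for h in local_align(q, s, cfg):
            assert h.evalue <= cfg.evalue_cutoff

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        q = random_seq(rng, 1500)
        s = random_seq(rng, 5000) + q[200:900] + random_seq(rng, 2000)
        r1 = local_align(q, s)
        r2 = local_align(q, s)
        assert [(h.q_start, h.q_end, h.s_start, h.s_end, h.score) for h in r1] == \
            [(h.q_start, h.q_end, h.s_start, h.s_end, h.score) for h in r2]

    def test_subject_index_reuse_equivalent(self):
        rng = np.random.default_rng(6)
        s = random_seq(rng, 3000)
        q = s[1000:1400]
        idx = SubjectIndex(s, 7)
        direct = local_align(q, s)
        via_index = local_align(q, idx)
        assert [(h.q_start, h.s_start, h.score) for h in direct] == \
            [(h.q_start, h.s_start, h.score) for h in via_index]

    def test_no_extension_through_long_n_run(self):
        rng = np.random.default_rng(7)
        left = random_seq(rng, 60)
        right = random_seq(rng, 60)
        q = left + right
        s = left + "N" * 30 + right
        for h in local_align(q, s):
            # no single HSP may bridge the 30 bp N run
            assert not (h.s_start < 55 and h.s_end > 95)

    def test_identity_times_length_integral(self):
        rng = np.random.default_rng(8)
        q = random_seq(rng, 600)
        s_list = list(q)
        for i in rng.choice(600, 30, replace=False):
            s_list[i] = "ACGT"[(("ACGT".index(s_list[i])) + 1) % 4]
        for h in local_align(q, "".join(s_list)):
            assert abs(h.identity * h.length - round(h.identity * h.length)) < 1e-9
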