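"""Dissolve, integer-position matching and the candidate filter cascade."""

import numpy as np
import pytest

from transposcan.aligner import HSP, AlignmentConfig, GenomeIndex
from transposcan.detector import (STATUS_CANDIDATE, STATUS_INTERRUPTER,
                                  STATUS_NONORTHOLOGOUS, STATUS_PSEUDO_TE,
                                  STATUS_RESIDUAL, TranspositionCandidate,
                                  apply_filters, best_pairs, dissolve,
                                  flanking_gene_scan, missing_between,
                                  pair_genes)
from transposcan.genome_io import OrthologousRegion

from conftest import build_genome, random_seq


def _hsp(qs, qe, ev=1e-20):
    return HSP("q", "s", qs, qe, qs, qe, "forward", qe - qs, 1.0, qe - qs, ev)


class TestDissolve:
    def test_disjoint_hits_sum(self):
        pairs = dissolve({("a", "b"): [_hsp(0, 50), _hsp(60, 110)]})
        assert pairs[0].merged_length == 100

    def test_overlap_merged_before_summing(self):
        # two 48 bp hits overlapping by 10 on the query: union is 86, dropped
        pairs = dissolve({("a", "b"): [_hsp(0, 48), _hsp(38, 86)]})
        assert pairs == []

    def test_boundary_96_retained_95_dropped(self):
        assert dissolve({("a", "b"): [_hsp(0, 96)]})[0].merged_length == 96
        assert dissolve({("a", "b"): [_hsp(0, 95)]}) == []

    def test_monotone_in_min_sum(self):
        rng = np.random.default_rng(0)
        hsps = {}
        for i in range(30):
            qs = int(rng.integers(0, 500))
            hsps.setdefault((f"q{i % 7}", f"s{i % 5}"), []).append(
                _hsp(qs, qs + int(rng.integers(10, 200))))
        prev = None
        for min_sum in (50, 96, 150, 300):
            kept = {(p.q_gene, p.s_gene) for p in dissolve(hsps, min_sum=min_sum)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_best_pairs_tie_breaking(self):
        hsps = {("q", "s2"): [_hsp(0, 100, ev=1e-10)],
                ("q", "s1"): [_hsp(0, 100, ev=1e-10)],
                ("q", "s3"): [_hsp(0, 100, ev=1e-5)]}
        assert best_pairs(dissolve(hsps)) == {"q": "s1"}


class TestMissingBetween:
    def test_methods_worked_example(self):
        assert missing_between([(1, 123), (2, 125)]) == [("subject", 124)]

    def test_missing_query_position(self):
        assert missing_between([(1, 123), (3, 124)]) == [("query", 2)]

    def test_two_consecutive_missing(self):
        assert missing_between([(1, 123), (4, 124)]) == [("query", 2), ("query", 3)]

    def test_no_gaps_no_calls(self):
        assert missing_between([(1, 10), (2, 11), (3, 12)]) == []

    def test_descending_subject_order(self):
        assert missing_between([(1, 125), (2, 123)]) == [("subject", 124)]


def _toy_pair(missing_in_b=("q4",), n=7, seed=0):
    """Two genomes with the same 7 genes; ``missing_in_b`` deleted from B."""
    rng = np.random.default_rng(seed)
    specs = [{"id": f"q{i}", "seq": random_seq(rng, 600),
              "exons": ((0, 250), (350, 600))} for i in range(1, n + 1)]
    genome_a, annot_a = build_genome(specs, seed=1)
    specs_b = [dict(s, id=s["id"].replace("q", "s")) for s in specs
               if s["id"] not in missing_in_b]
    genome_b, annot_b = build_genome(specs_b, seed=2, genome_id="B")
    return genome_a, annot_a, genome_b, annot_b


class TestFlankingGeneScan:
    def test_single_missing_gene_reported_with_flankers(self):
        ga, aa, gb, ab = _toy_pair(missing_in_b=("q4",))
        pairs = pair_genes(ga, aa, ab, GenomeIndex(gb))
        cands = flanking_gene_scan(pairs, aa, ab)
        assert [c.gene_id for c in cands] == ["q4"]
        c = cands[0]
        assert (c.flanker_q1, c.flanker_q2) == ("q3", "q5")
        assert (c.flanker_s1, c.flanker_s2) == ("s3", "s5")

    def test_identical_annotations_no_candidates(self):
        ga, aa, gb, ab = _toy_pair(missing_in_b=())
        pairs = pair_genes(ga, aa, ab, GenomeIndex(gb))
        assert flanking_gene_scan(pairs, aa, ab) == []

    def test_two_consecutive_missing_share_flankers(self):
        ga, aa, gb, ab = _toy_pair(missing_in_b=("q4", "q5"))
        pairs = pair_genes(ga, aa, ab, GenomeIndex(gb))
        cands = flanking_gene_scan(pairs, aa, ab)
        assert sorted(c.gene_id for c in cands) == ["q4", "q5"]
        assert all((c.flanker_q1, c.flanker_q2) == ("q3", "q6") for c in cands)


class TestApplyFilters:
    def _setup(self, cand_class="gene", plant_residual=False, seed=3):
        rng = np.random.default_rng(seed)
        gene_seq = random_seq(rng, 600)
        specs_a = [
            {"id": "q1", "seq": random_seq(rng, 600), "exons": ((0, 600),)},
            {"id": "q2", "seq": gene_seq, "exons": ((0, 250), (350, 600)),
             "feature_class": cand_class},
            {"id": "q3", "seq": random_seq(rng, 600), "exons": ((0, 600),)},
        ]
        gap = random_seq(rng, 500)
        if plant_residual:
            gap = gap[:200] + gene_seq[300:340] + gap[240:]
        specs_b = [dict(specs_a[0], id="s1", spacer_after=gap),
                   dict(specs_a[2], id="s3")]
        ga, aa = build_genome(specs_a, seed=4)
        gb, ab = build_genome(specs_b, seed=5, genome_id="B")
        cand = TranspositionCandidate(
            gene_id="q2", chromosome="chr1", start=aa["q2"].start,
            end=aa["q2"].end, flanker_q1="q1", flanker_q2="q3",
            flanker_s1="s1", flanker_s2="s3")
        regions = [OrthologousRegion("r1", "chr1", 0, ga.length("chr1"),
                                     "chr1", 0, gb.length("chr1"))]
        return cand, ga, aa, gb, ab, regions

    def test_clean_candidate_retained(self):
        cand, ga, aa, gb, ab, regions = self._setup()
        assert apply_filters(cand, ga, aa, gb, ab, regions).status == STATUS_CANDIDATE

    def test_outside_orthologous_regions_discarded(self):
        cand, ga, aa, gb, ab, _ = self._setup()
        small = [OrthologousRegion("r1", "chr1", 0, 10, "chr1", 0, 10)]
        assert apply_filters(cand, ga, aa, gb, ab, small).status == \
            STATUS_NONORTHOLOGOUS

    @pytest.mark.parametrize("cls", ["pseudogene", "transposable_element"])
    def test_pseudogene_or_te_discarded(self, cls):
        cand, ga, aa, gb, ab, regions = self._setup(cand_class=cls)
        assert apply_filters(cand, ga, aa, gb, ab, regions).status == STATUS_PSEUDO_TE

    def test_residual_hit_discarded(self):
        # 40 bp of the candidate's intron sequence planted in the B gap
        cand, ga, aa, gb, ab, regions = self._setup(plant_residual=True)
        out = apply_filters(cand, ga, aa, gb, ab, regions)
        assert out.status == STATUS_RESIDUAL
        assert out.residual_hit_len >= 15

    def test_identical_subject_flankers_interrupter(self):
        cand, ga, aa, gb, ab, regions = self._setup()
        cand.flanker_s2 = cand.flanker_s1
        assert apply_filters(cand, ga, aa, gb, ab, regions).status == \
            STATUS_INTERRUPTER

    def test_every_candidate_gets_exactly_one_terminal_status(self):
        for kwargs in ({}, {"cand_class": "pseudogene"}, {"plant_residual": True}):
            cand, ga, aa, gb, ab, regions = self._setup(**kwargs)
            out = apply_filters(cand, ga, aa, gb, ab, regions)
            assert out.status in {STATUS_CANDIDATE, STATUS_INTERRUPTER,
                                  STATUS_NONORTHOLOGOUS, STATUS_RESIDUAL,
                                  STATUS_PSEUDO_TE}
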