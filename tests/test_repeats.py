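"""Flanking-repeat discovery, context classification and the genome scan."""

import numpy as np
import pytest

from transposcan.aligner import GenomeIndex, reverse_complement
from transposcan.genome_io import AnnotationSet, GeneFeature, GenomeSequence
from transposcan.repeats import (RepeatPair, classify_repeat_context,
                                 find_flanking_repeats,
                                 repeat_sequence_identity_annotation,
                                 scan_genome_repeats)

from conftest import mismatch_everywhere, random_seq


def _flanked_gene(rng, rep_up, rep_down, up_offset=120, down_offset=150,
                  gene_len=600, flank=500):
    """Genome with one gene whose windows carry the given repeat copies.

    ``up_offset``: distance from the upstream copy's end to the gene start;
    ``down_offset``: distance from gene end to the downstream copy's start.
    """
    up_pad = flank - up_offset - len(rep_up)
    up_window = random_seq(rng, up_pad) + rep_up + random_seq(rng, up_offset)
    down_window = random_seq(rng, down_offset) + rep_down + \
        random_seq(rng, flank - down_offset - len(rep_down))
    gene_seq = random_seq(rng, gene_len)
    chrom = random_seq(rng, 50) + up_window + gene_seq + down_window + \
        random_seq(rng, 50)
    start = 50 + flank
    genome = GenomeSequence("T", {"chr1": chrom})
    gene = GeneFeature("t1", "chr1", start, start + gene_len,
                       exons=((start, start + gene_len),))
    annot = AnnotationSet("T", [gene], genome=genome)
    return genome, annot, gene


class TestFindFlankingRepeats:
    def test_planted_direct_repeat_found(self):
        rng = np.random.default_rng(0)
        rep = random_seq(rng, 40)
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        pairs = find_flanking_repeats(gene, genome)
        assert pairs and pairs[0].orientation == "direct"
        top = pairs[0]
        assert top.repeat_length >= 40
        # reported intervals must contain the planted copies
        chrom = genome.chromosomes["chr1"]
        assert rep in chrom[top.up_start : top.up_end]
        assert rep in chrom[top.down_start : top.down_end]

    def test_planted_inverted_repeat_found(self):
        rng = np.random.default_rng(1)
        rep = random_seq(rng, 40)
        genome, annot, gene = _flanked_gene(rng, rep, reverse_complement(rep))
        pairs = find_flanking_repeats(gene, genome)
        assert pairs and pairs[0].orientation == "inverted"
        assert pairs[0].repeat_length >= 40

    def test_simple_sequence_plant_rejected(self):
        rng = np.random.default_rng(2)
        rep = "AT" * 20
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        assert find_flanking_repeats(gene, genome) == []

    def test_window_intervals_respect_gene_bounds(self):
        rng = np.random.default_rng(3)
        rep = random_seq(rng, 60)
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        for p in find_flanking_repeats(gene, genome):
            assert p.up_end <= gene.start
            assert p.down_start >= gene.end

    def test_length_classes_strict(self):
        p = RepeatPair("g", 0, 15, 100, 115, 15, 1.0, "direct")
        assert not p.exceeds_15 and not p.exceeds_30
        p = RepeatPair("g", 0, 16, 100, 116, 16, 1.0, "direct")
        assert p.exceeds_15 and not p.exceeds_30
        p = RepeatPair("g", 0, 31, 100, 131, 31, 1.0, "direct")
        assert p.exceeds_15 and p.exceeds_30

    def test_higher_threshold_never_adds_pairs(self):
        rng = np.random.default_rng(4)
        rep = random_seq(rng, 25)
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        from transposcan.aligner import AlignmentConfig
        base = find_flanking_repeats(gene, genome)
        # doubling the match reward doubles the 15/15-equivalent floor too;
        # rescoring never reports more pairs than the default
        stricter = find_flanking_repeats(
            gene, genome, config=AlignmentConfig(match=2, mismatch=-6,
                                                 gap_open=-10, gap_extend=-4,
                                                 karlin_lambda=0.687))
        assert len(stricter) <= len(base)


class TestScanBoundaries:
    def _scan_genome(self, rep_len, seed=0):
        """Planted exact repeat whose context mismatches everywhere, so the

        aligned length equals the planted length exactly.
        """
        rng = np.random.default_rng(seed)
        rep = random_seq(rng, rep_len)
        pos = 1200 - rep_len
        up_window = random_seq(rng, pos) + rep + random_seq(rng, 2000 - pos - rep_len)
        # same offset in both windows: every context column mismatches on the
        # repeat's diagonal, so the aligned length is exactly the planted one
        down_window = mismatch_everywhere(up_window[:pos]) + rep + \
            mismatch_everywhere(up_window[pos + rep_len :])
        gene_seq = random_seq(rng, 500)
        chrom = up_window + gene_seq + down_window
        genome = GenomeSequence("S", {"chr1": chrom})
        gene = GeneFeature("g1", "chr1", 2000, 2500, exons=((2000, 2500),))
        annot = AnnotationSet("S", [gene], genome=genome)
        return scan_genome_repeats(genome, annot)

    def test_length_30_reported(self):
        df = self._scan_genome(30)
        assert bool(df.iloc[0]["has_flanking_repeat"])
        assert df.iloc[0]["best_repeat_length"] == 30

    def test_length_29_not_reported(self):
        df = self._scan_genome(29)
        assert not bool(df.iloc[0]["has_flanking_repeat"])

    def test_length_above_400_not_reported(self):
        df = self._scan_genome(450)
        assert not bool(df.iloc[0]["has_flanking_repeat"])

    def test_scan_flags_only_the_repeat_bearing_gene(self):
        rng = np.random.default_rng(9)
        rep = random_seq(rng, 60)
        g1 = random_seq(rng, 500)
        g2 = random_seq(rng, 500)
        chrom = (random_seq(rng, 2000) + g1 + random_seq(rng, 2500)
                 + rep + random_seq(rng, 500) + g2
                 + random_seq(rng, 700) + rep + random_seq(rng, 1300))
        genome = GenomeSequence("S", {"chr1": chrom})
        s2 = chrom.index(g2)
        annot = AnnotationSet("S", [
            GeneFeature("plain", "chr1", 2000, 2500, exons=((2000, 2500),)),
            GeneFeature("flanked", "chr1", s2, s2 + 500, exons=((s2, s2 + 500),)),
        ], genome=genome)
        df = scan_genome_repeats(genome, annot).set_index("gene_id")
        assert bool(df.loc["flanked", "has_flanking_repeat"])
        assert not bool(df.loc["plain", "has_flanking_repeat"])


class TestContextClassification:
    def _pair_for(self, genome, gene, rep_len):
        pairs = find_flanking_repeats(gene, genome)
        assert pairs
        return pairs[0]

    def test_carryover_present_at_parent_only(self):
        rng = np.random.default_rng(10)
        rep = random_seq(rng, 60)
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        parent_window = random_seq(rng, 400) + rep + random_seq(rng, 400)
        ga = GenomeSequence("A", {"chr1": genome.chromosomes["chr1"],
                                  "chr9": parent_window})
        gb = GenomeSequence("B", {"chr1": random_seq(rng, 3000)})
        pair = self._pair_for(ga, gene, 60)
        out = classify_repeat_context(pair, ga, "chr1",
                                      ("chr9", 400, 460), gb, ("chr1", 500, 2500))
        assert out.present_at_parent is True
        assert out.present_at_ortholog_target is False
        assert out.chimeric_with_target is False

    def test_target_homology_present_at_target_only(self):
        rng = np.random.default_rng(11)
        rep = random_seq(rng, 60)
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        gb = GenomeSequence("B", {"chr1": random_seq(rng, 1000) + rep
                                  + random_seq(rng, 1000)})
        pair = self._pair_for(genome, gene, 60)
        out = classify_repeat_context(pair, genome, "chr1", None, gb,
                                      ("chr1", 900, 1200))
        assert out.present_at_parent is None
        assert out.present_at_ortholog_target is True

    def test_de_novo_absent_everywhere(self):
        rng = np.random.default_rng(12)
        rep = random_seq(rng, 60)
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        ga = GenomeSequence("A", {"chr1": genome.chromosomes["chr1"],
                                  "chr9": random_seq(rng, 1200)})
        gb = GenomeSequence("B", {"chr1": random_seq(rng, 3000)})
        pair = self._pair_for(ga, gene, 60)
        out = classify_repeat_context(pair, ga, "chr1", ("chr9", 400, 800),
                                      gb, ("chr1", 500, 2500))
        assert out.present_at_parent is False
        assert out.present_at_ortholog_target is False

    def test_chimera_between_donor_and_target(self):
        rng = np.random.default_rng(13)
        left, right = random_seq(rng, 40), random_seq(rng, 40)
        rep = left + right
        genome, annot, gene = _flanked_gene(rng, rep, rep)
        ga = GenomeSequence("A", {"chr1": genome.chromosomes["chr1"],
                                  "chr9": random_seq(rng, 300) + left
                                  + random_seq(rng, 300)})
        gb = GenomeSequence("B", {"chr1": random_seq(rng, 800) + right
                                  + random_seq(rng, 800)})
        pair = self._pair_for(ga, gene, 80)
        out = classify_repeat_context(pair, ga, "chr1", ("chr9", 280, 360),
                                      gb, ("chr1", 700, 950))
        assert out.present_at_parent is True
        assert out.present_at_ortholog_target is True
        assert out.chimeric_with_target is True


class TestIdentityAnnotation:
    def _setup(self, rep_source: str, seed=20):
        """Genome: [geneX][TE][transposed gene flanked by repeat copies]."""
        rng = np.random.default_rng(seed)
        gene_x = random_seq(rng, 600)
        te = random_seq(rng, 400)
        if rep_source == "genic":
            rep = gene_x[100:160]
        elif rep_source == "transposon":
            rep = te[50:110]
        else:
            rep = random_seq(rng, 60)
        t_seq = random_seq(rng, 500)
        if rep_source == "within_transposed":
            rep = t_seq[200:260]
        chrom = (random_seq(rng, 300) + gene_x + random_seq(rng, 400) + te
                 + random_seq(rng, 400) + rep + random_seq(rng, 120)
                 + t_seq + random_seq(rng, 150) + rep + random_seq(rng, 300))
        genome = GenomeSequence("A", {"chr1": chrom})
        t_start = chrom.index(t_seq)
        feats = [
            GeneFeature("gx", "chr1", 300, 900, exons=((300, 900),)),
            GeneFeature("te1", "chr1", 1300, 1700,
                        feature_class="transposable_element"),
            GeneFeature("t1", "chr1", t_start, t_start + 500,
                        exons=((t_start, t_start + 500),)),
        ]
        annot = AnnotationSet("A", feats, genome=genome)
        gene = annot["t1"]
        pairs = find_flanking_repeats(gene, genome)
        assert pairs
        return pairs[0], genome, annot, gene

    @pytest.mark.parametrize("source,expected", [
        ("genic", "genic:gx"),
        ("transposon", "transposon"),
        ("intergenic", "intergenic"),
        ("within_transposed", "within_transposed_sequence"),
    ])
    def test_labels(self, source, expected):
        pair, genome, annot, gene = self._setup(source)
        label = repeat_sequence_identity_annotation(
            pair, genome, "chr1", annot, GenomeIndex(genome), gene)
        assert label == expected
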