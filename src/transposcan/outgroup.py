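"""Outgroup-based confirmation: insertion in genome A vs loss in genome B.

Each candidate's coding sequence is searched in a deeply diverged outgroup
genome; its 15 kb flanks (gene excluded) locate the syntenous outgroup
region.  A gene found only away from that region is in a non-ancestral
position.  A candidate is a confirmed insertion only when both outgroups
independently place it away from the ancestral position.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aligner import AlignmentConfig, GenomeIndex
from .coanno import cluster_hits
from .detector import TranspositionCandidate
from .genome_io import AnnotationSet, GenomeSequence, coding_sequence

OUTGROUP_BUFFER = 15_000

CALL_NO_GENE_HIT = "no_gene_hit"
CALL_GENE_ELSEWHERE = "gene_elsewhere"
CALL_ANCESTRAL = "ancestral_position"
CALL_UNPLACEABLE = "unplaceable"

FINAL_CONFIRMED = "confirmed_insertion"
FINAL_DISCARDED = "discarded"

#: gene-hit loci scoring below this fraction of the best locus are noise
_MIN_RELATIVE_SCORE = 0.33

#: a gene-hit locus must reach this score to count as a hit at all; random
#: chance hits at the relaxed scoring pass the e-value cutoff with scores
#: near the significance floor, while a true homolog at outgroup divergence
#: accumulates score proportional to its coding length
_MIN_GENE_SCORE_FRACTION = 0.05
_MIN_GENE_SCORE_FLOOR = 25


@dataclass
class OutgroupVerdict:
    gene_id: str
    call_outgroup1: str
    call_outgroup2: str
    final: str


def classify_against_outgroup(gene_id: str, genome_a: GenomeSequence,
                              annot_a: AnnotationSet,
                              outgroup_index: GenomeIndex,
                              config: AlignmentConfig | None = None,
                              buffer: int = OUTGROUP_BUFFER) -> str:
    """Position call for one candidate gene against one outgroup genome.

    Searches use a relaxed scoring profile appropriate for the deep
    divergence to the outgroups.  Returns one of ``no_gene_hit``,
    ``ancestral_position``, ``gene_elsewhere`` or ``unplaceable`` (no
    syntenous region located by the flanks; conservatively discarded later).
    """
    config = (config or AlignmentConfig()).relaxed()
    gene = annot_a[gene_id]
    cds = coding_sequence(gene, genome_a)
    if len(cds) < config.word_size:
        return CALL_NO_GENE_HIT
    gene_hits = outgroup_index.align(cds, config, q_id=gene_id)
    min_gene_score = max(_MIN_GENE_SCORE_FLOOR,
                         _MIN_GENE_SCORE_FRACTION * len(cds))
    gene_loci = [c for c in cluster_hits(gene_hits, gap=buffer)
                 if c["score"] >= min_gene_score]
    if not gene_loci:
        return CALL_NO_GENE_HIT
    best_score = gene_loci[0]["score"]
    gene_loci = [c for c in gene_loci if c["score"] >= _MIN_RELATIVE_SCORE * best_score]

    flanks = []
    up = genome_a.fetch(gene.chromosome, gene.start - buffer, gene.start)
    down = genome_a.fetch(gene.chromosome, gene.end, gene.end + buffer)
    for flank in (up, down):
        if len(flank) >= config.word_size:
            flanks.extend(outgroup_index.align(flank, config, q_id=gene_id + ":flank"))
    if not flanks:
        return CALL_UNPLACEABLE
    region = cluster_hits(flanks, gap=buffer)[0]

    def inside(locus: dict) -> bool:
        return (locus["s_id"] == region["s_id"]
                and locus["s_start"] < region["s_end"] + buffer
                and locus["s_end"] > region["s_start"] - buffer)

    if any(inside(locus) for locus in gene_loci):
        return CALL_ANCESTRAL
    return CALL_GENE_ELSEWHERE


def confirm(candidates: list[TranspositionCandidate],
            calls1: dict[str, str], calls2: dict[str, str]) -> list[OutgroupVerdict]:
    """Two-outgroup intersection rule.

    A candidate is a confirmed insertion if and only if both outgroups call
    it ``gene_elsewhere``; every other combination (missing from an
    outgroup, ancestral in an outgroup, or unplaceable) is discarded with
    its reason retained.
    """
    verdicts = []
    for cand in candidates:
        c1 = calls1.get(cand.gene_id, CALL_UNPLACEABLE)
        c2 = calls2.get(cand.gene_id, CALL_UNPLACEABLE)
        final = (FINAL_CONFIRMED
                 if c1 == CALL_GENE_ELSEWHERE and c2 == CALL_GENE_ELSEWHERE
                 else FINAL_DISCARDED)
        verdicts.append(OutgroupVerdict(cand.gene_id, c1, c2, final))
    return verdicts
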