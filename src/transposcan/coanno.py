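"""Co-annotation: project features annotated in one genome onto the other.

A gene annotated in genome A whose sequence is present but unannotated in
genome B becomes a provisional feature in B (and symmetrically), so that
annotation asymmetry does not masquerade as gene movement downstream.
Existing features are never modified; a second pass is a no-op.
"""

from __future__ import annotations

from .aligner import AlignmentConfig, GenomeIndex, HSP
from .genome_io import AnnotationSet, GeneFeature, GenomeSequence

#: a projected feature must be covered to at least this fraction of its source
MIN_COVERAGE = 0.5

#: HSPs within this many bp on the subject are clustered into one hit chain
CLUSTER_GAP = 5000


def cluster_hits(hsps: list[HSP], gap: int = CLUSTER_GAP) -> list[dict]:
    """Group HSPs into per-locus chains (same chromosome and orientation,

    subject-interval gaps below ``gap``).  Each chain records its summed
    score, subject interval and the union of query intervals covered.
    """
    chains: list[dict] = []
    by_key: dict[tuple, list[HSP]] = {}
    for h in hsps:
        by_key.setdefault((h.s_id, h.orientation), []).append(h)
    for (s_id, orientation), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.s_start)
        cur: list[HSP] = []
        for h in group:
            if cur and h.s_start - cur[-1].s_end > gap:
                chains.append(_chain_summary(s_id, orientation, cur))
                cur = []
            cur.append(h)
        if cur:
            chains.append(_chain_summary(s_id, orientation, cur))
    chains.sort(key=lambda c: (-c["score"], c["s_id"], c["s_start"]))
    return chains


def _chain_summary(s_id: str, orientation: str, hsps: list[HSP]) -> dict:
    intervals = sorted((h.q_start, h.q_end) for h in hsps)
    covered = 0
    pos = -1
    for qs, qe in intervals:
        if qs > pos:
            covered += qe - qs
            pos = qe
        elif qe > pos:
            covered += qe - pos
            pos = qe
    return {
        "s_id": s_id,
        "orientation": orientation,
        "s_start": min(h.s_start for h in hsps),
        "s_end": max(h.s_end for h in hsps),
        "score": sum(h.score for h in hsps),
        "q_covered": covered,
        "hsps": hsps,
    }


def _project_direction(genome_src: GenomeSequence, annot_src: AnnotationSet,
                       genome_dst: GenomeSequence, annot_dst: AnnotationSet,
                       dst_index: GenomeIndex, config: AlignmentConfig,
                       suffix: str) -> list[GeneFeature]:
    new_feats: list[GeneFeature] = []
    claimed: list[GeneFeature] = []  # provisional features added this pass
    for gene in annot_src.features:
        seq = genome_src.fetch(gene.chromosome, gene.start, gene.end)
        hits = dst_index.align(seq, config, q_id=gene.gene_id)
        if not hits:
            continue
        chains = cluster_hits(hits, gap=2 * gene.length)
        best = chains[0]  # highest summed score; ties resolved by position
        if best["q_covered"] < MIN_COVERAGE * gene.length:
            continue
        s_chrom, s_start, s_end = best["s_id"], best["s_start"], best["s_end"]
        if annot_dst.overlapping(s_chrom, s_start, s_end):
            continue
        if any(f.overlaps(s_chrom, s_start, s_end) for f in claimed):
            continue
        strand = gene.strand if best["orientation"] == "forward" else \
            ("-" if gene.strand == "+" else "+")
        feat = GeneFeature(
            gene_id=f"{gene.gene_id}{suffix}",
            chromosome=s_chrom,
            start=s_start,
            end=s_end,
            strand=strand,
            exons=(),
            feature_class=gene.feature_class,
            family=gene.family,
            provisional=True,
            source_gene_id=gene.gene_id,
        )
        claimed.append(feat)
        new_feats.append(feat)
    return new_feats


def co_annotate(genome_a: GenomeSequence, annot_a: AnnotationSet,
                genome_b: GenomeSequence, annot_b: AnnotationSet,
                config: AlignmentConfig | None = None,
                index_a: GenomeIndex | None = None,
                index_b: GenomeIndex | None = None,
                ) -> tuple[AnnotationSet, AnnotationSet]:
    """Mutual projection of unannotated homologs.

    For every gene of A with no overlapping annotated feature at its best
    hit-chain location in B, and whose chain covers at least half of the
    gene, a provisional feature is added to B (and symmetrically B -> A).
    Provisional features inherit family and feature class from their source
    and are plain intervals (no exon structure).  Rank indexes are rebuilt
    with the provisional features included.
    """
    config = config or AlignmentConfig()
    index_a = index_a or GenomeIndex(genome_a, config)
    index_b = index_b or GenomeIndex(genome_b, config)
    new_b = _project_direction(genome_a, annot_a, genome_b, annot_b, index_b,
                               config, suffix="@B")
    new_a = _project_direction(genome_b, annot_b, genome_a, annot_a, index_a,
                               config, suffix="@A")
    return annot_a.with_features(new_a), annot_b.with_features(new_b)
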