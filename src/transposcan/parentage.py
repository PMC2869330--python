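"""Parent (donor) locus identification for confirmed transposed genes.

The genomic span of a transposed gene (introns included) is searched
against its own genome; the best-scoring hit chain outside the gene itself
is the putative parent locus.  It qualifies only when the aligned columns
falling on the gene's *noncoding* positions reach at least 50 bp at >= 75%
identity -- the signature of a recent DNA-level duplication rather than
retroposition or deep paralogy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aligner import AlignmentConfig, GenomeIndex, HSP, encode
from .coanno import cluster_hits
from .detector import DissolvedPair, best_pairs
from .genome_io import AnnotationSet, GeneFeature, GenomeSequence

MIN_NONCODING_IDENTITY = 0.75
MIN_NONCODING_SPAN = 50
#: each noncoding piece contributing to the 50 bp tally must itself be this long
MIN_PIECE = 20
#: ranks within this distance count as the same tandem neighbourhood
TANDEM_RANK_WINDOW = 5


@dataclass
class ParentHit:
    transposed_gene_id: str
    parent_gene_id: str
    parent_chromosome: str
    parent_start: int
    parent_end: int
    noncoding_identity: float
    noncoding_span: int
    parent_is_syntenic_in_b: bool | None = None
    parent_in_tandem_array: bool = False


def _noncoding_flags(gene: GeneFeature) -> np.ndarray:
    """Boolean array over the gene span; True where position is noncoding."""
    flags = np.ones(gene.length, dtype=bool)
    for es, ee in gene.exons:
        flags[es - gene.start : ee - gene.start] = False
    return flags


def _noncoding_tally(gene: GeneFeature, genome: GenomeSequence,
                     hsps: list[HSP], subject_seq: str,
                     strict: bool = False) -> tuple[int, float]:
    """(span, identity) of aligned columns on the gene's noncoding positions.

    Restricted to ungapped segments, where query and subject columns map
    one-to-one, so per-column identity is exact.  Pieces shorter than
    ``MIN_PIECE`` bp of noncoding alignment are ignored to avoid splinter
    artifacts; the remaining pieces are summed.
    """
    flags = _noncoding_flags(gene)
    qa = encode(genome.fetch(gene.chromosome, gene.start, gene.end))
    sa = encode(subject_seq)
    span = 0
    ident = 0
    for h in hsps:
        if h.q_end - h.q_start != h.length or h.s_end - h.s_start != h.length:
            continue  # chained/gapped HSP: columns no longer map 1:1
        qs, qe = h.q_start, h.q_end
        if h.orientation == "forward":
            s_idx = np.arange(h.s_start, h.s_end)
        else:
            s_idx = np.arange(h.s_end - 1, h.s_start - 1, -1)
        q_idx = np.arange(qs, qe)
        nc = flags[q_idx]
        n_nc = int(nc.sum())
        if n_nc < MIN_PIECE:
            continue
        q_bases = qa[q_idx[nc]].astype(np.int16)
        s_bases = sa[s_idx[nc]].astype(np.int16)
        if h.orientation == "reverse":
            s_bases = 3 - s_bases  # complement; N (4) becomes -1, never equal
        matches = int(np.sum((q_bases == s_bases) & (q_bases < 4)))
        span += n_nc
        ident += matches
    if span == 0:
        return 0, 0.0
    return span, ident / span


def find_parent(gene_id: str, genome: GenomeSequence, annot: AnnotationSet,
                index: GenomeIndex, config: AlignmentConfig | None = None,
                min_identity: float = MIN_NONCODING_IDENTITY,
                min_span: int = MIN_NONCODING_SPAN,
                strict_identity: bool = False) -> ParentHit | None:
    """Best hit outside the gene itself, qualified by noncoding similarity.

    ``strict_identity`` switches the 75% boundary from inclusive (>=, the
    default) to strict (>).  Returns None when no locus passes, including
    when the best hit conserves only coding sequence (a retroposition-like
    signature).
    """
    config = config or AlignmentConfig()
    gene = annot[gene_id]
    seq = genome.fetch(gene.chromosome, gene.start, gene.end)
    hits = index.align(seq, config, q_id=gene_id)
    # exclude any hit overlapping the query gene's own interval
    hits = [h for h in hits
            if not (h.s_id == gene.chromosome and h.s_start < gene.end
                    and gene.start < h.s_end)]
    if not hits:
        return None
    loci = cluster_hits(hits, gap=2 * gene.length)
    best = loci[0]
    subject_seq = genome.chromosomes[best["s_id"]]
    hsps = best["hsps"]
    span, identity = _noncoding_tally(gene, genome, hsps, subject_seq)
    passes = identity > min_identity if strict_identity else identity >= min_identity
    if span < min_span or not passes:
        return None
    overlapping = annot.overlapping(best["s_id"], best["s_start"], best["s_end"])
    overlapping = [f for f in overlapping if f.gene_id != gene_id]
    if not overlapping:
        return None  # best hit is unannotated sequence; no parent gene to report
    parent = max(overlapping,
                 key=lambda f: (min(f.end, best["s_end"]) - max(f.start, best["s_start"]),
                                f.gene_id))
    return ParentHit(
        transposed_gene_id=gene_id,
        parent_gene_id=parent.gene_id,
        parent_chromosome=parent.chromosome,
        parent_start=parent.start,
        parent_end=parent.end,
        noncoding_identity=identity,
        noncoding_span=span,
        parent_in_tandem_array=in_tandem_array(parent, annot),
    )


def in_tandem_array(gene: GeneFeature, annot: AnnotationSet,
                    rank_window: int = TANDEM_RANK_WINDOW) -> bool:
    """True when another same-family gene lies within ``rank_window`` ranks."""
    chrom, rank = annot.rank_of(gene.gene_id)
    for r in range(rank - rank_window, rank + rank_window + 1):
        if r == rank:
            continue
        other = annot.at_rank(chrom, r)
        if other is not None and other.family == gene.family \
                and other.family not in ("unknown", ""):
            return True
    return False


def parent_syntenic_in_b(parent_gene_id: str, pairs: list[DissolvedPair],
                         annot_a: AnnotationSet, annot_b: AnnotationSet,
                         window: int = 3) -> bool | None:
    """Whether the parent passes the flanking-gene consistency check.

    True when the parent pairs to a subject gene whose rank lies between
    the subject ranks of the parent's nearest paired neighbours -- i.e. the
    parent occupies the same relative position in both genomes.  None when
    the check cannot be made (parent or its neighbours unpaired).
    """
    chosen = best_pairs(pairs)
    if parent_gene_id not in chosen:
        return False
    chrom, rank = annot_a.rank_of(parent_gene_id)
    own_chrom, own_rank = annot_b.rank_of(chosen[parent_gene_id])
    feats = annot_a.on_chromosome(chrom)

    def paired_rank(direction: int) -> tuple[str, int] | None:
        r = rank + direction
        steps = 0
        while 0 <= r < len(feats) and steps < window:
            gid = feats[r].gene_id
            if gid in chosen and gid != parent_gene_id:
                return annot_b.rank_of(chosen[gid])
            r += direction
            steps += 1
        return None

    left = paired_rank(-1)
    right = paired_rank(+1)
    if left is None or right is None:
        return None
    (lc, lr), (rc, rr) = left, right
    if lc != own_chrom or rc != own_chrom:
        return False
    lo, hi = min(lr, rr), max(lr, rr)
    return lo <= own_rank <= hi
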