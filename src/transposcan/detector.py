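"""Transposition candidate detection via the flanking-gene method.

Genes are paired between the two genomes by dissolved local-alignment hits
(per-pair merged hit length >= 96 bp), gene identities are replaced by
integer positions along each chromosome, and a gene present between two
matched flankers in one genome but absent between their orthologs in the
other is emitted as a transposition candidate.  Candidates then pass a
fixed filter cascade (orthologous region, feature class, residual hit,
interrupter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aligner import AlignmentConfig, GenomeIndex, HSP, local_align
from .genome_io import (AnnotationSet, GeneFeature, GenomeSequence,
                        OrthologousRegion)

MIN_DISSOLVED_LENGTH = 96
RESIDUAL_HIT_BP = 15
FLANK_WINDOW = 3
RESIDUAL_MARGIN = 200

STATUS_PENDING = "pending"
STATUS_CANDIDATE = "candidate"
STATUS_INTERRUPTER = "interrupter"
STATUS_NONORTHOLOGOUS = "discarded_nonorthologous_region"
STATUS_RESIDUAL = "discarded_residual_hit"
STATUS_PSEUDO_TE = "discarded_pseudogene_or_TE"


@dataclass
class DissolvedPair:
    """One gene pair retained after merging its hits into a single pairing."""

    q_gene: str
    s_gene: str
    merged_length: int
    best_evalue: float
    total_score: int = 0


@dataclass
class TranspositionCandidate:
    """A gene present between flankers in the query genome but missing

    between their orthologs in the subject genome, with its filter audit.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    flanker_q1: str
    flanker_q2: str
    flanker_s1: str | None
    flanker_s2: str | None
    status: str = STATUS_PENDING
    residual_hit_len: int = 0


def merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    covered = 0
    pos = None
    for s, e in sorted(intervals):
        if pos is None or s > pos:
            covered += e - s
            pos = e
        elif e > pos:
            covered += e - pos
            pos = e
    return covered


def dissolve(hsps_by_pair: dict[tuple[str, str], list[HSP]],
             min_sum: int = MIN_DISSOLVED_LENGTH) -> list[DissolvedPair]:
    """Merge small hits to the same gene pair into one pairing.

    Overlapping query intervals are merged before summing; pairs whose
    merged length falls below ``min_sum`` (default 96) are dropped.
    """
    out = []
    for (q_gene, s_gene), hsps in hsps_by_pair.items():
        if not hsps:
            continue
        merged = merged_interval_length([(h.q_start, h.q_end) for h in hsps])
        if merged < min_sum:
            continue
        out.append(DissolvedPair(q_gene=q_gene, s_gene=s_gene, merged_length=merged,
                                 best_evalue=min(h.evalue for h in hsps),
                                 total_score=sum(h.score for h in hsps)))
    out.sort(key=lambda p: (p.q_gene, -p.merged_length, p.best_evalue, p.s_gene))
    return out


def best_pairs(pairs: list[DissolvedPair]) -> dict[str, str]:
    """One subject gene per query gene: highest merged length, then best

    e-value, then lexicographic subject id.
    """
    best: dict[str, DissolvedPair] = {}
    for p in pairs:
        cur = best.get(p.q_gene)
        if cur is None or (-p.merged_length, p.best_evalue, p.s_gene) < \
                (-cur.merged_length, cur.best_evalue, cur.s_gene):
            best[p.q_gene] = p
    return {q: p.s_gene for q, p in best.items()}


def pair_genes(genome_q: GenomeSequence, annot_q: AnnotationSet,
               annot_s: AnnotationSet, index_s: GenomeIndex,
               config: AlignmentConfig | None = None,
               min_sum: int = MIN_DISSOLVED_LENGTH) -> list[DissolvedPair]:
    """Align every query gene against the subject genome and dissolve hits.

    Genome-wide hits are attributed to the subject gene whose interval they
    overlap most; hits landing outside any annotated feature contribute to
    no pairing.
    """
    config = config or AlignmentConfig()
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for gene in annot_q.features:
        seq = genome_q.fetch(gene.chromosome, gene.start, gene.end)
        for h in index_s.align(seq, config, q_id=gene.gene_id):
            feats = annot_s.overlapping(h.s_id, h.s_start, h.s_end)
            if not feats:
                continue
            target = max(feats, key=lambda f: (min(f.end, h.s_end) - max(f.start, h.s_start),
                                               f.gene_id))
            by_pair.setdefault((gene.gene_id, target.gene_id), []).append(h)
    return dissolve(by_pair, min_sum=min_sum)


# ---------------------------------------------------------------------------
# integer-position matching
# ---------------------------------------------------------------------------


def missing_between(rank_pairs: list[tuple[int, int]],
                    max_gap: int = FLANK_WINDOW) -> list[tuple[str, int]]:
    """Missing integer positions implied by a matched rank-pair list.

    Given ortholog pairs as (query rank, subject rank) sorted by query rank,
    a subject rank skipped between two pairs whose query ranks are
    consecutive is missing in the query genome, and vice versa.  For the
    pair list [(1, 123), (2, 125)] the subject gene at position 124 is
    unaccounted for.  Both ascending and descending subject order are
    handled; gaps larger than ``max_gap`` are not called.
    """
    out: list[tuple[str, int]] = []
    pairs = sorted(rank_pairs)
    for (q1, s1), (q2, s2) in zip(pairs, pairs[1:]):
        dq = q2 - q1
        ds = s2 - s1
        step = 1 if ds >= 0 else -1
        if dq == 1 and 2 <= abs(ds) <= max_gap + 1:
            for s in range(s1 + step, s2, step):
                out.append(("subject", s))
        elif abs(ds) == 1 and 2 <= dq <= max_gap + 1:
            for q in range(q1 + 1, q2):
                out.append(("query", q))
    return out


def flanking_gene_scan(pairs: list[DissolvedPair], annot_q: AnnotationSet,
                       annot_s: AnnotationSet,
                       window: int = FLANK_WINDOW) -> list[TranspositionCandidate]:
    """Report query genes absent between their flankers' subject orthologs.

    For each pair of matched query genes adjacent in the paired subsequence
    of one chromosome, any unmatched query genes strictly between them are
    emitted when the two subject ranks are consecutive (a clean gap) or
    identical (both flankers hitting one subject gene, the tandem
    "interrupter" configuration), provided the in-between gene itself has
    no subject pairing inside the window.
    """
    chosen = best_pairs(pairs)
    # per candidate gene keep the tightest flanker window (so a gene inside a
    # tandem duplication is reported between its identical flankers, not a
    # wider pair), tie broken by leftmost window
    best_windows: dict[str, tuple[int, int, TranspositionCandidate]] = {}
    for chrom in annot_q.chromosomes():
        feats = annot_q.on_chromosome(chrom)
        ranks = []
        for f in feats:
            partner = chosen.get(f.gene_id)
            ranks.append(annot_s.rank_of(partner) if partner is not None else None)
        for r1, g1 in enumerate(feats):
            if ranks[r1] is None:
                continue
            s_chrom, s1_rank = ranks[r1]
            # right flankers whose ortholog is adjacent (or identical, the
            # tandem interrupter configuration) to g1's ortholog
            for r2 in range(r1 + 2, min(r1 + window + 2, len(feats))):
                if ranks[r2] is None:
                    continue
                s2_chrom, s2_rank = ranks[r2]
                if s2_chrom != s_chrom or abs(s2_rank - s1_rank) > 1:
                    continue  # paired, but not to the adjacent ortholog
                g2 = feats[r2]
                lo = min(s1_rank, s2_rank) - window
                hi = max(s1_rank, s2_rank) + window
                for r in range(r1 + 1, r2):
                    g = feats[r]
                    if ranks[r] is not None:
                        p_chrom, p_rank = ranks[r]
                        if p_chrom == s_chrom and lo <= p_rank <= hi:
                            continue  # accounted for inside the window
                    cand = TranspositionCandidate(
                        gene_id=g.gene_id, chromosome=g.chromosome, start=g.start,
                        end=g.end, flanker_q1=g1.gene_id, flanker_q2=g2.gene_id,
                        flanker_s1=chosen[g1.gene_id], flanker_s2=chosen[g2.gene_id])
                    key = (r2 - r1, r1)
                    cur = best_windows.get(g.gene_id)
                    if cur is None or key < cur[:2]:
                        best_windows[g.gene_id] = (*key, cand)
                break
    return [cand for _, _, cand in
            sorted(best_windows.values(),
                   key=lambda t: (t[2].chromosome, t[2].start))]


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------


def _masked_window(genome: GenomeSequence, annot: AnnotationSet, chrom: str,
                   start: int, end: int) -> str:
    """Window sequence with exon positions of overlapping features masked."""
    start = max(0, start)
    end = min(genome.length(chrom), end)
    seq = list(genome.fetch(chrom, start, end))
    for f in annot.overlapping(chrom, start, end):
        for es, ee in f.exons:
            for i in range(max(es, start), min(ee, end)):
                seq[i - start] = "N"
    return "".join(seq)


def apply_filters(cand: TranspositionCandidate, genome_q: GenomeSequence,
                  annot_q: AnnotationSet, genome_s: GenomeSequence,
                  annot_s: AnnotationSet, regions: list[OrthologousRegion],
                  config: AlignmentConfig | None = None,
                  query_is_a: bool = True,
                  residual_bp: int = RESIDUAL_HIT_BP) -> TranspositionCandidate:
    """Assign the candidate's terminal status by the first failing rule.

    Order: (1) outside every orthologous region; (2) pseudogene or TE;
    (3) residual alignment of the gene to the subject inter-flanker
    noncoding gap of at least ``residual_bp`` aligned bp (which would
    instead suggest gene loss in the subject genome); (4) identical subject
    flankers (interrupter).  Survivors are retained candidates.
    """
    config = config or AlignmentConfig()
    gene = annot_q[cand.gene_id]

    def inside_region() -> bool:
        for r in regions:
            if query_is_a:
                if r.contains_a(gene.chromosome, gene.start, gene.end):
                    return True
            else:
                if (gene.chromosome == r.chrom_b and gene.start >= r.start_b
                        and gene.end <= r.end_b):
                    return True
        return False

    if cand.flanker_s1 is None or cand.flanker_s2 is None or not inside_region():
        cand.status = STATUS_NONORTHOLOGOUS
        return cand
    if gene.feature_class != "gene":
        cand.status = STATUS_PSEUDO_TE
        return cand
    f1 = annot_s[cand.flanker_s1]
    f2 = annot_s[cand.flanker_s2]
    if f1.gene_id != f2.gene_id:
        left, right = (f1, f2) if f1.start <= f2.start else (f2, f1)
        win_start = max(left.start, left.end - RESIDUAL_MARGIN)
        win_end = min(right.end, right.start + RESIDUAL_MARGIN)
        if win_end > win_start:
            window = _masked_window(genome_s, annot_s, left.chromosome,
                                    win_start, win_end)
            gene_seq = genome_q.fetch(gene.chromosome, gene.start, gene.end)
            if len(window) >= config.word_size and set(window) != {"N"}:
                hits = local_align(gene_seq, window, config, q_id=gene.gene_id)
                residual = max((h.length for h in hits), default=0)
                cand.residual_hit_len = residual
                if residual >= residual_bp:
                    cand.status = STATUS_RESIDUAL
                    return cand
    if f1.gene_id == f2.gene_id:
        cand.status = STATUS_INTERRUPTER
        return cand
    cand.status = STATUS_CANDIDATE
    return cand


def detect(genome_a: GenomeSequence, annot_a: AnnotationSet,
           genome_b: GenomeSequence, annot_b: AnnotationSet,
           regions: list[OrthologousRegion],
           config: AlignmentConfig | None = None,
           index_a: GenomeIndex | None = None,
           index_b: GenomeIndex | None = None,
           window: int = FLANK_WINDOW,
           min_sum: int = MIN_DISSOLVED_LENGTH,
           ) -> tuple[list[TranspositionCandidate], list[TranspositionCandidate],
                      list[DissolvedPair], list[DissolvedPair]]:
    """Run pairing + scan + filters in both directions.

    Returns (A-gain candidates, B-gain candidates, A->B pairs, B->A pairs).
    A-gain candidates are genes present in genome A and missing between
    their flanker orthologs in B; downstream stages consume these.
    """
    config = config or AlignmentConfig()
    index_a = index_a or GenomeIndex(genome_a, config)
    index_b = index_b or GenomeIndex(genome_b, config)
    pairs_ab = pair_genes(genome_a, annot_a, annot_b, index_b, config, min_sum)
    pairs_ba = pair_genes(genome_b, annot_b, annot_a, index_a, config, min_sum)
    cands_a = flanking_gene_scan(pairs_ab, annot_a, annot_b, window)
    cands_b = flanking_gene_scan(pairs_ba, annot_b, annot_a, window)
    for c in cands_a:
        apply_filters(c, genome_a, annot_a, genome_b, annot_b, regions, config,
                      query_is_a=True)
    for c in cands_b:
        apply_filters(c, genome_b, annot_b, genome_a, annot_a, regions, config,
                      query_is_a=False)
    return cands_a, cands_b, pairs_ab, pairs_ba
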