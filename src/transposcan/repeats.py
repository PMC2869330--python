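"""Direct/inverted repeat discovery in gene-flanking windows.

The upstream window (~500 bp before the gene) is aligned against the
downstream window (~500 bp after it); hits at least as significant as a
15/15 bp exact match, and not low-complexity, are flanking repeats.
Forward hits are direct repeats, reverse hits inverted.  Context
classification asks whether the repeat sequence also occurs at the parent
locus (carryover out of the donor site) and at the orthologous target
window in genome B (homology that could have seeded the insertion), and
whether the repeat is a chimera of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .aligner import (AlignmentConfig, GenomeIndex, HSP, is_low_complexity,
                      local_align, min_repeat_score)
from .genome_io import AnnotationSet, GeneFeature, GenomeSequence

FLANK_WINDOW_BP = 500
SCAN_WINDOW_BP = 2000
SCAN_MIN_LEN = 30
SCAN_MAX_LEN = 400
CONTEXT_MARGIN = 2000

#: query intervals of parent- and target-hits overlapping less than this
#: fraction of the shorter interval count as disjoint portions (chimera)
_CHIMERA_MAX_OVERLAP = 0.25


@dataclass
class RepeatPair:
    """A matched upstream/downstream flanking repeat around one gene."""

    gene_id: str
    up_start: int
    up_end: int
    down_start: int
    down_end: int
    repeat_length: int       # aligned columns
    identity: float
    orientation: str         # "direct" | "inverted"
    score: int = 0
    present_at_parent: bool | None = None
    present_at_ortholog_target: bool | None = None
    chimeric_with_target: bool = False
    annotation_label: str = ""

    @property
    def exceeds_15(self) -> bool:
        """Length class mirroring the '>15 bp' table column (strict >)."""
        return self.repeat_length > 15

    @property
    def exceeds_30(self) -> bool:
        return self.repeat_length > 30


def _windows(gene: GeneFeature, genome: GenomeSequence, flank: int,
             anchor_coding: bool = False) -> tuple[tuple[int, int], tuple[int, int]]:
    if anchor_coding and gene.exons:
        left, right = gene.exons[0][0], gene.exons[-1][1]
    else:
        left, right = gene.start, gene.end
    n = genome.length(gene.chromosome)
    return (max(0, left - flank), left), (right, min(n, right + flank))


def find_flanking_repeats(gene: GeneFeature, genome: GenomeSequence,
                          flank: int = FLANK_WINDOW_BP,
                          config: AlignmentConfig | None = None,
                          anchor_coding: bool = False,
                          both_orientations: bool = True) -> list[RepeatPair]:
    """All repeat pairs linking the gene's upstream and downstream windows.

    Hits below the score of a 15/15 exact match in this search space, or
    with a low-complexity repeat sequence, are discarded.  Multiple
    surviving hits are all reported, longest first.
    """
    config = config or AlignmentConfig()
    (us, ue), (ds, de) = _windows(gene, genome, flank, anchor_coding)
    if ue - us < config.word_size or de - ds < config.word_size:
        return []
    up = genome.fetch(gene.chromosome, us, ue)
    down = genome.fetch(gene.chromosome, ds, de)
    floor = min_repeat_score(config, len(up), len(down))
    hits = local_align(up, down, config, q_id=gene.gene_id,
                       both_strands=both_orientations)
    out = []
    for h in hits:
        if h.score < floor:
            continue
        rep_seq = up[h.q_start : h.q_end]
        if not rep_seq or is_low_complexity(rep_seq, config):
            continue
        out.append(RepeatPair(
            gene_id=gene.gene_id,
            up_start=us + h.q_start, up_end=us + h.q_end,
            down_start=ds + h.s_start, down_end=ds + h.s_end,
            repeat_length=h.length, identity=h.identity,
            orientation="direct" if h.orientation == "forward" else "inverted",
            score=h.score))
    out.sort(key=lambda r: (-r.repeat_length, -r.score, r.up_start))
    return out


def _hits_in_window(repeat_seq: str, window_seq: str,
                    config: AlignmentConfig) -> list[HSP]:
    if len(window_seq) < config.word_size or len(repeat_seq) < config.word_size:
        return []
    floor = min_repeat_score(config, len(repeat_seq), len(window_seq))
    hits = local_align(repeat_seq, window_seq, config, q_id="repeat")
    return [h for h in hits if h.score >= floor]


def classify_repeat_context(pair: RepeatPair, genome_a: GenomeSequence,
                            chromosome: str,
                            parent_interval: tuple[str, int, int] | None,
                            genome_b: GenomeSequence,
                            target_interval: tuple[str, int, int] | None,
                            config: AlignmentConfig | None = None,
                            margin: int = CONTEXT_MARGIN) -> RepeatPair:
    """Set carryover/target/chimera flags on a repeat pair.

    ``parent_interval`` is the parent locus in genome A (None when no
    parent was identified), ``target_interval`` the inter-flanker window in
    genome B (the pre-insertion orthologous site).  Both are expanded by
    ``margin`` bp.  The chimera flag is set when the best parent hit and
    the best target hit cover essentially disjoint portions of the repeat.
    """
    config = config or AlignmentConfig()
    repeat_seq = genome_a.fetch(chromosome, pair.up_start, pair.up_end)

    best_parent: HSP | None = None
    if parent_interval is not None:
        p_chrom, p_start, p_end = parent_interval
        window = genome_a.fetch(p_chrom, p_start - margin, p_end + margin)
        hits = _hits_in_window(repeat_seq, window, config)
        pair.present_at_parent = bool(hits)
        best_parent = hits[0] if hits else None
    else:
        pair.present_at_parent = None

    best_target: HSP | None = None
    if target_interval is not None:
        t_chrom, t_start, t_end = target_interval
        window = genome_b.fetch(t_chrom, t_start - margin, t_end + margin)
        hits = _hits_in_window(repeat_seq, window, config)
        pair.present_at_ortholog_target = bool(hits)
        best_target = hits[0] if hits else None
    else:
        pair.present_at_ortholog_target = None

    pair.chimeric_with_target = False
    if best_parent is not None and best_target is not None:
        p0, p1 = best_parent.q_start, best_parent.q_end
        t0, t1 = best_target.q_start, best_target.q_end
        overlap = max(0, min(p1, t1) - max(p0, t0))
        shorter = max(1, min(p1 - p0, t1 - t0))
        if overlap <= _CHIMERA_MAX_OVERLAP * shorter:
            pair.chimeric_with_target = True
    return pair


def scan_genome_repeats(genome: GenomeSequence, annot: AnnotationSet,
                        flank: int = SCAN_WINDOW_BP,
                        min_len: int = SCAN_MIN_LEN, max_len: int = SCAN_MAX_LEN,
                        config: AlignmentConfig | None = None) -> pd.DataFrame:
    """Genome-wide automated scan for direct repeats flanking each gene.

    Windows of ``flank`` bp up- and downstream of the coding-sequence
    bounds of every feature (pseudogenes included) are compared in the
    direct orientation; a gene is flagged when any hit with aligned length
    in [min_len, max_len] survives the 15/15 significance and
    low-complexity filters.  Returns one row per feature.
    """
    config = config or AlignmentConfig()
    rows = []
    for gene in annot.features:
        pairs = find_flanking_repeats(gene, genome, flank=flank, config=config,
                                      anchor_coding=True, both_orientations=False)
        qual = [p for p in pairs if min_len <= p.repeat_length <= max_len]
        rows.append({
            "gene_id": gene.gene_id,
            "family": gene.family,
            "feature_class": gene.feature_class,
            "has_flanking_repeat": bool(qual),
            "best_repeat_length": qual[0].repeat_length if qual else 0,
        })
    return pd.DataFrame(rows)


def repeat_sequence_identity_annotation(pair: RepeatPair, genome: GenomeSequence,
                                        chromosome: str, annot: AnnotationSet,
                                        index: GenomeIndex,
                                        transposed: GeneFeature,
                                        config: AlignmentConfig | None = None) -> str:
    """Label a repeat by what its best genome hit overlaps.

    Returns ``genic:<gene_id>``, ``transposon``, ``within_transposed_sequence``
    or ``intergenic``.  Hits to the repeat's own two copies are excluded
    before taking the best hit.
    """
    config = config or AlignmentConfig()
    repeat_seq = genome.fetch(chromosome, pair.up_start, pair.up_end)
    hits = index.align(repeat_seq, config, q_id="repeat")

    def is_self(h: HSP) -> bool:
        if h.s_id != chromosome:
            return False
        for s, e in ((pair.up_start, pair.up_end), (pair.down_start, pair.down_end)):
            if h.s_start < e and s < h.s_end:
                return True
        return False

    hits = [h for h in hits if not is_self(h)]
    if not hits:
        return "intergenic"
    best = hits[0]
    if (best.s_id == transposed.chromosome and best.s_start < transposed.end
            and transposed.start < best.s_end):
        return "within_transposed_sequence"
    feats = annot.overlapping(best.s_id, best.s_start, best.s_end)
    tes = [f for f in feats if f.feature_class == "transposable_element"]
    if tes:
        return "transposon"
    genic = [f for f in feats if f.feature_class in ("gene", "pseudogene")]
    if genic:
        top = max(genic, key=lambda f: (min(f.end, best.s_end) - max(f.start, best.s_start),
                                        f.gene_id))
        return f"genic:{top.gene_id}"
    return "intergenic"
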