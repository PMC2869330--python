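"""End-to-end orchestration: co-annotation -> detection -> outgroup

confirmation -> parentage -> flanking repeats -> statistics, with TSV
outputs as the contracts between stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .aligner import AlignmentConfig, GenomeIndex
from .coanno import co_annotate
from .detector import (FLANK_WINDOW, MIN_DISSOLVED_LENGTH, RESIDUAL_HIT_BP,
                       STATUS_CANDIDATE, detect)
from .genome_io import (AnnotationSet, GenomeSequence, read_fasta, read_gff,
                        read_regions, write_gff)
from .outgroup import (FINAL_CONFIRMED, OUTGROUP_BUFFER,
                       classify_against_outgroup, confirm)
from .parentage import (MIN_NONCODING_IDENTITY, MIN_NONCODING_SPAN, find_parent,
                        parent_syntenic_in_b)
from .repeats import (CONTEXT_MARGIN, FLANK_WINDOW_BP, SCAN_MAX_LEN, SCAN_MIN_LEN,
                      SCAN_WINDOW_BP, classify_repeat_context,
                      find_flanking_repeats, repeat_sequence_identity_annotation)
from .stats import enrichment_tables, family_table, transposition_rate

logger = logging.getLogger("transposcan")


@dataclass
class Thresholds:
    """Every numeric knob of the pipeline, with the documented defaults:

    values: dissolved-pair floor 96 bp, +-3-gene windows, 15 bp residual
    hits, 15 kb outgroup buffers, parent criteria 75% identity over 50 bp
    of noncoding sequence, 500 bp repeat windows (2 kb and 30-400 bp for
    the genome-wide scan).
    """

    min_sum: int = MIN_DISSOLVED_LENGTH
    window: int = FLANK_WINDOW
    residual: int = RESIDUAL_HIT_BP
    buffer: int = OUTGROUP_BUFFER
    parent_identity: float = MIN_NONCODING_IDENTITY
    parent_span: int = MIN_NONCODING_SPAN
    flank: int = FLANK_WINDOW_BP
    scan_flank: int = SCAN_WINDOW_BP
    repeat_min: int = SCAN_MIN_LEN
    repeat_max: int = SCAN_MAX_LEN
    context_margin: int = CONTEXT_MARGIN
    divergence_my: float = 5.0

    def __post_init__(self):
        for name in ("min_sum", "window", "residual", "buffer", "parent_span",
                     "flank", "scan_flank", "repeat_min", "repeat_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    """File-based run configuration (see the YAML template in the docs)."""

    genome_a: str
    annot_a: str
    genome_b: str
    annot_b: str
    genome_o1: str
    annot_o1: str
    genome_o2: str
    annot_o2: str
    regions: str
    outdir: str
    controls: str | None = None
    seed: int = 0
    run_scan: bool = True
    thresholds: Thresholds = field(default_factory=Thresholds)
    aligner: AlignmentConfig = field(default_factory=AlignmentConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        al = AlignmentConfig(**raw.pop("aligner", {}))
        missing = [k for k in ("genome_a", "annot_a", "genome_b", "annot_b",
                               "genome_o1", "annot_o1", "genome_o2", "annot_o2",
                               "regions", "outdir") if k not in raw]
        if missing:
            raise ValueError(f"pipeline config missing keys: {missing}")
        return cls(thresholds=thr, aligner=al, **raw)


def _candidates_frame(cands) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "chrom": c.chromosome, "start": c.start,
        "end": c.end, "status": c.status, "flankerA1": c.flanker_q1,
        "flankerA2": c.flanker_q2, "flankerB1": c.flanker_s1,
        "flankerB2": c.flanker_s2, "residual_hit_len": c.residual_hit_len,
    } for c in cands])


def run_pipeline(genome_a: GenomeSequence, annot_a: AnnotationSet,
                 genome_b: GenomeSequence, annot_b: AnnotationSet,
                 outgroups: list[tuple[GenomeSequence, AnnotationSet]],
                 regions, control_genes: list[str] | None = None,
                 config: AlignmentConfig | None = None,
                 thr: Thresholds | None = None,
                 outdir: str | Path | None = None,
                 run_scan: bool = True) -> dict:
    """Run every stage on in-memory inputs; optionally write report TSVs.

    Returns a report dict with the per-stage DataFrames and summary counts.
    """
    config = config or AlignmentConfig()
    thr = thr or Thresholds()
    report: dict = {}

    index_a = GenomeIndex(genome_a, config)
    index_b = GenomeIndex(genome_b, config)

    logger.info("stage coanno: projecting unannotated homologs")
    annot_a, annot_b = co_annotate(genome_a, annot_a, genome_b, annot_b, config,
                                   index_a=index_a, index_b=index_b)
    n_prov = sum(f.provisional for f in annot_a.features + annot_b.features)
    logger.info("coanno: %d provisional features added", n_prov)

    logger.info("stage detect: pairing and flanking-gene scan")
    cands_a, cands_b, pairs_ab, pairs_ba = detect(
        genome_a, annot_a, genome_b, annot_b, regions, config,
        index_a=index_a, index_b=index_b, window=thr.window, min_sum=thr.min_sum)
    cand_df = _candidates_frame(cands_a)
    logger.info("detect: %d A-gain candidates (%d retained), %d B-gain",
                len(cands_a),
                sum(c.status == STATUS_CANDIDATE for c in cands_a), len(cands_b))

    logger.info("stage confirm: outgroup classification")
    retained = [c for c in cands_a if c.status == STATUS_CANDIDATE]
    out_indexes = [GenomeIndex(g, config) for g, _ in outgroups]
    calls = []
    for (og_genome, og_annot), og_index in zip(outgroups, out_indexes):
        calls.append({c.gene_id: classify_against_outgroup(
            c.gene_id, genome_a, annot_a, og_index, config, buffer=thr.buffer)
            for c in retained})
    verdicts = confirm(retained, calls[0], calls[1])
    verdict_df = pd.DataFrame([asdict(v) for v in verdicts])
    confirmed = [v.gene_id for v in verdicts if v.final == FINAL_CONFIRMED]
    logger.info("confirm: %d confirmed insertions of %d candidates",
                len(confirmed), len(retained))

    logger.info("stage parents: donor-locus search")
    parent_rows = []
    parents = {}
    for gid in confirmed:
        hit = find_parent(gid, genome_a, annot_a, index_a, config,
                          min_identity=thr.parent_identity,
                          min_span=thr.parent_span)
        parents[gid] = hit
        if hit is not None:
            hit.parent_is_syntenic_in_b = parent_syntenic_in_b(
                hit.parent_gene_id, pairs_ab, annot_a, annot_b, thr.window)
        parent_rows.append({
            "gene_id": gid,
            "parent_id": hit.parent_gene_id if hit else "",
            "noncoding_identity": round(hit.noncoding_identity, 4) if hit else "",
            "noncoding_span": hit.noncoding_span if hit else 0,
            "parent_syntenic_in_B": hit.parent_is_syntenic_in_b if hit else "",
            "parent_in_tandem_array": hit.parent_in_tandem_array if hit else "",
        })
    parent_df = pd.DataFrame(parent_rows)
    logger.info("parents: %d of %d confirmed genes have a qualifying parent",
                sum(1 for h in parents.values() if h), len(confirmed))

    logger.info("stage repeats: flanking-repeat discovery and context")
    by_id = {c.gene_id: c for c in retained}
    repeat_rows = []
    transposed_flags = []
    for gid in confirmed:
        gene = annot_a[gid]
        pairs = find_flanking_repeats(gene, genome_a, flank=thr.flank, config=config)
        best = pairs[0] if pairs else None
        if best is not None:
            cand = by_id[gid]
            hit = parents.get(gid)
            parent_iv = (hit.parent_chromosome, hit.parent_start, hit.parent_end) \
                if hit else None
            target_iv = None
            if cand.flanker_s1 and cand.flanker_s2:
                f1, f2 = annot_b[cand.flanker_s1], annot_b[cand.flanker_s2]
                left, right = (f1, f2) if f1.start <= f2.start else (f2, f1)
                if right.start > left.end:
                    target_iv = (left.chromosome, left.end, right.start)
            classify_repeat_context(best, genome_a, gene.chromosome, parent_iv,
                                    genome_b, target_iv, config,
                                    margin=thr.context_margin)
            best.annotation_label = repeat_sequence_identity_annotation(
                best, genome_a, gene.chromosome, annot_a, index_a, gene, config)
        repeat_rows.append({
            "gene_id": gid,
            "repeat_length": best.repeat_length if best else 0,
            "identity": round(best.identity, 4) if best else "",
            "orientation": best.orientation if best else "",
            "up_start": best.up_start if best else "",
            "up_end": best.up_end if best else "",
            "down_start": best.down_start if best else "",
            "down_end": best.down_end if best else "",
            "present_at_parent": best.present_at_parent if best else "",
            "present_at_ortholog_target": best.present_at_ortholog_target if best else "",
            "chimeric": best.chimeric_with_target if best else "",
            "annotation_label": best.annotation_label if best else "",
        })
        transposed_flags.append({
            "gene_id": gid,
            "repeat_gt15": bool(best and best.exceeds_15),
            "repeat_gt30": bool(best and best.exceeds_30),
            "has_parent": parents.get(gid) is not None,
        })
    repeat_df = pd.DataFrame(repeat_rows)
    transposed_df = pd.DataFrame(transposed_flags)

    control_df = pd.DataFrame()
    if control_genes:
        logger.info("stage controls: repeats and parent search on %d genes",
                    len(control_genes))
        rows = []
        for gid in control_genes:
            gene = annot_a[gid]
            pairs = find_flanking_repeats(gene, genome_a, flank=thr.flank,
                                          config=config)
            best = pairs[0] if pairs else None
            hit = find_parent(gid, genome_a, annot_a, index_a, config,
                              min_identity=thr.parent_identity,
                              min_span=thr.parent_span)
            rows.append({
                "gene_id": gid,
                "repeat_gt15": bool(best and best.exceeds_15),
                "repeat_gt30": bool(best and best.exceeds_30),
                "has_parent": hit is not None,
            })
        control_df = pd.DataFrame(rows)

    scan_df = pd.DataFrame()
    scan_family = pd.DataFrame()
    if run_scan:
        logger.info("stage scan: genome-wide flanking-repeat scan")
        from .repeats import scan_genome_repeats
        scan_df = scan_genome_repeats(genome_a, annot_a, flank=thr.scan_flank,
                                      min_len=thr.repeat_min,
                                      max_len=thr.repeat_max, config=config)
        flagged = scan_df[scan_df["has_flanking_repeat"]]
        if len(flagged):
            scan_family = family_table(list(flagged["family"]), min_members=5)

    logger.info("stage stats")
    enrichment = None
    if len(transposed_df) and len(control_df):
        enrichment = enrichment_tables(transposed_df, control_df)
    families = family_table([annot_a[g].family for g in confirmed], min_members=2) \
        if confirmed else pd.DataFrame()
    rate = transposition_rate(len(confirmed), thr.divergence_my) if confirmed else None

    report.update({
        "annot_a": annot_a, "annot_b": annot_b,
        "candidates_a": cands_a, "candidates_b": cands_b,
        "pairs_ab": pairs_ab, "pairs_ba": pairs_ba,
        "candidates": cand_df, "verdicts": verdict_df, "confirmed": confirmed,
        "parents": parent_df, "parent_hits": parents, "repeats": repeat_df,
        "transposed_flags": transposed_df, "control_flags": control_df,
        "scan": scan_df, "scan_family": scan_family,
        "enrichment": enrichment, "families": families, "rate": rate,
        "counts": {
            "provisional_features": n_prov,
            "candidates_total": len(cands_a),
            "candidates_retained": len(retained),
            "confirmed": len(confirmed),
            "with_parent": sum(1 for h in parents.values() if h),
            "status_counts": cand_df["status"].value_counts().to_dict()
            if len(cand_df) else {},
        },
    })
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for key, fname in (("candidates", "candidates.tsv"), ("verdicts", "verdicts.tsv"),
                       ("parents", "parents.tsv"), ("repeats", "repeats.tsv"),
                       ("scan", "scan.tsv"), ("scan_family", "scan_family.tsv"),
                       ("families", "families.tsv"),
                       ("transposed_flags", "transposed_flags.tsv"),
                       ("control_flags", "control_flags.tsv")):
        df = report.get(key)
        if isinstance(df, pd.DataFrame) and len(df):
            df.to_csv(outdir / fname, sep="\t", index=False)
    write_gff(report["annot_a"], outdir / "A.coanno.gff3")
    write_gff(report["annot_b"], outdir / "B.coanno.gff3")
    with open(outdir / "summary.txt", "w") as fh:
        for k, v in report["counts"].items():
            fh.write(f"{k}\t{v}\n")
        if report["rate"] is not None:
            r = report["rate"]
            fh.write(f"years_per_event\t{r.years_per_event:.1f}\n")
            fh.write(f"years_per_event_rounded\t{r.rounded_years_per_event}\n")
        enr = report.get("enrichment")
        if enr:
            fh.write("\n# enrichment (transposed vs control)\n")
            for name, res in enr["tests"].items():
                if res is not None:
                    fh.write(f"p_{name}\t{res.p_two_sided:.6g}\n")


def run(config: PipelineConfig) -> dict:
    """Load the configured files, run every stage, write reports."""
    for key in ("genome_a", "annot_a", "genome_b", "annot_b", "genome_o1",
                "annot_o1", "genome_o2", "annot_o2", "regions"):
        path = Path(getattr(config, key))
        if not path.exists():
            raise FileNotFoundError(f"pipeline input {key}: {path} does not exist")
    genome_a = read_fasta(config.genome_a, "A")
    annot_a = read_gff(config.annot_a, genome_a)
    genome_b = read_fasta(config.genome_b, "B")
    annot_b = read_gff(config.annot_b, genome_b)
    outgroups = []
    for gpath, apath, name in ((config.genome_o1, config.annot_o1, "O1"),
                               (config.genome_o2, config.annot_o2, "O2")):
        g = read_fasta(gpath, name)
        outgroups.append((g, read_gff(apath, g)))
    regions = read_regions(config.regions)
    controls = None
    if config.controls:
        controls = [line.strip() for line in open(config.controls)
                    if line.strip()]
    return run_pipeline(genome_a, annot_a, genome_b, annot_b, outgroups, regions,
                        control_genes=controls, config=config.aligner,
                        thr=config.thresholds, outdir=config.outdir,
                        run_scan=config.run_scan)
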