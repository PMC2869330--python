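"""Genome and annotation I/O plus interval utilities shared by all stages.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
1-based closed convention is converted exactly once, at the file boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")

FEATURE_CLASSES = ("gene", "pseudogene", "transposable_element")


class ParseError(ValueError):
    """Raised for malformed FASTA/GFF/region inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A genome: mapping of chromosome name to an uppercase ACGTN string."""

    genome_id: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ParseError(f"chromosome {name!r} in {self.genome_id} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ParseError(
                    f"chromosome {name!r} in {self.genome_id} contains "
                    f"invalid characters: {sorted(bad)}"
                )

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Subsequence [start, end), clamped to the chromosome."""
        seq = self.chromosomes[chromosome]
        return seq[max(0, start) : min(len(seq), end)]

    def length(self, chromosome: str) -> int:
        return len(self.chromosomes[chromosome])


@dataclass
class GeneFeature:
    """An annotated interval: gene, pseudogene, or transposable element.

    ``exons`` are 0-based half-open sub-intervals of [start, end), sorted and
    non-overlapping.  ``family`` is a free-text functional label used only for
    the family tabulations.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    feature_class: str = "gene"
    family: str = "unknown"
    provisional: bool = False
    source_gene_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ParseError(f"{self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.feature_class not in FEATURE_CLASSES:
            raise ParseError(f"{self.gene_id}: unknown feature class {self.feature_class!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = self.start
        for es, ee in exons:
            if es < prev_end or ee > self.end or es >= ee:
                raise ParseError(f"{self.gene_id}: exon ({es},{ee}) violates gene bounds/order")
            prev_end = ee
        self.exons = exons

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return self.chromosome == chromosome and self.start < end and start < self.end


class AnnotationSet:
    """Ordered gene features for one genome with a per-chromosome rank index.

    The rank index numbers features 0..n-1 along each chromosome by start
    coordinate; integer-rank matching in the detector operates on it.
    """

    def __init__(self, genome_id: str, features: list[GeneFeature],
                 genome: GenomeSequence | None = None):
        self.genome_id = genome_id
        if genome is not None:
            for f in features:
                if f.chromosome not in genome.chromosomes:
                    raise ParseError(f"{f.gene_id}: unknown chromosome {f.chromosome!r}")
                if f.end > genome.length(f.chromosome):
                    raise ParseError(f"{f.gene_id}: extends past end of {f.chromosome}")
        self.features = sorted(features, key=lambda f: (f.chromosome, f.start, f.gene_id))
        self._by_id = {f.gene_id: f for f in self.features}
        if len(self._by_id) != len(self.features):
            seen: set[str] = set()
            for f in features:
                if f.gene_id in seen:
                    raise ParseError(f"duplicate feature id {f.gene_id!r}")
                seen.add(f.gene_id)
        self._by_chrom: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            self._by_chrom.setdefault(f.chromosome, []).append(f)
        self._rank: dict[str, tuple[str, int]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, feats in self._by_chrom.items():
            for i, f in enumerate(feats):
                self._rank[f.gene_id] = (chrom, i)
            self._starts[chrom] = [f.start for f in feats]

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneFeature:
        return self._by_id[gene_id]

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chromosome(self, chromosome: str) -> list[GeneFeature]:
        return self._by_chrom.get(chromosome, [])

    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, rank) of a feature."""
        return self._rank[gene_id]

    def at_rank(self, chromosome: str, rank: int) -> GeneFeature | None:
        feats = self._by_chrom.get(chromosome, [])
        if 0 <= rank < len(feats):
            return feats[rank]
        return None

    def overlapping(self, chromosome: str, start: int, end: int) -> list[GeneFeature]:
        """All features intersecting [start, end)."""
        feats = self._by_chrom.get(chromosome, [])
        if not feats:
            return []
        # features are sorted by start; scan a bounded neighbourhood
        idx = bisect.bisect_left(self._starts[chromosome], start)
        out = []
        i = idx - 1
        while i >= 0 and feats[i].end > start:
            out.append(feats[i])
            i -= 1
        out.reverse()
        i = idx
        while i < len(feats) and feats[i].start < end:
            out.append(feats[i])
            i += 1
        return [f for f in out if f.start < end and f.end > start]

    def with_features(self, extra: list[GeneFeature]) -> "AnnotationSet":
        """New AnnotationSet with ``extra`` added and ranks rebuilt."""
        return AnnotationSet(self.genome_id, self.features + list(extra))


@dataclass(frozen=True)
class OrthologousRegion:
    """A pair of intervals asserted orthologous between genomes A and B."""

    region_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def contains_a(self, chromosome: str, start: int, end: int) -> bool:
        return chromosome == self.chrom_a and start >= self.start_a and end <= self.end_a


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeSequence:
    """Read a multi-record FASTA into a :class:`GenomeSequence`.

    Lowercase input is normalized to uppercase; any character outside
    {A,C,G,T,N} or a duplicated/empty record is a :class:`ParseError`.
    """
    path = Path(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise ParseError(f"{path}: record with empty header")
        if name in chroms:
            raise ParseError(f"{path}: duplicate record name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {name!r} is empty")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(f"{path}: record {name!r} contains invalid characters {sorted(bad)}")
        chroms[name] = seq
    if not chroms:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(genome_id or path.stem, chroms)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.chromosomes):
            fh.write(f">{name}\n")
            seq = genome.chromosomes[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff(path: str | Path, genome: GenomeSequence) -> AnnotationSet:
    """Read GFF3 gene/pseudogene/transposable_element + exon features.

    GFF 1-based closed coordinates become 0-based half-open.  Exons must
    reference an already-declared parent feature via ``Parent=``.  Parsing
    is delegated to :mod:`gffutils` (in-memory database).
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                                merge_strategy="error", id_spec="ID")
    except Exception as exc:  # sqlite/gffutils errors on malformed input
        raise ParseError(f"{path}: {exc}") from exc

    def _attr(feat, key, default=None):
        vals = feat.attributes.get(key)
        return vals[0] if vals else default

    feats: dict[str, dict] = {}
    for ftype in FEATURE_CLASSES:
        for feat in db.features_of_type(ftype):
            fid = _attr(feat, "ID")
            if not fid:
                raise ParseError(f"{path}: {ftype} feature at {feat.seqid}:{feat.start} "
                                 "without ID attribute")
            start, end = feat.start - 1, feat.end
            if feat.seqid not in genome.chromosomes:
                raise ParseError(f"{path}: feature {fid} on unknown chromosome {feat.seqid!r}")
            if not (0 <= start < end <= genome.length(feat.seqid)):
                raise ParseError(f"{path}: feature {fid} outside chromosome bounds")
            feats[fid] = dict(
                gene_id=fid,
                chromosome=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                exons=[],
                feature_class=ftype,
                family=_attr(feat, "family", _attr(feat, "Name", "unknown")),
                provisional=_attr(feat, "provisional", "false") == "true",
                source_gene_id=_attr(feat, "source_gene") or None,
            )
    for feat in db.features_of_type("exon"):
        parent = _attr(feat, "Parent")
        if not parent:
            raise ParseError(f"{path}: exon at {feat.seqid}:{feat.start} without Parent")
        if parent not in feats:
            raise ParseError(f"{path}: exon references unknown parent {parent!r}")
        feats[parent]["exons"].append((feat.start - 1, feat.end))
    features = [GeneFeature(**kw) for kw in feats.values()]
    return AnnotationSet(genome.genome_id, features, genome=genome)


def write_gff(annot: AnnotationSet, path: str | Path) -> None:
    """Write features (and exons) back out as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annot.features:
            attrs = [f"ID={f.gene_id}", f"family={f.family}"]
            if f.provisional:
                attrs.append("provisional=true")
                if f.source_gene_id:
                    attrs.append(f"source_gene={f.source_gene_id}")
            fh.write(
                "\t".join(
                    [f.chromosome, "transposcan", f.feature_class, str(f.start + 1),
                     str(f.end), ".", f.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )
            for i, (es, ee) in enumerate(f.exons, 1):
                fh.write(
                    "\t".join(
                        [f.chromosome, "transposcan", "exon", str(es + 1), str(ee),
                         ".", f.strand, ".", f"ID={f.gene_id}.exon{i};Parent={f.gene_id}"]
                    )
                    + "\n"
                )


REGION_COLUMNS = ["region_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]


def read_regions(path: str | Path) -> list[OrthologousRegion]:
    """Orthologous-region list: TSV with 0-based half-open intervals."""
    df = pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS, comment="#")
    regions = []
    for row in df.itertuples(index=False):
        if row.start_a >= row.end_a or row.start_b >= row.end_b:
            raise ParseError(f"region {row.region_id}: empty interval")
        regions.append(OrthologousRegion(str(row.region_id), row.chrom_a, int(row.start_a),
                                         int(row.end_a), row.chrom_b, int(row.start_b),
                                         int(row.end_b)))
    return regions


def write_regions(regions: list[OrthologousRegion], path: str | Path) -> None:
    rows = [[r.region_id, r.chrom_a, r.start_a, r.end_a, r.chrom_b, r.start_b, r.end_b]
            for r in regions]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


def noncoding_sequence(gene: GeneFeature, genome: GenomeSequence) -> str:
    """The gene's genomic span with every exon position replaced by N.

    Alignments against the result can only score on introns and other
    non-exonic positions, which is how noncoding similarity to a parent
    locus is measured.  Features with no exon records (e.g. pseudogene
    fragments) are treated as fully noncoding and returned unmasked.
    """
    span = list(genome.fetch(gene.chromosome, gene.start, gene.end))
    for es, ee in gene.exons:
        for i in range(es - gene.start, ee - gene.start):
            span[i] = "N"
    return "".join(span)


def coding_sequence(gene: GeneFeature, genome: GenomeSequence) -> str:
    """Concatenated exon sequence (the gene span itself if no exons)."""
    if not gene.exons:
        return genome.fetch(gene.chromosome, gene.start, gene.end)
    return "".join(genome.fetch(gene.chromosome, es, ee) for es, ee in gene.exons)


def noncoding_mask(gene: GeneFeature) -> list[tuple[int, int]]:
    """Noncoding sub-intervals of the gene span, genome coordinates."""
    out = []
    pos = gene.start
    for es, ee in gene.exons:
        if es > pos:
            out.append((pos, es))
        pos = ee
    if pos < gene.end:
        out.append((pos, gene.end))
    return out
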