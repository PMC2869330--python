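"""Synthetic genome quartets with a planted-event truth ledger.

An ancestral genome of random multi-exon genes separated by random
intergenic spacers is evolved into two ingroups (A and B, point
substitutions only, jointly ~5% diverged by default) and two deep
outgroups (~35% diverged) that retain the ancestral gene order.  Events
planted on the ingroup lineages -- single-gene duplication-transpositions
into A (with configurable repeat structure and donor retention), gene
losses in B, interrupter insertions into tandem duplications, and
pseudogene/TE insertions -- are recorded exhaustively in a
:class:`SyntheticTruth` ledger, which is the oracle for every pipeline
stage.  Substitution-only divergence keeps the coordinate bookkeeping for
the ledger exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .aligner import is_low_complexity
from .genome_io import (AnnotationSet, GeneFeature, GenomeSequence,
                        OrthologousRegion, write_fasta, write_gff, write_regions)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_FAMILY_POOL = [
    ("unknown", 0.35), ("other", 0.20), ("F-box", 0.08), ("LRR", 0.06),
    ("defensin", 0.05), ("protein kinase family protein", 0.05),
    ("MADS/AGL", 0.03), ("DC1-domain containing", 0.03),
    ("PR peptide", 0.03), ("zinc finger family protein", 0.03),
    ("beta-galactosidase", 0.02), ("nucleic acid binding", 0.02),
    ("RALF family protein", 0.02), ("tRNA-intron endonuclease", 0.02),
    ("small secreted cysteine-rich protein", 0.01),
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic quartet.

    The defaults emulate the motivating study conditions at desk scale: two
    ingroups ~5% diverged (0.05 substitutions/site split evenly across the
    two branches), outgroups at 0.35 substitutions/site, 2 chromosomes of
    200 genes each (~1 Mb/genome), ten planted transpositions into A and
    five losses in B.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 200
    gene_length: tuple[float, float] = (1000.0, 250.0)
    intergenic_length: tuple[float, float] = (1400.0, 400.0)
    ingroup_divergence: float = 0.05
    outgroup_divergence: float = 0.35
    n_transpositions: int = 10
    fraction_with_parent_retained: float = 0.6
    fraction_in_tandem_context: float = 0.3
    fraction_with_flanking_repeats: float = 0.6
    fraction_repeat_carryover: float = 0.5
    fraction_chimeric: float = 0.2
    fraction_inverted: float = 0.15
    repeat_length_range: tuple[int, int] = (15, 400)
    n_losses_in_b: int = 5
    n_interrupters: int = 2
    n_pseudogenes: int = 3
    n_tes: int = 3
    n_control_genes: int = 60
    carried_flank: int = 100    # donor flank bp carried along with the gene
    min_site_spacing: int = 5   # gene-index spacing between planted sites
    min_donor_distance: int = 30  # gene-index distance donor <-> insertion

    def __post_init__(self):
        for name in ("fraction_with_parent_retained", "fraction_in_tandem_context",
                     "fraction_with_flanking_repeats", "fraction_repeat_carryover",
                     "fraction_chimeric", "fraction_inverted"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.ingroup_divergence < 0 or self.outgroup_divergence < 0:
            raise ValueError("divergences must be >= 0")


@dataclass
class SyntheticTruth:
    """Exhaustive ledger of planted events.

    Besides substitutions, the two ingroup genomes differ only by the
    events listed here.  ``control_genes`` are untouched genes sampled away
    from every event site, for use as the non-transposed comparison set.
    """

    events: list[dict] = field(default_factory=list)
    control_genes: list[str] = field(default_factory=list)

    def of_type(self, event_type: str) -> list[dict]:
        return [e for e in self.events if e["type"] == event_type]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"events": self.events, "control_genes": self.control_genes},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(events=d["events"], control_genes=d["control_genes"])


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _nonsimple_sequence(rng: np.random.Generator, n: int) -> str:
    """Random sequence re-drawn until it passes the low-complexity filter."""
    for _ in range(20):
        seq = random_sequence(rng, n)
        if n < 8 or not is_low_complexity(seq):
            return seq
    raise RuntimeError("could not draw a non-simple sequence")


def mutate(seq: str, rate: float, seed_or_rng) -> str:
    """Point substitutions: each position independently replaced with

    probability ``rate`` by a uniformly chosen *different* base; N
    positions are left untouched.  Deterministic under a seed.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    is_base = np.isin(arr, _BASES)
    hit = (rng.random(len(arr)) < rate) & is_base
    idx = np.nonzero(hit)[0]
    if len(idx):
        # map ACGT to 0..3 via lookup
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            lut[b] = i
        cur = lut[arr[idx]]
        new = (cur + 1 + rng.integers(0, 3, len(idx))) % 4
        arr[idx] = _BASES[new]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------


def _draw_len(rng, mean_sd, lo):
    mean, sd = mean_sd
    return max(lo, int(rng.normal(mean, sd)))


def _make_gene(rng: np.random.Generator, gene_id: str, family: str,
               length: int) -> dict:
    """A gene record: multi-exon (introns of ~80 bp) so that every gene has

    alignable noncoding sequence.
    """
    n_exons = int(rng.integers(2, 4))
    intron = 80
    coding = length - intron * (n_exons - 1)
    cuts = np.sort(rng.integers(1, max(2, coding - 1), n_exons - 1))
    exon_lens = np.diff(np.concatenate(([0], cuts, [coding])))
    exon_lens = np.maximum(exon_lens, 30)
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el) + (intron if i < n_exons - 1 else 0)
    length = exons[-1][1]
    return {
        "id": gene_id,
        "family": family,
        "feature_class": "gene",
        "strand": "+" if rng.random() < 0.5 else "-",
        "exons": exons,
        "seq": random_sequence(rng, length),
    }


def _draw_family(rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for fam, p in _FAMILY_POOL:
        acc += p
        if u < acc:
            return fam
    return "unknown"


def _build_ancestor(cfg: SimConfig, rng: np.random.Generator) -> list[list[dict]]:
    """Per-chromosome slot lists alternating intergenic and gene slots."""
    chroms = []
    gid = 0
    for _ in range(cfg.n_chromosomes):
        slots = []
        slots.append({"kind": "seq", "seq": random_sequence(
            rng, _draw_len(rng, cfg.intergenic_length, 200))})
        for _ in range(cfg.genes_per_chromosome):
            gid += 1
            gene = _make_gene(rng, f"g{gid:05d}", _draw_family(rng),
                              _draw_len(rng, cfg.gene_length, 400))
            slots.append({"kind": "gene", "gene": gene})
            slots.append({"kind": "seq", "seq": random_sequence(
                rng, _draw_len(rng, cfg.intergenic_length, 200))})
        chroms.append(slots)
    return chroms


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------


def _gene_slot_indices(slots: list[dict]) -> list[int]:
    return [i for i, s in enumerate(slots) if s["kind"] == "gene"]


class _SitePicker:
    """Deterministic sampler of event sites with spacing constraints."""

    def __init__(self, cfg: SimConfig, chroms: list[list[dict]],
                 rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.used: dict[int, list[int]] = {c: [] for c in range(len(chroms))}
        self.pool = []
        for c, slots in enumerate(chroms):
            gidx = _gene_slot_indices(slots)
            # avoid chromosome ends where flanking windows would truncate
            for rank in range(4, len(gidx) - 4):
                self.pool.append((c, rank))
        order = rng.permutation(len(self.pool))
        self.queue = [self.pool[i] for i in order]

    def take(self, exclude_near: tuple[int, int] | None = None) -> tuple[int, int]:
        spacing = self.cfg.min_site_spacing
        far = self.cfg.min_donor_distance
        while self.queue:
            c, rank = self.queue.pop()
            if any(abs(rank - r) < spacing for r in self.used[c]):
                continue
            if exclude_near is not None:
                ec, er = exclude_near
                if c == ec and abs(rank - er) < far:
                    continue
            self.used[c].append(rank)
            return c, rank
        raise ValueError("configuration demands more event sites than available loci")


def _choose_repeat_origin(cfg: SimConfig, rng) -> str:
    u = rng.random()
    if u < cfg.fraction_repeat_carryover:
        return "donor_carryover"
    u -= cfg.fraction_repeat_carryover
    if u < cfg.fraction_chimeric:
        return "chimeric"
    rest = max(1e-9, 1.0 - cfg.fraction_repeat_carryover - cfg.fraction_chimeric)
    return "target_homology" if (u - cfg.fraction_chimeric) < rest / 2 else "de_novo"


def generate_quartet(cfg: SimConfig | None = None):
    """Build the four genomes, the region list and the truth ledger.

    Returns ``(genomes, regions, truth)`` where ``genomes`` maps
    ``"A"/"B"/"O1"/"O2"`` to ``(GenomeSequence, AnnotationSet)``.
    """
    cfg = cfg or SimConfig()
    root = np.random.default_rng(cfg.seed)
    rng_anc, rng_events, rng_mut_a, rng_mut_b, rng_o1, rng_o2, rng_ctrl = \
        [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(7)]

    ancestor = _build_ancestor(cfg, rng_anc)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # per-genome copies of the slot lists (shallow slot copies; slots replaced
    # wholesale when modified, never mutated in place)
    slots_a = [list(slots) for slots in ancestor]
    slots_b = [list(slots) for slots in ancestor]

    picker = _SitePicker(cfg, ancestor, rng_events)
    truth = SyntheticTruth()
    touched: set[str] = set()

    def gene_at(chrom_i: int, rank: int) -> tuple[int, dict]:
        gidx = _gene_slot_indices(ancestor[chrom_i])
        slot_i = gidx[rank]
        return slot_i, ancestor[chrom_i][slot_i]["gene"]

    def neighbours(chrom_i: int, rank: int) -> list[dict]:
        gidx = _gene_slot_indices(ancestor[chrom_i])
        out = []
        for r in (rank - 1, rank + 1):
            if 0 <= r < len(gidx):
                out.append(ancestor[chrom_i][gidx[r]]["gene"])
        return out

    def flank_of(chrom_i: int, slot_i: int, side: str, n: int, offset: int = 0) -> str:
        """Sequence just up/downstream of a gene slot in the ancestor."""
        seq = ancestor[chrom_i][slot_i - 1 if side == "up" else slot_i + 1]["seq"]
        if side == "up":
            end = len(seq) - offset
            return seq[max(0, end - n): end]
        return seq[offset: offset + n]

    def insert_cassette(slots: list[list[dict]], chrom_i: int, gap_rank: int,
                        pieces: list[dict]) -> None:
        """Split the intergenic slot after gene ``gap_rank`` and splice."""
        gidx = _gene_slot_indices(ancestor[chrom_i])
        gap_slot = gidx[gap_rank] + 1  # intergenic slot right after the gene
        target = slots[chrom_i]
        pos = target.index(ancestor[chrom_i][gap_slot])
        gap_seq = ancestor[chrom_i][gap_slot]["seq"]
        mid = len(gap_seq) // 2
        target[pos : pos + 1] = ([{"kind": "seq", "seq": gap_seq[:mid]}] + pieces
                                 + [{"kind": "seq", "seq": gap_seq[mid:]}])

    n_sites = (2 * cfg.n_transpositions + cfg.n_losses_in_b
               + 2 * cfg.n_interrupters + 2 * cfg.n_pseudogenes + cfg.n_tes)
    capacity = cfg.n_chromosomes * max(0, cfg.genes_per_chromosome - 8)
    if n_sites * cfg.min_site_spacing > capacity:
        raise ValueError("configuration demands more events than available loci")

    next_id = [cfg.n_chromosomes * cfg.genes_per_chromosome + 1]

    def fresh_id() -> str:
        next_id[0] += 1
        return f"g{next_id[0]:05d}"

    # --- transpositions into A -------------------------------------------
    for k in range(cfg.n_transpositions):
        donor_c, donor_rank = picker.take()
        ins_c, ins_rank = picker.take(exclude_near=(donor_c, donor_rank))
        donor_slot, donor = gene_at(donor_c, donor_rank)
        retained = rng_events.random() < cfg.fraction_with_parent_retained
        tandem_ctx = rng_events.random() < cfg.fraction_in_tandem_context
        with_repeats = rng_events.random() < cfg.fraction_with_flanking_repeats

        if tandem_ctx:
            fam = donor["family"] if donor["family"] not in ("unknown", "other") \
                else "F-box"
            donor["family"] = fam
            for nb in neighbours(donor_c, donor_rank):
                nb["family"] = fam
                break

        new_gene = dict(donor)
        new_gene["id"] = fresh_id()
        flank_l = flank_of(donor_c, donor_slot, "up", cfg.carried_flank)
        flank_r = flank_of(donor_c, donor_slot, "down", cfg.carried_flank)

        repeat_structure = "none"
        repeat_origin = "none"
        rep_seq = ""
        if with_repeats:
            rlen = int(rng_events.integers(cfg.repeat_length_range[0],
                                           cfg.repeat_length_range[1] + 1))
            repeat_origin = _choose_repeat_origin(cfg, rng_events)
            gidx_ins = _gene_slot_indices(ancestor[ins_c])
            gap_seq = ancestor[ins_c][gidx_ins[ins_rank] + 1]["seq"]
            mid = len(gap_seq) // 2
            if repeat_origin == "donor_carryover":
                rep_seq = flank_of(donor_c, donor_slot, "up", rlen,
                                   offset=cfg.carried_flank)
            elif repeat_origin == "target_homology":
                rep_seq = gap_seq[mid : mid + rlen]
            elif repeat_origin == "chimeric":
                half = rlen // 2
                rep_seq = (flank_of(donor_c, donor_slot, "up", half,
                                    offset=cfg.carried_flank)
                           + gap_seq[mid : mid + (rlen - half)])
            else:
                rep_seq = _nonsimple_sequence(rng_events, rlen)
            if len(rep_seq) < cfg.repeat_length_range[0] or is_low_complexity(rep_seq):
                rep_seq = _nonsimple_sequence(rng_events, rlen)
                repeat_origin = "de_novo"
            inverted = rng_events.random() < cfg.fraction_inverted
            repeat_structure = "inverted" if inverted else "direct"

        if repeat_structure == "direct":
            rep_down = rep_seq
        elif repeat_structure == "inverted":
            from .aligner import reverse_complement
            rep_down = reverse_complement(rep_seq)
        else:
            rep_down = ""

        pieces = [{"kind": "seq", "seq": rep_seq + flank_l},
                  {"kind": "gene", "gene": new_gene},
                  {"kind": "seq", "seq": flank_r + rep_down}]
        insert_cassette(slots_a, ins_c, ins_rank, pieces)
        if not retained:
            donor_anc_slot = ancestor[donor_c][donor_slot]
            sa = slots_a[donor_c]
            sa.remove(donor_anc_slot)
        touched.update({donor["id"], new_gene["id"]})
        truth.events.append({
            "type": "transposition_A",
            "gene_id": new_gene["id"],
            "donor_gene_id": donor["id"],
            "donor_chrom": chrom_names[donor_c],
            "insertion_chrom": chrom_names[ins_c],
            "insertion_after_rank": ins_rank,
            "parent_retained": bool(retained),
            "tandem_context": bool(tandem_ctx),
            "repeat_structure": repeat_structure,
            "repeat_origin": repeat_origin,
            "repeat_length": len(rep_seq),
        })

    # --- losses in B ------------------------------------------------------
    for _ in range(cfg.n_losses_in_b):
        c, rank = picker.take()
        slot_i, gene = gene_at(c, rank)
        slots_b[c].remove(ancestor[c][slot_i])
        touched.add(gene["id"])
        truth.events.append({
            "type": "loss_B",
            "gene_id": gene["id"],
            "chrom": chrom_names[c],
        })

    # --- interrupters (tandem duplication in A with an insertion inside) --
    for _ in range(cfg.n_interrupters):
        host_c, host_rank = picker.take()
        src_c, src_rank = picker.take(exclude_near=(host_c, host_rank))
        host_slot, host = gene_at(host_c, host_rank)
        _, src = gene_at(src_c, src_rank)
        host_copy = dict(host)
        host_copy["id"] = fresh_id()
        inter = dict(src)
        inter["id"] = fresh_id()
        spacer1 = _nonsimple_sequence(rng_events, 200)
        spacer2 = _nonsimple_sequence(rng_events, 200)
        sa = slots_a[host_c]
        pos = sa.index(ancestor[host_c][host_slot])
        sa[pos : pos + 1] = [
            {"kind": "gene", "gene": host},
            {"kind": "seq", "seq": spacer1},
            {"kind": "gene", "gene": inter},
            {"kind": "seq", "seq": spacer2},
            {"kind": "gene", "gene": host_copy},
        ]
        touched.update({host["id"], host_copy["id"], inter["id"], src["id"]})
        truth.events.append({
            "type": "interrupter",
            "gene_id": inter["id"],
            "source_gene_id": src["id"],
            "tandem_host_id": host["id"],
            "tandem_copy_id": host_copy["id"],
            "chrom": chrom_names[host_c],
        })

    # --- pseudogene / TE insertions into A --------------------------------
    for event_type, count in (("pseudogene", cfg.n_pseudogenes), ("TE", cfg.n_tes)):
        for _ in range(count):
            ins_c, ins_rank = picker.take()
            if event_type == "pseudogene":
                src_c, src_rank = picker.take(exclude_near=(ins_c, ins_rank))
                _, src = gene_at(src_c, src_rank)
                rec = {
                    "id": fresh_id(), "family": src["family"],
                    "feature_class": "pseudogene", "strand": src["strand"],
                    "exons": [],
                    "seq": mutate(src["seq"], 0.05, rng_events),
                }
                touched.add(src["id"])
            else:
                rec = {
                    "id": fresh_id(), "family": "transposable element",
                    "feature_class": "transposable_element", "strand": "+",
                    "exons": [],
                    "seq": _nonsimple_sequence(rng_events, 800),
                }
            insert_cassette(slots_a, ins_c, ins_rank,
                            [{"kind": "gene", "gene": rec}])
            touched.add(rec["id"])
            truth.events.append({
                "type": event_type,
                "gene_id": rec["id"],
                "insertion_chrom": chrom_names[ins_c],
                "insertion_after_rank": ins_rank,
            })

    # --- assembly ---------------------------------------------------------
    def assemble(slot_lists, genome_id: str, rate: float, rng_mut) -> tuple:
        chroms: dict[str, str] = {}
        feats: list[GeneFeature] = []
        for c, slots in enumerate(slot_lists):
            parts = []
            pos = 0
            for slot in slots:
                if slot["kind"] == "seq":
                    parts.append(slot["seq"])
                    pos += len(slot["seq"])
                else:
                    g = slot["gene"]
                    seq = g["seq"]
                    feats.append(GeneFeature(
                        gene_id=g["id"], chromosome=chrom_names[c], start=pos,
                        end=pos + len(seq), strand=g["strand"],
                        exons=tuple((pos + s, pos + e) for s, e in g["exons"]),
                        feature_class=g["feature_class"], family=g["family"]))
                    parts.append(seq)
                    pos += len(seq)
            seq = "".join(parts)
            if rate > 0:
                seq = mutate(seq, rate, rng_mut)
            chroms[chrom_names[c]] = seq
        genome = GenomeSequence(genome_id, chroms)
        return genome, AnnotationSet(genome_id, feats, genome=genome)

    half = cfg.ingroup_divergence / 2.0
    genomes = {
        "A": assemble(slots_a, "A", half, rng_mut_a),
        "B": assemble(slots_b, "B", half, rng_mut_b),
        "O1": assemble(ancestor, "O1", cfg.outgroup_divergence, rng_o1),
        "O2": assemble(ancestor, "O2", cfg.outgroup_divergence, rng_o2),
    }

    # final coordinates into the ledger
    annot_a, annot_b = genomes["A"][1], genomes["B"][1]
    for ev in truth.events:
        gid = ev["gene_id"]
        if gid in annot_a:
            f = annot_a[gid]
            ev["locus_a"] = [f.chromosome, f.start, f.end]
        if ev["type"] == "transposition_A" and ev["donor_gene_id"] in annot_a:
            f = annot_a[ev["donor_gene_id"]]
            ev["donor_locus_a"] = [f.chromosome, f.start, f.end]
        if ev["type"] == "loss_B" and gid in annot_a:
            pass  # locus_a above is the surviving ancestral copy

    regions = [OrthologousRegion(f"r{i + 1}", name, 0,
                                 genomes["A"][0].length(name), name, 0,
                                 genomes["B"][0].length(name))
               for i, name in enumerate(chrom_names)]

    # control genes: untouched, away from chromosome ends
    candidates = [f.gene_id for f in annot_a.features
                  if f.gene_id not in touched and f.feature_class == "gene"]
    order = rng_ctrl.permutation(len(candidates))
    truth.control_genes = sorted(candidates[i] for i in
                                 order[: cfg.n_control_genes])
    return genomes, regions, truth


def write_quartet(outdir: str | Path, cfg: SimConfig | None = None):
    """Generate a quartet and write FASTA/GFF3/regions TSV/truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, regions, truth = generate_quartet(cfg)
    for name, (genome, annot) in genomes.items():
        write_fasta(genome, outdir / f"{name}.fasta")
        write_gff(annot, outdir / f"{name}.gff3")
    write_regions(regions, outdir / "regions.tsv")
    truth.to_json(outdir / "truth.json")
    with open(outdir / "controls.txt", "w") as fh:
        fh.write("\n".join(truth.control_genes) + "\n")
    return genomes, regions, truth
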