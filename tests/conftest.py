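"""Shared fixtures: deterministic random sequences, toy genome builder,

and a session-scoped synthetic quartet with its pipeline report.
"""

from __future__ import annotations

import numpy as np
import pytest

from transposcan.genome_io import AnnotationSet, GeneFeature, GenomeSequence
from transposcan.pipeline import run_pipeline
from transposcan.synthetic import SimConfig, generate_quartet


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


_MISMATCH_MAP = str.maketrans("ACGT", "CATG")


def mismatch_everywhere(seq: str) -> str:
    """Per-position remap guaranteeing no position matches the original,

    without creating low-complexity sequence.  Used to build alignment
    contexts that cannot extend past a planted repeat.
    """
    return seq.translate(_MISMATCH_MAP)


def build_genome(gene_specs, spacer: int = 400, genome_id: str = "T",
                 chrom: str = "chr1", seed: int = 0,
                 prefix: str | None = None, suffix: str | None = None):
    """Assemble a single-chromosome genome from gene specs.

    Each spec: dict with ``id``, ``seq`` and optional ``exons`` (relative),
    ``feature_class``, ``family``, ``strand``.  Genes are separated by
    random spacers (or explicit ``spacer_seqs``).
    """
    rng = np.random.default_rng(seed)
    parts = [prefix if prefix is not None else random_seq(rng, spacer)]
    feats = []
    pos = len(parts[0])
    for spec in gene_specs:
        seq = spec["seq"]
        exons = tuple((pos + s, pos + e) for s, e in spec.get("exons", ()))
        feats.append(GeneFeature(
            gene_id=spec["id"], chromosome=chrom, start=pos, end=pos + len(seq),
            strand=spec.get("strand", "+"), exons=exons,
            feature_class=spec.get("feature_class", "gene"),
            family=spec.get("family", "unknown")))
        parts.append(seq)
        pos += len(seq)
        sp = spec.get("spacer_after")
        sp = sp if sp is not None else random_seq(rng, spacer)
        parts.append(sp)
        pos += len(sp)
    if suffix is not None:
        parts.append(suffix)
    genome = GenomeSequence(genome_id, {chrom: "".join(parts)})
    return genome, AnnotationSet(genome_id, feats, genome=genome)


SMALL_SIM = SimConfig(seed=7, n_chromosomes=2, genes_per_chromosome=60,
                      n_transpositions=4, n_losses_in_b=2, n_interrupters=1,
                      n_pseudogenes=1, n_tes=1, n_control_genes=12)


@pytest.fixture(scope="session")
def small_quartet():
    """A reduced synthetic quartet shared across the integration tests."""
    genomes, regions, truth = generate_quartet(SMALL_SIM)
    return genomes, regions, truth


@pytest.fixture(scope="session")
def small_report(small_quartet):
    genomes, regions, truth = small_quartet
    (ga, aa), (gb, ab) = genomes["A"], genomes["B"]
    return run_pipeline(ga, aa, gb, ab, [genomes["O1"], genomes["O2"]], regions,
                        control_genes=truth.control_genes, run_scan=True)
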