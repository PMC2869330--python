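# transposcan

Detection and characterization of recently transposed genes by comparing
two closely related genomes against two deeper outgroups.

## The problem

Single non-transposon genes move to unlinked genomic positions
surprisingly often. Comparing two genomes that diverged only recently
(call them A and B, ~5 MY apart, ~5% nucleotide divergence) exposes such
events before mutation erodes their signatures: a gene present between two
flanking genes in A but absent between those flankers' orthologs in B is a
candidate transposition. Two more distant outgroup genomes that retain the
ancestral gene order distinguish a true insertion in the A lineage from a
loss in B. Because the events are recent, the donor ("parent") locus often
still exists and still shares *noncoding* (intronic/flanking) sequence with
the moved copy, and the moved copy is frequently bracketed by direct
repeats whose sequence can be traced to the donor flanks and/or to the
pre-insertion target site — the signature of excision as a circle by
intrachromosomal recombination and re-insertion into homologous sequence.

`transposcan` implements that entire analysis:

1. **Co-annotation** — features annotated in one genome but not the other
   are projected as provisional features, so annotation asymmetry is not
   mistaken for gene movement.
2. **Detection (flanking gene method)** — all-vs-genome local alignment
   (built-in seed-and-extend engine, word size 7, E ≤ 0.1), hits
   "dissolved" per gene pair and kept when the merged length ≥ 96 bp, gene
   identities converted to integer ranks per chromosome, and rank windows
   of ±3 genes scanned for unaccounted-for positions: from ortholog pairs
   `[(1, 123), (2, 125)]` the gene at subject position 124 is reported
   missing. Candidates then pass a fixed filter cascade: inside a known
   orthologous region; not a pseudogene/TE; no residual alignment ≥ 15 bp
   of the gene inside the subject inter-flanker gap (which would instead
   suggest loss in B); flanking genes with distinct orthologs (otherwise
   the gene is an "interrupter" inside a tandem array).
3. **Outgroup confirmation** — the gene's coding sequence and its 15 kb
   flanks are located in each outgroup; a gene found only away from the
   flank-defined syntenous region is non-ancestral. Confirmation requires
   *both* outgroups to agree.
4. **Parentage** — best genome-wide hit outside the gene itself, qualified
   by ≥ 75% identity over ≥ 50 bp of noncoding sequence.
5. **Flanking repeats** — ~500 bp windows up/downstream compared against
   each other; hits at least as significant as a 15/15 bp exact match
   (Karlin–Altschul E-value floor), excluding simple sequence, reported as
   direct or inverted repeat pairs; each repeat is checked for presence at
   the parent locus and at the orthologous target window in B, including
   the chimeric (part-donor, part-target) configuration. A genome-wide
   scan mode searches 2 kb windows for 30–400 bp direct repeats around
   every gene.
6. **Statistics** — two-sided exact 2×2 tests by full hypergeometric
   enumeration (exact integer arithmetic), per-family tabulations, and the
   transposition-rate estimate (divergence · 10⁶ / events, e.g. 226 events
   over 5 MY ≈ one transposition every 22,000 years).

A synthetic-data module generates genome quartets (ancestor → two ingroups
+ two outgroups, substitution-only divergence) with planted
transpositions, losses, interrupters, pseudogenes and TEs, and an
exhaustive truth ledger, so every stage is testable without external data.

## Worked example

```python
from transposcan import SimConfig, generate_quartet, run_pipeline

genomes, regions, truth = generate_quartet(SimConfig(seed=1))
(ga, aa), (gb, ab) = genomes["A"], genomes["B"]
report = run_pipeline(ga, aa, gb, ab, [genomes["O1"], genomes["O2"]],
                      regions, control_genes=truth.control_genes)
print(report["counts"])
```

prints (seed 1, default study conditions — 2 chromosomes × 200 genes per
genome, 0.05/0.35 ingroup/outgroup divergence, 10 planted transpositions,
5 losses in B):

```
{'provisional_features': 0, 'candidates_total': 23, 'candidates_retained': 15,
 'confirmed': 10, 'with_parent': 8,
 'status_counts': {'candidate': 15, 'discarded_pseudogene_or_TE': 6,
                   'interrupter': 2}}
```

All 23 candidates are planted events: the 10 transpositions plus the 5
losses survive the filters (losses are indistinguishable from insertions
without outgroups), the 6 pseudogene/TE insertions are discarded by the
feature-class filter, and the 2 interrupters are recognized by their
identical flanker orthologs. Outgroup confirmation then keeps exactly the
10 true insertions (`confirmed`) and discards the 5 losses as ancestral.
8 of the 10 confirmed genes have a qualifying parent locus — the planted
donor — and `report["repeats"]` lists their flanking repeats with
carryover/target flags.

The same pipeline runs from files (FASTA + GFF3 + regions TSV) via the CLI:

```bash
transposcan simulate --outdir quartet --seed 1
transposcan run --config run.yaml          # paths + thresholds in YAML
```

with stage subcommands (`coanno`, `detect`, `confirm`, `parents`,
`repeats`, `scan`, `stats`) operating on the intermediate TSVs.

## Layout

| module | role |
|---|---|
| `genome_io` | FASTA/GFF3/region I/O, interval arithmetic, coding/noncoding masks |
| `aligner` | seed-and-extend local alignment, E-values, DUST-style filter |
| `coanno` | cross-genome projection of unannotated homologs |
| `detector` | hit dissolving, flanking-gene scan, candidate filters |
| `outgroup` | ancestral/non-ancestral position calls, two-outgroup rule |
| `parentage` | donor-locus search by noncoding similarity |
| `repeats` | flanking direct/inverted repeats, context flags, genome scan |
| `stats` | exact 2×2 tests, family tables, rate estimate |
| `synthetic` | genome-quartet simulator with planted-event truth ledger |
| `pipeline`, `cli` | orchestration, YAML config, subcommands |

See `docs/methods.md` for the model, parameter defaults and limitations.
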