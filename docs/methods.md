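# Methods

This note documents the models and procedures implemented in
`transposcan`, the parameter defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerical choices that
matter for reproducing a run.

## Detection model

The unit of evidence is positional: gene order. Two genomes that diverged
recently share long runs of colinear genes; a single-gene transposition
breaks colinearity at exactly one rank. Genes are paired across genomes by
sequence, not by name:

* every gene span (introns included) is aligned genome-wide with the
  built-in seed-and-extend engine (word size 7, E-value cutoff 0.1);
* hits are attributed to the annotated feature they overlap most, and all
  hits to one (query gene, subject gene) pair are **dissolved** into a
  single pairing — overlapping query intervals merged, pairs kept only
  when the merged length is ≥ 96 bp;
* each query gene keeps its best pairing (largest merged length, then best
  E-value, then lexicographic subject id).

Gene identities are then replaced by integer ranks along each chromosome
(provisional features included) and windows of ±3 genes are scanned. For a
gene at rank r whose neighbours at ranks r₁ < r < r₂ pair to *adjacent*
subject ranks, with the gene itself pairing nowhere inside that subject
neighbourhood, the gene is unaccounted for in the subject genome and
becomes a candidate. The same scan run with the genomes swapped yields
subject-side gains. When one gene sits between several alternative flanker
pairs, the tightest window wins; this is what routes a gene inserted
between two tandem copies (which both pair to the same subject gene) into
the interrupter classification rather than a wider, misleading window.

Candidate filters run in a fixed order, and each candidate receives
exactly one terminal status:

1. outside every listed orthologous region → discarded (unverifiable);
2. pseudogene or transposable element → discarded;
3. the candidate's sequence aligns ≥ 15 bp inside the subject
   inter-flanker gap (gap plus 200 bp of noncoding margin into each
   flanker, exons masked) → discarded as possible loss in the subject
   genome rather than gain in the query;
4. the two flanker orthologs are the same subject gene → "interrupter"
   (a gene inside a tandem array; positional verification impossible).

## Outgroup confirmation

For each retained candidate, the coding sequence and the two 15 kb flanks
(gene excluded) are searched in each outgroup. The flanks locate the
syntenous region (the highest-scoring cluster of flank hits); the gene
call is then:

* no gene hit anywhere → `no_gene_hit`;
* a gene hit inside the flank region (± the 15 kb buffer) →
  `ancestral_position`;
* gene hits only elsewhere → `gene_elsewhere`;
* flanks find no region → `unplaceable` (conservatively discarded).

A candidate is a **confirmed insertion** only when both outgroups
independently return `gene_elsewhere`. Dropping one outgroup can only
grow the confirmed set; the rule is an intersection.

Outgroup searches use a relaxed scoring profile: match/mismatch +1/−1,
E-value cutoff 1.0, λ = ln 3 (the exact ungapped Karlin–Altschul solution
for ±1 scoring at uniform base composition; K is approximate at 0.333).
The default +1/−3 profile has negative expected score per aligned column
at ~35% divergence and cannot extend through outgroup homology at all;
±1 keeps the drift positive down to 50% identity. Gene-hit clusters must
additionally reach a score of max(25, 0.05 × CDS length): with E ≤ 1.0,
chance hits near the significance floor would otherwise occasionally
masquerade as gene hits for genes truly absent from an outgroup.

## Alignment engine

Exact words of length 7 seed ungapped extensions under an x-drop rule
(default 20); seeds already covered by an extension on the same diagonal
are skipped. Collinear HSPs separated by gaps ≤ 50 bp are then chained
with affine penalties (open −5, extend −2; the residual unaligned stretch
costs one mismatch per column), which is the gapped step — chained HSPs
count gap columns in their aligned length. E-values use the ungapped
Karlin–Altschul form E = K·m·n·e^(−λS) with λ = 1.374, K = 0.711 for the
default +1/−3 scoring. N columns score as mismatches and extension stops
at a run of 10 Ns, so hard-masked input cannot seed or bridge alignments.

Low complexity is handled twice: a DUST-style triplet score (windows of
64, threshold 2.0) masks query windows, and HSPs with more than half of
their query columns masked are dropped; `is_low_complexity` additionally
flags short-period (1–3 bp) tandem repeats by autocorrelation (≥ 85%
matching at lag 1–3). Repeat-threshold scores ("at least as significant
as a 15/15 bp exact match") are realized as the smallest integer score
whose E-value does not exceed that of score 15·match in the same search
space, so an imperfect-but-longer repeat qualifies.

All searches are deterministic: seeds are processed in sorted diagonal
order, ties in cluster scores resolve by leftmost subject coordinate, and
results are reproducible run-to-run.

## Parent loci and flanking repeats

The parent search aligns the gene span genome-wide, drops hits overlapping
the gene itself, clusters the rest by locus and takes the best-scoring
cluster. Identity is then measured **only on noncoding columns** (gene
span minus exons; features without exon records count as fully noncoding)
of ungapped HSPs, where query and subject columns map 1:1; pieces shorter
than 20 bp are ignored and the remainder summed. A parent qualifies at
≥ 75% identity over ≥ 50 bp (a strict-inequality switch is provided, since
">75%" and "higher than 75%" both appear as phrasings of the threshold).
The tandem flag is positional-plus-family: another gene of the same
(non-"unknown") family within 5 ranks.

Flanking repeats compare the 500 bp windows immediately up- and
downstream of the gene (both orientations; forward hits are direct
repeats, reverse hits inverted). Repeat context is classified by
re-aligning the upstream repeat copy against the parent locus ± 2 kb
(`present_at_parent`, carryover out of the donor site) and against the
genome-B inter-flanker window ± 2 kb (`present_at_ortholog_target`,
homology that could have seeded the insertion); when the best parent hit
and the best target hit cover essentially disjoint portions of the repeat
(≤ 25% mutual overlap of the shorter), the repeat is flagged chimeric.
The genome-wide scan mode uses 2 kb windows anchored at coding-sequence
bounds, direct orientation only, and reports aligned lengths within
30–400 bp; length classes in the per-gene tables use strict inequalities
(> 15 bp, > 30 bp).

## Statistics

The 2×2 test is a two-sided exact (Fisher-type) test: all tables with the
observed margins whose hypergeometric point probability does not exceed
the observed one contribute to p. The enumeration uses exact integer
combinatorics — ties are compared on integer products, not floats — and a
chi-square variant is provided for sensitivity analysis. The odds ratio is
(a·d)/(b·c) with a 0.5 continuity correction when any cell is zero.
Percentages print at one decimal place; family tables aggregate families
below a minimum membership (2 in transposed-gene mode, 5 in genome-scan
mode) into "Other", with empty labels counted as "unknown". The
transposition rate is divergence·10⁶/events, reported rounded to two
significant figures. No multiple-testing correction is applied.

## Synthetic data: what it emulates and what it does not

The generator builds an ancestral genome of random multi-exon genes
(2–3 exons, 80 bp introns, lengths ~N(1000, 250) clipped at 400 bp)
separated by random spacers (~N(1400, 400)), on 2 chromosomes of 200
genes (~1 Mb/genome) by default — small enough for the full pipeline to
run in a few minutes on one CPU. Divergence is substitution-only
(Jukes–Cantor-style: each position substituted with the configured
probability to a uniformly chosen different base): 0.05 split evenly
across the two ingroup branches, 0.35 on each outgroup branch. Keeping
indels out makes every coordinate in the truth ledger exact; it also
means the identity thresholds are exercised by substitutions alone.

Planted events:

* **Transposition into A** — a donor gene is copied (introns plus 100 bp
  of donor flank on each side, the DNA-level signature) into an
  intergenic site far from the donor (≥ 30 gene ranks or another
  chromosome, so outgroup calls are unambiguous). 60% of donors are
  retained (the rest deleted from A, emulating segregational loss of the
  donor allele); 60% of insertions carry flanking repeats of 15–400 bp,
  drawn as donor-flank copies (carryover), copies of target-site sequence
  (homology), half-and-half chimeras, or novel sequence, in direct (85%)
  or inverted orientation, and re-drawn if low-complexity so detectability
  is guaranteed by construction.
* **Loss in B** — a gene deleted from B; surfaces as an A-side candidate
  and must be discarded by the outgroups.
* **Interrupter** — a tandem duplication created on the A lineage with a
  foreign gene inserted between the two copies. B retains a single copy,
  so both A copies pair to the same B gene and the candidate in between
  shows identical flanker orthologs — the configuration the
  flanker-identity rule detects. (Placing the tandem pair in the ancestor
  would let each copy pair 1:1 with its own ortholog and the rule would
  never fire; the A-lineage placement is the scenario the rule is for.)
* **Pseudogene / TE insertions** — exercised solely so the feature-class
  filter has something to discard.

Event sites keep ≥ 5 gene ranks of separation, and chromosome ends are
avoided. Control genes are sampled away from every event.

What passing tests on this generator do **not** show about real data:
no indels or rearrangements other than the planted events (real synteny
is noisier); annotation is complete and consistent by construction
(co-annotation is exercised by dedicated fixtures instead); outgroups
retain perfect ancestral gene order; repeat divergence equals background
divergence; and gene/intergenic sequence is i.i.d. random, so there are
no gene families with genuinely similar sequences, no segmental
duplications, and far less low-complexity sequence than in a real plant
genome.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; GFF3's 1-based closed
  convention is converted once at the file boundary.
* "Consecutive" subject ranks are evaluated on the rank index *including*
  provisional features; identical subject ranks (distance 0) are treated
  as the interrupter configuration.
* Ties everywhere resolve deterministically: highest score, then leftmost
  coordinate, then lexicographic id.
* Genes at chromosome ends get truncated flank windows; windows shorter
  than the word size return no repeats. Candidates whose flankers lack
  orthologs are discarded as unverifiable rather than erroring.
* The reference p-values attached to the repeat-enrichment contrasts
  (0.00025 and 0.000051) are not reproduced by either the exact test or
  chi-square on the printed counts (both give smaller values); since the
  original test is unnamed, the package reports both of its own tests and
  treats the printed figures as a logged consistency check. Both analyses
  agree the contrasts are highly significant.

## Known limitations

* The aligner is ungapped-plus-chaining, not full gapped dynamic
  programming; highly indel-rich homology will fragment into chained
  pieces, and noncoding identity is measured on ungapped segments only.
* Retroposition is out of scope by design: a parentless candidate is
  simply a candidate without a parent, and CDS-only duplicates are
  deliberately rejected by the noncoding criterion.
* Segmental (multi-gene) movements are not detected; the rank scan only
  calls gaps of up to the window size.
* The outgroup logic is purely positional; no gene trees are built.
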