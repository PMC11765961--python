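# Methods

## The localization model

The pipeline formalizes "find the gene by its neighbours" as a small
constraint system over gene order.

For a focal gene on a scaffold, its *neighbour context* is the set of the
`k` nearest genes on each side in coordinate order (the rank), each with a
relative orientation (`same` if the two genes share a strand, `opposite`
otherwise) and the bp gap between gene bodies. Ranks are computed on the
biotype-filtered gene list (default: protein-coding only), so pseudogenes
and small RNAs do not consume rank positions.

Given one context per species, the consensus step emits an *anchor
constraint* for every symbol that appears within the window in enough
species: its majority relative orientation (a tie degrades to `any`), its
empirical support — the fraction of species with both genes annotated whose
context shows the symbol with the majority orientation — and the tightest
rank window covering the supporting species. Constraints with support below
`min_support` are dropped. Aggregation iterates species in sorted order, so
the result is independent of input order.

Localization scores each gene within an anchor's window in the query by the
number of constraints it satisfies (anchor occurrence within the
constraint's rank window, orientation compatible). Two immediately adjacent
anchors with a gap and no gene between them additionally yield an
*empty-slot* prediction spanning the inter-anchor interval, its strand
inferred from the orientation constraints. Predictions are sorted by
(score desc, summed bp gap to the satisfied anchors asc, seq_id, start) —
fully deterministic.

For the ASMT case the learned pattern is two constraints — AKAP17A
(adjacent, same orientation) and ASMTL (adjacent, opposite orientation) —
and the correct locus is the unique gene satisfying both.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` (window) | 2 | genes per side considered adjacent; 1 matches browser-view adjacency, 2 absorbs one interloping annotation |
| `min_support` | 0.8 | fraction of informative species required per constraint; conserved arrangements hold in "most", not all, species |
| biotype filter | protein-coding | ranks computed after filtering |

## Paralog decision

Domain presence is decided by an ungapped sliding-window PSSM scan: per
position, base-2 log-odds of each residue against a uniform background with
+1 pseudocounts; a window is a hit when its summed score reaches the
profile's threshold, and overlapping hits are merged keeping the best
window. Non-standard residues contribute 0. No indel states are modelled:
the downstream decision is presence/absence, not boundary reconstruction,
and an ungapped scan with a calibrated threshold is sufficient and exactly
testable against a brute-force scorer.

Thresholds come from `calibrate_threshold`: the empirical `1 − target_fpr`
quantile (upper order statistic) of per-sequence maximum window scores over
≥ 100 background proteins. The default `target_fpr` is 0.001 per 1000-aa
background protein — presence/absence calls should be conservative. Shorter
query proteins contain proportionally fewer windows and therefore realise a
lower per-protein false-positive rate than the calibration unit.

The decision table is total and deterministic: Methyltransf_2 ∧ Maf →
ASMTL; Methyltransf_2 ∧ ¬Maf → ASMT; anything else → unclassified.

The shipped profiles (`data/profiles/*_synthetic.pssm`) are *synthetic*
stand-ins: built by `build_profile` from synthetic seed alignments
(25 sequences, 15% per-position divergence from a random consensus) and
calibrated on 500 random 1000-aa backgrounds. They exercise every code path
with realistic score distributions; they do not encode the sequence content
of curated Pfam/CDD models, so classification of real proteins requires
supplying real profiles in the same plain-text format.

## Concordance, GC, PCR, programs

Exon-chain concordance is positional: base-level Jaccard over 1-based
inclusive exon intervals plus exact-exon counts; chains on different
scaffolds or strands are an error, not a zero. CDS phase is ignored — the
claim being checked ("the exons of the two models align") is positional.

GC content is `100·(G+C)/(A+C+G+T)` with ambiguous bases excluded (warned
above 1%). Sliding windows start at offsets 0, step, 2·step, …; a trailing
partial window is kept iff at least half a window long.

In-silico PCR matches the forward primer and the reverse primer's reverse
complement exactly (default); with `max_mismatches > 0` the three
3'-terminal bases of each primer must still match exactly, because 3'
mismatches abolish extension. Degenerate IUPAC primers are rejected rather
than expanded. Product length is end-to-end including both primer
footprints. All compatible site pairs are enumerated.

The slow-down program generator emits annealing blocks at
`anneal_start, anneal_start − decrement, …, anneal_end` (a non-dividing
decrement is an error, not silently rounded), each with the configured
denaturation/extension steps and cycles. The defaults (98 °C/10 s
denaturation, 30 s annealing stepping 72 → 65 °C by 1 °C every 4 cycles,
72 °C/45 s extension, 120 s pre-denaturation, 600 s final extension)
reproduce the published protocol for the GC-rich ASMT template.

## Transcript-variant calling

`map_exons` places each reference exon (ordered 5'→3') in the query cDNA by
its best full-length ungapped match; an exon is present iff identity
≥ 0.95 — chosen so that a ~1% Sanger error rate (per-exon identity ≈ 0.99)
never costs a true exon while random placements (~25% identity) never reach
it. Chosen placements must be colinear and non-overlapping; with duplicated
exon sequences the assignment maximizing (number matched, total identity)
is selected by dynamic programming over candidate placements, and exons
squeezed out of every colinear chain are demoted to unmatched with a log
message. Reference exons under 10 bp are merged into a neighbour (logged).

Variant correspondence is 3'-anchored: two variants correspond iff their
missing-exon sets counted from the 3' end coincide. Exon-skipping variants
are conventionally described relative to references whose exon counts
differ between species (a nine- vs. a ten-exon reference), and counting
from the 3' end is the numbering under which the pig clone and the short
human variant — both missing their 3rd- and 4th-from-last exons — agree.
`SplicedMap` reports missing indices in both numbering systems
(`missing_exons`, `missing_exons_from_3p`) and does not adjudicate between
them.

## Synthetic data: what it emulates, what it does not

`generate_panel` plants the anchor–target–paralog block *contiguously* in
gene order (first constraint's anchor immediately left of the target,
second immediately right), surrounded by decoy genes with random positions
and strands. Decoy symbols (`DECOY####`) are panel-wide: every decoy symbol
occurs exactly once in every species, at an independent random position.
This mirrors the real situation — orthologs exist across species but only
the anchors travel with the target — and it is what keeps decoy support
low (≈ 1/n_species) under the support definition; species-private decoy
names would trivially reach support 1.0 in their only species.

Default study conditions: 10 species, 20 decoys per scaffold, gene lengths
uniform in 2–5 kb, intergenic gaps uniform in 0.2–2 kb (a gene-dense,
PAR-like neighbourhood; genes deliberately longer than gaps so rank-1
neighbours are also bp-nearest, making the distance tie-break consistent
with rank adjacency), target strand randomized per species. Constraint
*ablation* deletes the anchor gene for the affected species, making the
constraint unsatisfiable — the cleanest "pattern partially absent"
condition.

Other generators: `generate_gc_cds` fixes the base composition exactly
(round(length·gc) G/C bases, shuffled), so window GC counts are
hypergeometric; `generate_transcript_variant` concatenates retained exons
with iid substitution errors; `plant_domains` embeds profile consensus
sequences in iid-uniform background proteins; `plant_primer_sites` embeds a
primer pair at an exact end-to-end distance in a GC-controlled template.
Every generator is a pure function of parameters + seed, with ground truth
returned alongside.

What the generators do *not* model — and hence what green tests do not
certify about real data: real intergenic length distributions, segmental
duplications and inversions beyond the planted paralog, biased amino-acid
composition and homologous (rather than random) decoy proteins, sequencing
indels (substitutions only), and annotation errors other than the planted
symbol misassignment. On real genomes, window size and `min_support` absorb
part of this (that is why `k` defaults to 2, not 1), but heavily rearranged
or fragmented assemblies remain out of scope: the method needs the anchors
assembled on the same scaffold as the target.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere internally; half-open
  formats convert at the I/O boundary. Symbol matching is
  case-insensitive; placeholder symbols are kept verbatim.
- Prediction tie-breaks: score, then summed bp gap to satisfied anchors,
  then (seq_id, start). Under the generator's defaults the bp tie-break
  orders rank-1 candidates ahead of rank-2 ones deterministically.
- Orientation is strand-to-strand, not upstream/downstream-aware — the
  weaker definition is invariant under scaffold reflection, which is
  exercised as a property (mirroring a scaffold changes no orientation,
  support, or top prediction).
- `calibrate_threshold` uses the `method="higher"` quantile so the
  threshold is an observed score, never an interpolation; `target_fpr = 0`
  returns strictly above the background maximum.
- Problem sizes in the test suite and acceptance script (200/100 panels,
  1000 null proteins of 250 aa against 500 calibration backgrounds of
  1000 aa, exhaustive drop sets over 8 exons, 40 noisy replicates) were
  chosen as the smallest sizes at which the binomial noise of the measured
  rates is well inside the asserted bounds.

## Known limitations

- The synteny score is a count of satisfied constraints; with many anchors
  a weighted score (by support or by anchor specificity) would rank better.
- The PSSM scan has no indel states; a degraded domain with insertions can
  fall below threshold. Real-profile users should calibrate on
  composition-matched backgrounds, not the uniform nulls used here.
- In-silico PCR is exact-match (with optional bounded mismatches); no
  melting-temperature or secondary-structure model.
- `map_exons` assumes the query is a spliced cDNA of the reference locus;
  it will not detect novel exons absent from the reference model.
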