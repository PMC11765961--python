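# syntenylocus

Locating a gene that a genome annotation has lost — or filed under the wrong
name — by the company it keeps.

Melatonin's final synthesis enzyme, acetylserotonin O-methyltransferase
(ASMT), sits in the pseudoautosomal region of the X chromosome, a
high-recombination neighbourhood that assemblers and annotation pipelines
handle badly. In the pig genome the gene exists but is hidden behind a
placeholder identifier and misdescribed as its paralog ASMTL. `syntenylocus`
packages the comparative-genomics workflow that resolves such cases into a
reusable, fully testable pipeline:

1. **Synteny localization** (`syntenylocus.synteny`) — learn, from species
   where the target is annotated, which anchor genes sit within a small
   gene-order window of it and with what relative orientation (for ASMT:
   *AKAP17A* adjacent on the same strand, *ASMTL* adjacent on the opposite
   strand), then score every candidate slot next to those anchors in a query
   genome. An anchor constraint is kept when a fraction ≥ `min_support`
   (default 0.8) of informative species shows it; a candidate's score is the
   number of constraints it satisfies.
2. **Paralog disambiguation** (`syntenylocus.domains`) — an ungapped PSSM
   scan (base-2 log-odds, calibrated score threshold) deciding
   ASMT vs. ASMTL from domain architecture: Methyltransf_2 alone → ASMT,
   Methyltransf_2 + Maf → ASMTL.
3. **Annotation concordance** (`syntenylocus.concordance`) — base-level
   Jaccard and exact-exon agreement between two gene models of one locus
   (e.g. an NCBI placeholder vs. an Ensembl stable ID).
4. **Cloning support** (`syntenylocus.gc_pcr`) — GC content (global and
   sliding-window), exact in-silico PCR, and slow-down (stepwise touchdown)
   thermal-program generation for GC-rich templates.
5. **Transcript-variant detection** (`syntenylocus.transcripts`) — map a
   cloned cDNA onto ordered reference exons, call missing exons, and match
   exon-skipping variants across species by their 3'-anchored missing-exon
   signature.
6. **Synthetic data** (`syntenylocus.simulate`) — seeded generators for
   species panels with planted synteny, GC-controlled sequences, planted
   domains, planted primer sites and exon-dropped cDNAs, each with
   machine-readable ground truth, so the whole pipeline is testable offline.

## Worked example

```sh
# a 10-species panel with the conserved AKAP17A/ASMT/ASMTL arrangement
syntenylocus simulate --n-species 10 --no-misannotate --seed 8 --out panel/
# a query genome whose target carries only a placeholder symbol
syntenylocus simulate --n-species 1 --seed 15 --out qpanel/
syntenylocus localize --query qpanel/species01.gff3 --panel panel/ --target ASMT
```

prints (columns: rank, seq\_id, start, end, strand, candidate\_gene\_id,
candidate\_symbol, score, anchor\_distance\_bp):

```
rank	seq_id	start	end	strand	candidate_gene_id	candidate_symbol	score	anchor_distance_bp
1	scf_species01	52323	56197	-	species01_g012	LOC900000001	2	1351
2	scf_species01	59956	62001	-	species01_g014	DECOY0015	1	667
...
```

The top candidate is the placeholder gene (`LOC900000001`), satisfying both
learned constraints (score 2 of 2): it is adjacent to AKAP17A on the same
strand and to ASMTL on the opposite strand — the synteny fingerprint of the
target. Lower-ranked rows are bystander genes satisfying only one
constraint. The slow-down program
for the subsequent cloning step:

```sh
syntenylocus slowdown
```

```
Pre-denaturation at 98 °C for 120 s.
98 °C 10 s, 72 °C 30 s, 72 °C 45 s, 4 cycles;
98 °C 10 s, 71 °C 30 s, 72 °C 45 s, 4 cycles;
...
98 °C 10 s, 65 °C 30 s, 72 °C 45 s, 4 cycles;
Final extension at 72 °C for 600 s.
```

eight annealing blocks stepping 72 → 65 °C, 32 cycles in total.

Other subcommands: `classify`, `concord`, `gc`, `pcr`, `exonmap`, and
`run-all --config run.cfg` for the end-to-end workflow (see
`docs/methods.md`).

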