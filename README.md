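# stopshift

Detection of stop-codon reassignment in nuclear genomes.

Most eukaryotes terminate translation at UAA, UAG and UGA, but several
lineages — ciliates above all — have repeatedly reassigned one or more stop
codons to amino acids. `stopshift` implements the comparative-genomic
evidence chain used to call such reassignments from assembly + annotation
data alone, aimed at people vetting the genetic code of newly assembled
(often metagenome-derived) protist genomes:

1. **Conserved-site voting.** Translate every gene model with the candidate
   codon(s) masked to `X`, locate each masked residue in its orthogroup
   multiple sequence alignment, and at every highly conserved column
   (modal background residue at ≥ 70 % identity, query excluded) record one
   vote for that residue. A codon with ≥ `min_sites` qualifying votes and a
   dominant residue (share ≥ 0.5 by default) is called *sense* for that
   residue; otherwise it stays *stop/undetermined*.
2. **C-terminus stop-context tally** (annotation-independent). From
   protein-to-genome alignments (miniprot-style PAF, protein-query dialect),
   take every alignment that reaches its query's C-terminus and read the
   in-frame codon immediately 3′ of the last aligned codon. A pure stop
   codon dominates this tally; re-aligning under a table that treats the
   candidate as sense must *increase* the number of full-C-terminus
   alignments if the candidate never terminates translation.
3. **Gene-body depletion test.** A codon that moonlights as a stop is
   depleted near the annotated stop codon. The test bins in-frame
   occurrences by relative position, compares the candidate's mass in the
   terminal tail (10 % by default) against its synonymous codons, and
   bootstraps over genes; verdict *depleted* iff the CI upper bound < 1.
4. **Codon usage.** Stop-codon usage over complete gene models, relative
   synonymous usage of the reassigned codon inside its new amino-acid
   family, internal-codon prevalence, assembly GC.
5. **Suppressor tRNAs.** Screen tRNAscan-SE output for anticodons
   complementary to stop codons (CTA→UAG; TTA→UAA/UAG by wobble; TCA→UGA),
   derive canonical numbering from the cloverleaf, check the leucine
   identity elements (discriminator A, acceptor pairs A4–U69/G5–C68, long
   variable arm, invariant loop nucleotides), find the nearest canonical
   isotype by global-alignment identity, and flag telomere-capped contigs.

Real genome-scale inputs (OrthoFinder orthogroups, miniprot alignments,
tRNAscan-SE runs) are consumed, not produced. A fully seeded synthetic-data
generator (`stopshift simulate`) emits every input format with ground truth,
so the whole chain is testable end to end.

Supported genetic codes: NCBI translation tables 1 (standard), 6
(UAR→Gln), 15 (UAG→Gln) and 16 (UAG→Leu).

## Worked example

Generate a synthetic genome that uses table 16 (UAG = leucine, 10 % of
leucine codons written as UAG) together with suppressor tRNAs, then analyze
it:

```sh
$ cat synth.yaml
seed: 7
query_table_id: 16
genes_per_genome: 150
n_orthogroups: 80
reassigned_codon_family_usage: 0.1
suppressor_trna: true
telomere_cap: true

$ stopshift simulate demo --config-file synth.yaml
wrote 93 files to demo

$ stopshift analyze run.yaml     # run.yaml points at the demo/ files
taxon16	TAA	stop/undetermined	n_sites=0
taxon16	TAG	sense:L	n_sites=39
taxon16	TGA	stop/undetermined	n_sites=0
```

The JSON report (`out/taxon16.report.json`) holds the full evidence. For
this run:

* `genetic_code.TAG`: 39 masked UAG codons fell on conserved columns; all
  39 vote leucine (`top_fraction` 1.0) → call `sense:L`, while UAA and UGA
  stay `stop/undetermined` with zero qualifying sites.
* `codon_usage.stop_fractions`: UAA 0.934, UGA 0.066, UAG 0.0 — UAA is the
  strongly preferred stop, and UAG never terminates a complete gene.
* `codon_usage.family_usage.UAG`: 0.112 — UAG is used for ~11 % of leucine
  positions (the generator wrote 10 %); 51.8 % of genes contain ≥ 1
  internal UAG.
* `stop_context.comparison`: 68 full-C-terminus alignments under table 1
  vs 139 under table 16 → `best_table: 16`; 93–94 % of tallied codons are
  UAA under either table.
* `gene_body`: tail ratio 1.03, verdict `not depleted` — no sign of a dual
  (sense + stop) meaning.
* `trna.suppressors`: two CTA-anticodon tRNAs decoding UAG, both passing
  the leucine identity-element check, nearest canonical isotype Leu-CAA
  (98.8 % / 92.6 % identity), on a telomere-capped contig.

Together these are the signatures of a genuine UAG→Leu reassignment.

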