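# Methods

## Problem and model

A stop-codon reassignment is inferred, not observed: the claim "UAG encodes
leucine in this genome" is supported when (i) in-frame UAG codons sit at
alignment positions where leucine is strongly conserved across related
proteomes, (ii) alignment-based evidence independent of the annotation shows
UAG never acting as a terminator, (iii) UAG behaves like a synonymous member
of the leucine codon family in usage statistics, and (iv) a plausible
decoding route (a CUA-anticodon tRNA chargeable with leucine) exists.
`stopshift` computes each line of evidence as a separate module and a
pipeline that aggregates them per genome.

### Conserved-site voting (`code_inference`)

Every gene model is translated with the candidate codons masked to `X`
(all three standard stops by default, masked simultaneously in one working
translation — on genomes whose complete genes contain internal occurrences
of at most one reassigned codon this is equivalent to per-codon masking,
and it keeps one proteome consistent with the orthogroup alignments). Each
masked residue is located in its orthogroup MSA column; the column's
background residues (query row, gaps and `X` excluded) vote if:

* depth ≥ `min_depth` (default 4) — a mode over fewer residues is noise;
* the modal residue is unique — ties discard the site, keeping counts
  integer-valued and conservative;
* modal share ≥ `threshold` (default 0.70, inclusive at the boundary).

The per-codon summary tallies modal residues over qualifying sites. A codon
is called `sense:<aa>` at ≥ `min_sites` (default 20) qualifying sites with
top-residue share ≥ `call_fraction` (default 0.5); otherwise
`stop/undetermined`, which is the expected outcome for a true stop codon
(genes simply do not contain internal occurrences of it). Identity is
computed excluding the query sequence; including a masked query would only
dilute the denominator, never flip a vote.

### C-terminus stop-context tally (`stop_context`)

From protein-to-genome alignments, only records with
`query_end == query_len` (the query's C-terminus aligned) contribute; the
tallied codon is the in-frame trinucleotide immediately 3′ of the last
aligned codon, reverse-complemented for minus-strand records. One best
alignment per query (by residue matches) is kept by default. Every record
is classified into exactly one of {contributes, non-C-terminal,
truncated-at-contig-end}. Comparing the tally across translation tables
(the table only affects where the aligner stops extending) flags the table
maximizing full-C-terminus alignments.

### Gene-body depletion test (`stop_context`)

Internal codons of complete genes are binned by relative position
(`floor(n_bins * i / L)`, `n_bins` = 20). The statistic is the ratio of the
target codon's profile mass in the terminal `tail_fraction` (default 0.1)
of bins to the pooled synonymous codons' mass in the same bins. The
interval is a percentile bootstrap over genes (default 1000 resamples, 95 %
CI); the verdict is *depleted* iff the CI upper bound < 1. The statistic,
tail width and bootstrap design are this package's own construction — the
underlying comparison is usually made visually — and all three are
configurable. Fewer than 50 target occurrences yields *insufficient data*.
Calibration on synthetic data (seeded, 40 replicates each): ≤ 10 % false
*depleted* verdicts on a uniform generator; ≥ 95 % detection when the
target codon is excluded from the terminal 10 % of each gene
(`tests/test_acceptance.py` recomputes both rates).

### Codon usage (`codon_usage`)

All gene-level statistics are restricted to complete models (start codon,
terminal stop under the applied table, in frame, no internal stop): partial
models would bias stop-codon denominators. Family membership for relative
synonymous usage follows the applied table, so UAG is the 7th leucine codon
under table 16 and the 3rd glutamine codon under table 15; terminal stops
are never counted as family members. GC content is computed on the
assembly (N excluded from the denominator), which is not directly
comparable to transcriptome-derived GC.

### Suppressor tRNAs (`trna_suppressor`)

Anticodons CTA, TTA and TCA (DNA, 5′→3′) decode UAG, UAA+UAG (wobble) and
UGA respectively. Canonical numbering is derived structurally from the
cloverleaf (acceptor stem, D-arm, anticodon arm, variable region, T-arm)
rather than from lookup tables; acceptor base pairs are numbered so pair
*i* partners position 73−*i*, and the discriminator is the last unpaired 3′
residue before any CCA tail. The leucine identity-element check evaluates
the discriminator A, acceptor pairs A4–U69 and G5–C68, a variable region of
≥ 10 nt (the type-II arm of Leu/Ser tRNAs), and the invariant nucleotides
G18, G19, A21, U33, U54, U55, C56, A58. The A4–U69 pair is optional by
default because natural suppressors can carry the swapped U4–A69 pair
without losing leucine identity; which elements are required is
configuration. Pairwise identity uses global alignment (match 1, mismatch
−1, gap open −2, extend −1); differences count mismatches plus gapped
columns, which reduces to a Hamming distance for gap-free alignments.
Telomere caps are detected as ≥ 2 tandem copies of CCCCAAA — matched in
any rotation and on either strand — within 100 nt of each contig end.

## Synthetic data generator (`synthdata`)

The generator emulates the inputs of a small ciliate-like genome project
with known ground truth; its defaults are chosen to resemble the regimes
in which these analyses are actually run:

* genes: 200 per genome, mean 150 codons (30 + Poisson), uniform amino
  acids after the initiator M, codons drawn within each standard family
  with GC bias (default 0.35, AT-rich like most ciliate assemblies)
  applied at synonymous third positions so protein truth is preserved;
* reassignment: under tables 6/15/16 a configurable share (default 0.08,
  the observed order of magnitude for reassigned-codon family usage) of the
  target amino acid's positions is written as the reassigned stop codon;
* stop usage: per-table defaults (table 1: UAA .85 / UAG .10 / UGA .05;
  tables 15/16: UAA .95 / UGA .05; table 6: UGA 1.0) mirroring the strong
  UAA preference of these genomes; mass on a sense codon is a config error;
* partial models: 10 % of genes lack their start and/or stop codon;
* orthogroups: one query (masked protein) plus `n_taxa − 1` background
  rows; at conserved columns (fraction 0.5 by default) at least
  `column_identity_at_conserved` (default 0.85) of the background carries
  the query's true residue, other columns are uniform noise from a flat
  residue model; background gaps at 5 %, query-gap columns at 2 %;
* alignments: one pseudo-reference protein per gene, truncated at the
  first internal codon that is a stop under the evaluation table; models
  lacking a stop codon get a query 25 residues longer than the alignable
  span, as a real reference protein would extend past a truncated model —
  so they never enter the C-terminus tally;
* tRNAs: synthetic cloverleaves built segment by segment (stand-ins, not
  natural sequences); canonical decoys Leu-CAA, Leu-TAA, Gln-TTG (the Gln
  decoy deliberately violates the leucine elements); suppressors are the
  leucine template with a CTA anticodon, further suppressors carrying a
  configurable number of extra substitutions (one in the anticodon loop,
  the rest in the variable loop — a recently diverged pair);
* dual-meaning emulation: `exclude_target_tail_fraction` forbids the
  reassigned codon from the terminal fraction of each gene.

All randomness flows from one integer seed through independent child
streams per generator; identical configurations are byte-identical on
disk, and a manifest of SHA-256 hashes is written with every bundle.

What the generator does **not** model: phylogenetic correlation between
background sequences (residues are i.i.d. given the conservation state),
realistic substitution processes, introns (gene models are single-segment,
though multi-segment extraction is implemented and tested), indel-rich
alignments, assembly error, or tRNA covariance-model scores. Passing tests
therefore demonstrate that the statistics recover their generating
parameters and discriminate the coded scenarios — not that the thresholds
are optimal for any particular real dataset.

## Numerical choices and degenerate inputs

* Thresholds on fractions are inclusive with a 1e-9 guard against float
  representation (a site at exactly 70 % identity qualifies).
* Modal ties and sub-depth columns are discarded, never split.
* Codons containing N translate to `X` and are excluded from usage
  denominators; an unmasked internal stop truncates the record, which is
  flagged and excluded from complete-gene statistics rather than repaired.
* Genes shorter than `n_bins` codons are binned by the same formula (some
  bins stay empty); bootstrap ratios of 0/0 are dropped, ∞ is kept (it can
  only push the CI upper bound up, i.e. toward the conservative verdict).
* Report JSON is byte-deterministic (sorted keys, no timestamps) and
  carries the package version, seed and a config hash.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: bundles of 120–400 genes (2000 for the codon-usage recovery
check), 5–200 orthogroups of 10 taxa, and 40 replicates per calibration
arm of the depletion test. These sizes already put the recovery checks
well inside their binomial tolerance bands while keeping a full run in the
tens of seconds.

## Known limitations

* The genetic-code call is evidence-based, not proof: confirming that a
  codon is translated to a particular amino acid requires proteomics.
* tRNAscan-SE confidence scores are surfaced but not recomputed.
* The cloverleaf decomposer expects clean stems (no bulges); structures
  that do not decompose produce an explicit error and the element checks
  are skipped for that tRNA.
* Codon-adaptation-style indices and phylogenetic tree inference are out
  of scope.
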