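"""Seeded generator for every input the pipeline consumes, with ground truth.

The generator emulates small ciliate-like genome bundles: multi-gene contigs
with configurable stop-codon usage, a genetic code per taxon (NCBI tables 1,
6, 15, 16), a configurable within-family usage rate of the reassigned codon,
orthogroup alignments with controllable per-column conservation, truncated
gene models, telomere-capped contigs, protein-to-genome alignments, and tRNA
gene predictions with or without suppressor anticodons.

Everything is driven by one integer seed; identical configurations produce
byte-identical output files.  Each emitted record is traceable to a ground
truth record so pipeline statistics can be recounted independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .genetic_code import (CODONS, GeneModel, STANDARD_STOPS, load_table,
                           revcomp, rna_to_dna)
from . import io as sio
from .stop_context import AlignmentRecord, write_paf
from .trna_suppressor import TRNAGene, write_structures, write_trnascan

log = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_STOP_USAGE = {
    1: {"TAA": 0.85, "TAG": 0.10, "TGA": 0.05},
    6: {"TGA": 1.0},
    15: {"TAA": 0.95, "TGA": 0.05},
    16: {"TAA": 0.95, "TGA": 0.05},
}

# rng stream ids: one independent child stream per generator
_STREAM_GENOME, _STREAM_ORTHO, _STREAM_ALN, _STREAM_TRNA = 0, 1, 2, 3


@dataclass
class SynthConfig:
    """Configuration of one synthetic taxon bundle.

    ``stop_usage`` maps stop codons (DNA or RNA spelling) to probabilities
    summing to 1; under a variant table the reassigned codon must carry no
    mass.  ``reassigned_codon_family_usage`` is the share of the target
    amino acid's codons written as the reassigned stop codon.
    ``exclude_target_tail_fraction`` > 0 emulates a dual-meaning codon by
    forbidding the reassigned codon from the terminal fraction of each gene.
    """

    seed: int = 0
    n_taxa: int = 10
    query_table_id: int = 1
    n_orthogroups: int = 100
    genes_per_genome: int = 200
    mean_gene_len_codons: int = 150
    conserved_column_fraction: float = 0.5
    column_identity_at_conserved: float = 0.85
    reassigned_codon_family_usage: float = 0.08
    stop_usage: Optional[Dict[str, float]] = None
    gc_bias: float = 0.35
    partial_gene_fraction: float = 0.1
    suppressor_trna: bool = False
    telomere_cap: bool = False
    exclude_target_tail_fraction: float = 0.0
    gap_rate: float = 0.05
    query_gap_rate: float = 0.02
    genes_per_contig: int = 50
    mean_intergenic_len: int = 100
    n_suppressors: int = 2
    suppressor_mutations: int = 5

    def __post_init__(self):
        table = load_table(self.query_table_id)
        if self.stop_usage is None:
            self.stop_usage = dict(_DEFAULT_STOP_USAGE[self.query_table_id])
        self.stop_usage = {rna_to_dna(c): float(p)
                           for c, p in self.stop_usage.items()}
        for name in ("conserved_column_fraction", "reassigned_codon_family_usage",
                     "gc_bias", "partial_gene_fraction", "gap_rate",
                     "query_gap_rate", "exclude_target_tail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.7 <= self.column_identity_at_conserved <= 1.0:
            raise ValueError("column_identity_at_conserved must be in [0.7,1]")
        total = sum(self.stop_usage.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stop_usage sums to {total}, not 1")
        for codon, p in self.stop_usage.items():
            if p > 0 and not table.is_stop(codon):
                raise ValueError(
                    f"stop_usage assigns mass to {codon}, a sense codon "
                    f"under table {self.query_table_id}")

    @classmethod
    def from_file(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    protein_true: str
    protein_masked: str
    stop_codon: str  # "" for models lacking a stop
    target_positions: Tuple[int, ...]  # internal codon indices of reassigned codon
    has_start: bool
    has_stop: bool
    internal_codons: Tuple[str, ...] = ()


@dataclass
class GenomeBundle:
    contigs: Dict[str, str]
    models: List[GeneModel]
    truths: List[GeneTruth]
    config: SynthConfig

    @property
    def masked_proteins(self) -> Dict[str, str]:
        return {t.gene_id: t.protein_masked for t in self.truths}


@dataclass
class OGColumnTruth:
    orthogroup_id: str
    column: int
    conserved: bool
    query_char: str
    true_residue: str


@dataclass
class TRNATruth:
    trna_id: str
    role: str  # "suppressor" or "canonical"
    isotype: str
    anticodon: str
    template: str
    n_mutations: int


@dataclass
class TRNABundle:
    trnas: List[TRNAGene]
    truths: List[TRNATruth]
    contigs: Dict[str, str]


def _reassigned_codons(table) -> Tuple[str, ...]:
    return tuple(c for c in STANDARD_STOPS if not table.is_stop(c))


def _codon_samplers(config: SynthConfig):
    """Per-amino-acid codon distributions (standard family, GC-weighted thirds).

    Returns ``(samplers, samplers_tail, target_aa)`` where each sampler maps
    amino acid -> (codon array, cumulative probabilities).  The tail sampler
    excludes the reassigned codon (used when emulating dual meaning).
    """
    std = load_table(1)
    table = load_table(config.query_table_id)
    reassigned = _reassigned_codons(table)
    target_aa = table.codon_map[reassigned[0]] if reassigned else None
    ru = config.reassigned_codon_family_usage

    def weights(fam):
        w = np.array([config.gc_bias if c[2] in "GC" else 1.0 - config.gc_bias
                      for c in fam])
        return w / w.sum()

    samplers = {}
    samplers_tail = {}
    for aa in AA20:
        fam = [c for c in CODONS if std.codon_map[c] == aa]
        w = weights(fam)
        if aa == target_aa and reassigned:
            codons = fam + list(reassigned)
            probs = np.concatenate([(1.0 - ru) * w,
                                    np.full(len(reassigned), ru / len(reassigned))])
        else:
            codons, probs = fam, w
        samplers[aa] = (np.array(codons), np.cumsum(probs))
        samplers_tail[aa] = (np.array(fam), np.cumsum(w))
    return samplers, samplers_tail, target_aa


def _random_dna(rng, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def simulate_genome(config: SynthConfig) -> GenomeBundle:
    """Simulate contigs, gene models, and working (masked) proteins.

    Complete genes begin with ATG and end with a stop drawn from
    ``stop_usage``; under a variant table the configured fraction of the
    target amino acid's positions are written as the reassigned codon.  A
    ``partial_gene_fraction`` of genes lack their start and/or stop codon.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    table = load_table(config.query_table_id)
    samplers, samplers_tail, target_aa = _codon_samplers(config)
    reassigned = set(_reassigned_codons(table))
    stops = sorted(config.stop_usage)
    stop_probs = np.array([config.stop_usage[c] for c in stops])

    n = config.genes_per_genome
    lengths = 30 + rng.poisson(max(config.mean_gene_len_codons - 30, 1), size=n)
    genes = []
    for g in range(n):
        L = int(lengths[g])
        aas = "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, L - 1)])
        u = rng.random(L)
        codons = []
        tail_start = L  # index from which the reassigned codon is forbidden
        if config.exclude_target_tail_fraction > 0:
            tail_start = int(math.ceil(L * (1 - config.exclude_target_tail_fraction)))
        for i, aa in enumerate(aas):
            pool, cum = (samplers_tail if i >= tail_start else samplers)[aa]
            codons.append(str(pool[np.searchsorted(cum, u[i])]))
        has_start = has_stop = True
        if rng.random() < config.partial_gene_fraction:
            kind = ("nostart", "nostop", "both")[rng.integers(0, 3)]
            has_start = kind == "nostop"
            has_stop = kind == "nostart"
        protein = aas
        if not has_start:
            # replace the initiator with a random non-start sense codon
            while True:
                aa = AA20[rng.integers(0, 20)]
                pool, cum = samplers[aa]
                codon = str(pool[np.searchsorted(cum, rng.random())])
                if aa != "M" and codon not in table.start_codons \
                        and codon not in reassigned:
                    break
            codons[0] = codon
            protein = aa + protein[1:]
        stop = str(np.array(stops)[np.searchsorted(np.cumsum(stop_probs),
                                                   rng.random())]) if has_stop else ""
        masked = "".join("X" if c in reassigned else p
                         for c, p in zip(codons, protein))
        target_pos = tuple(i for i, c in enumerate(codons) if c in reassigned)
        genes.append((codons, stop, protein, masked, target_pos,
                      has_start, has_stop))

    contigs: Dict[str, str] = {}
    models: List[GeneModel] = []
    truths: List[GeneTruth] = []
    n_contigs = math.ceil(n / config.genes_per_contig)
    gene_idx = 0
    for ci in range(n_contigs):
        name = f"contig{ci + 1:03d}"
        parts = []
        pos = 0
        if config.telomere_cap:
            cap = "CCCCAAA" * 3
            parts.append(cap)
            pos += len(cap)
        contig_genes = []
        for _ in range(min(config.genes_per_contig, n - gene_idx)):
            spacer = _random_dna(rng, 20 + int(rng.poisson(config.mean_intergenic_len)),
                                 config.gc_bias)
            parts.append(spacer)
            pos += len(spacer)
            codons, stop, protein, masked, target_pos, has_start, has_stop = \
                genes[gene_idx]
            gene_seq = "".join(codons) + stop
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(gene_seq if strand == "+" else revcomp(gene_seq))
            gid = f"g{gene_idx + 1:05d}"
            start, end = pos, pos + len(gene_seq)
            models.append(GeneModel(gene_id=gid, seq_id=name, strand=strand,
                                    cds_segments=[(start, end)]))
            truths.append(GeneTruth(
                gene_id=gid, contig=name, strand=strand, start=start, end=end,
                protein_true=protein, protein_masked=masked, stop_codon=stop,
                target_positions=target_pos, has_start=has_start,
                has_stop=has_stop, internal_codons=tuple(codons)))
            pos = end
            gene_idx += 1
        tail = _random_dna(rng, 20 + int(rng.poisson(config.mean_intergenic_len)),
                           config.gc_bias)
        parts.append(tail)
        if config.telomere_cap:
            parts.append("GGGGTTT" * 3)
        contigs[name] = "".join(parts)
    return GenomeBundle(contigs=contigs, models=models, truths=truths,
                        config=config)


def simulate_orthogroups(config: SynthConfig, bundle: GenomeBundle
                         ) -> Tuple[Dict[str, Dict[str, str]], List[OGColumnTruth]]:
    """Build one alignment per orthogroup around each query protein.

    Each orthogroup holds the (masked) query and ``n_taxa - 1`` background
    sequences.  At conserved columns at least ``column_identity_at_conserved``
    of the background carries the query's *true* residue (the reassigned
    amino acid at masked positions); other columns are uniform noise.
    Background residues gap out at ``gap_rate``; extra all-background columns
    where the query is gapped appear at ``query_gap_rate``.
    """
    if config.n_taxa < 5:
        raise ValueError("n_taxa must be >= 5 for conservation voting")
    rng = np.random.default_rng([config.seed, _STREAM_ORTHO])
    n_bg = config.n_taxa - 1
    k = math.ceil(config.column_identity_at_conserved * n_bg)
    complete = [t for t in bundle.truths if t.has_start and t.has_stop]
    if len(complete) < config.n_orthogroups:
        log.warning("only %d complete genes for %d orthogroups",
                    len(complete), config.n_orthogroups)
    chosen = complete[:config.n_orthogroups]
    aa_arr = np.array(list(AA20))
    msas: Dict[str, Dict[str, str]] = {}
    col_truth: List[OGColumnTruth] = []
    for og_i, truth in enumerate(chosen):
        og_id = f"og{og_i + 1:04d}"
        query = truth.protein_masked
        true_res = np.array(list(truth.protein_true))
        ncols = len(query)
        conserved = rng.random(ncols) < config.conserved_column_fraction
        bg = aa_arr[rng.integers(0, 20, size=(n_bg, ncols))]
        if k > 0:
            R = rng.random((n_bg, ncols))
            kth = np.sort(R, axis=0)[k - 1]
            matched = R <= kth
            sel = matched & conserved
            bg[sel] = np.broadcast_to(true_res, (n_bg, ncols))[sel]
        if config.gap_rate > 0:
            bg[rng.random((n_bg, ncols)) < config.gap_rate] = "-"
        # query-gap columns: background-only columns interleaved at random
        n_extra = rng.binomial(ncols, config.query_gap_rate)
        insert_at = np.sort(rng.integers(0, ncols + 1, size=n_extra))
        q_chars = list(query)
        bg_cols = [list(bg[:, j]) for j in range(ncols)]
        cons_flags = list(conserved)
        true_chars = list(truth.protein_true)
        for offset, at in enumerate(insert_at):
            j = at + offset
            q_chars.insert(j, "-")
            bg_cols.insert(j, list(aa_arr[rng.integers(0, 20, size=n_bg)]))
            cons_flags.insert(j, False)
            true_chars.insert(j, "-")
        rows = {truth.gene_id: "".join(q_chars)}
        for b in range(n_bg):
            rows[f"taxon{b + 1:02d}"] = "".join(col[b] for col in bg_cols)
        msas[og_id] = rows
        for j, (flag, q, tr) in enumerate(zip(cons_flags, q_chars, true_chars)):
            col_truth.append(OGColumnTruth(og_id, j, bool(flag), q, tr))
    return msas, col_truth


def _spliced_to_genomic(model: GeneModel, offset: int) -> int:
    """Genomic coordinate of a spliced-transcript nucleotide offset.

    For plus-strand models the returned coordinate is the position of that
    base; for minus-strand it is the position *after* it (so spans can be
    built half-open from the transcript 5' end).
    """
    segs = model.cds_segments if model.strand == "+" \
        else list(reversed(model.cds_segments))
    rem = offset
    for a, b in segs:
        length = b - a
        if rem < length or (a, b) == segs[-1]:
            return a + rem if model.strand == "+" else b - rem
        rem -= length
    raise ValueError("offset outside spliced transcript")


def simulate_alignments(config: SynthConfig, bundle: GenomeBundle,
                        eval_table_id: int) -> List[AlignmentRecord]:
    """Pseudo-reference protein-to-genome alignments under one translation table.

    When the evaluation table treats an internal codon as a stop, the
    alignment is truncated just before it; otherwise it extends to the last
    sense codon.  Gene models lacking a stop codon get a query longer than
    the alignable span (a reference protein would extend past the truncated
    model), so they never register as full-C-terminus alignments.
    """
    table = load_table(eval_table_id)
    records = []
    for model, truth in zip(bundle.models, bundle.truths):
        internal = truth.internal_codons
        n_internal = len(internal)
        first_stop = next((i for i, c in enumerate(internal) if table.is_stop(c)),
                          None)
        qend = first_stop if first_stop is not None else n_internal
        qlen = n_internal if truth.has_stop else n_internal + 25
        contig_len = len(bundle.contigs[model.seq_id])
        if model.strand == "+":
            tstart = _spliced_to_genomic(model, 0)
            tend = _spliced_to_genomic(model, 3 * qend - 1) + 1
        else:
            tend = _spliced_to_genomic(model, 0)
            tstart = _spliced_to_genomic(model, 3 * qend - 1) - 1
        records.append(AlignmentRecord(
            query_id=f"ref_{model.gene_id}", query_len=qlen, query_start=0,
            query_end=qend, strand=model.strand, target_id=model.seq_id,
            target_len=contig_len, target_start=tstart, target_end=tend,
            n_match=qend, alignment_len=qend, mapq=60))
    return records


# ---------------------------------------------------------------------------
# tRNA templates.  These are synthetic cloverleaves built segment by segment
# (acceptor stem 7 bp, D-arm 4 bp + 8 nt loop, anticodon arm 5 bp + 7 nt
# loop, variable region, T-arm 5 bp + 7 nt loop, discriminator, no CCA);
# they are stand-ins constructed to carry -- or deliberately violate -- the
# leucine identity elements, not natural sequences.

_ACC5_LEU = "GGCAGTG"   # pair 4 = A-U, pair 5 = G-C
_ACC5_GLN = "GGCTATG"   # pairs 4/5 violated
_DLOOP_LEU = "ATCTGGTA"  # G18 G19 A21
_DLOOP_GLN = "ATCTAATA"  # G18/G19 absent
_TLOOP = "TTCGAAT"       # U54 U55 C56 A58
_VAR_LEU = "GGTTAGAGTCTAA"  # 13 nt: large (type II) variable region
_VAR_GLN = "ATCA"


def _build_trna(acc5: str, dloop: str, anticodon: str, var: str,
                discriminator: str) -> Tuple[str, str]:
    dstem5, dstem3 = "GCTC", "GAGC"
    acstem5, acstem3 = "CTGGC", "GCCAG"
    tstem5, tstem3 = "GTGGC", "GCCAC"
    acloop = "CT" + anticodon + "AA"
    seq = (acc5 + "TA" + dstem5 + dloop + dstem3 + "A" + acstem5 + acloop
           + acstem3 + var + tstem5 + _TLOOP + tstem3 + revcomp(acc5)
           + discriminator)
    struct = (">" * len(acc5) + ".." + ">" * 4 + "." * len(dloop) + "<" * 4
              + "." + ">" * 5 + "." * 7 + "<" * 5 + "." * len(var)
              + ">" * 5 + "." * 7 + "<" * 5 + "<" * len(acc5) + ".")
    return seq, struct


def leu_template(anticodon: str = "CAA") -> Tuple[str, str]:
    """An element-complete synthetic leucine tRNA with the given anticodon."""
    return _build_trna(_ACC5_LEU, _DLOOP_LEU, anticodon, _VAR_LEU, "A")


def gln_decoy(anticodon: str = "TTG") -> Tuple[str, str]:
    """A synthetic glutamine tRNA violating the leucine identity elements."""
    return _build_trna(_ACC5_GLN, _DLOOP_GLN, anticodon, _VAR_GLN, "G")


def _mutate(rng, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_trnas(config: SynthConfig) -> TRNABundle:
    """Emit canonical decoy tRNAs and, when configured, CTA suppressors.

    The first suppressor is the leucine template with its anticodon switched
    to CTA; each further suppressor carries ``suppressor_mutations``
    additional substitutions relative to the first (one in the anticodon
    loop outside the anticodon, the rest in the variable loop), mirroring a
    recently diverged suppressor pair.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TRNA])
    entries: List[Tuple[str, str, str, str, float, str, str, int]] = []
    # (key, isotype, anticodon, sequence+structure..., role fields)
    leu_caa_seq, leu_struct = leu_template("CAA")
    leu_taa_seq, _ = leu_template("TAA")
    gln_seq, gln_struct = gln_decoy("TTG")
    canon = [
        ("Leu", "CAA", leu_caa_seq, leu_struct, 62.4),
        ("Leu", "TAA", leu_taa_seq, leu_struct, 61.8),
        ("Gln", "TTG", gln_seq, gln_struct, 55.7),
    ]
    sups: List[Tuple[str, str, str, str, float, str, int]] = []
    if config.suppressor_trna:
        sup1_seq = leu_template("CTA")[0]
        sups.append(("Leu", "CTA", sup1_seq, leu_struct, 54.2, "template", 1))
        anticodon_loop_pos = len(_ACC5_LEU) + 2 + 4 + len(_DLOOP_LEU) + 4 + 1 + 5
        var_start = anticodon_loop_pos + 7 + 5
        for j in range(1, config.n_suppressors):
            kmut = config.suppressor_mutations
            positions = []
            if kmut >= 1:
                positions.append(anticodon_loop_pos + 6)  # loop pos 38
            n_var = min(max(kmut - 1, 0), len(_VAR_LEU))
            var_positions = var_start + rng.choice(len(_VAR_LEU), size=n_var,
                                                   replace=False)
            positions.extend(int(p) for p in var_positions)
            seq_j = _mutate(rng, sup1_seq, positions)
            sups.append(("Leu", "CTA", seq_j, leu_struct, 52.0 - j,
                         "sup1", len(positions)))

    trnas: List[TRNAGene] = []
    truths: List[TRNATruth] = []
    contigs: Dict[str, str] = {}

    def place(contig_name: str, items, spacing: int, cap: bool,
              minus_index: int = -1):
        flank = _random_dna(rng, 200, config.gc_bias)
        parts = []
        if cap:
            parts.append("CCCCAAA" * 3)
        parts.append(flank)
        pos = sum(len(p) for p in parts)
        placed = []
        for i, (isotype, anticodon, seq, struct, score) in enumerate(items):
            strand = "-" if i == minus_index else "+"
            genomic = seq if strand == "+" else revcomp(seq)
            parts.append(genomic)
            placed.append((pos, pos + len(seq), strand, isotype, anticodon,
                           seq, struct, score))
            pos += len(seq)
            spacer = _random_dna(rng, spacing, config.gc_bias)
            parts.append(spacer)
            pos += len(spacer)
        if cap:
            parts.append("GGGGTTT" * 3)
        contigs[contig_name] = "".join(parts)
        out = []
        for i, (b, e, strand, isotype, anticodon, seq, struct, score) in \
                enumerate(placed):
            out.append(TRNAGene(
                seq_id=contig_name, begin=b, end=e, strand=strand,
                isotype=isotype, anticodon=anticodon, score=score,
                trna_id=f"{contig_name}.trna{i + 1}",
                sequence=seq, structure=struct))
        return out

    canon_genes = place("trna_contig_canon",
                        [(i, a, s, st, sc) for i, a, s, st, sc in canon],
                        spacing=60, cap=False, minus_index=1)
    for t, (isotype, anticodon, _, _, _) in zip(canon_genes, canon):
        truths.append(TRNATruth(t.trna_id, "canonical", isotype, anticodon,
                                "", 0))
    trnas.extend(canon_genes)
    if sups:
        sup_genes = place("trna_contig_sup",
                          [(i, a, s, st, sc) for i, a, s, st, sc, _, _ in sups],
                          spacing=60, cap=config.telomere_cap)
        for t, (isotype, anticodon, _, _, _, template, nmut) in \
                zip(sup_genes, sups):
            truths.append(TRNATruth(t.trna_id, "suppressor", isotype,
                                    anticodon, template, nmut))
        trnas.extend(sup_genes)
    return TRNABundle(trnas=trnas, truths=truths, contigs=contigs)


# ---------------------------------------------------------------------------
# bundle writer


def _write_truth_genes(path, truths: Sequence[GeneTruth]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig\tstrand\tstart\tend\thas_start\thas_stop\t"
                 "stop_codon\ttarget_positions\tprotein_true\tprotein_masked\n")
        for t in truths:
            fh.write("\t".join([
                t.gene_id, t.contig, t.strand, str(t.start), str(t.end),
                str(t.has_start).lower(), str(t.has_stop).lower(),
                t.stop_codon, ",".join(map(str, t.target_positions)),
                t.protein_true, t.protein_masked]) + "\n")


def _write_truth_og(path, col_truth: Sequence[OGColumnTruth]) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tcolumn\tconserved\tquery_char\ttrue_residue\n")
        for c in col_truth:
            fh.write(f"{c.orthogroup_id}\t{c.column}\t"
                     f"{str(c.conserved).lower()}\t{c.query_char}\t"
                     f"{c.true_residue}\n")


def _write_truth_trna(path, truths: Sequence[TRNATruth]) -> None:
    with open(path, "w") as fh:
        fh.write("trna_id\trole\tisotype\tanticodon\ttemplate\tn_mutations\n")
        for t in truths:
            fh.write(f"{t.trna_id}\t{t.role}\t{t.isotype}\t{t.anticodon}\t"
                     f"{t.template}\t{t.n_mutations}\n")


def run_synth(config: SynthConfig, outdir, force: bool = False) -> dict:
    """Write the full synthetic bundle plus ground truth and a manifest.

    Returns the manifest (relative path -> sha256).  Refuses to write into an
    existing non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty "
                              "(pass force/--force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_genome(config)
    sio.write_fasta(outdir / "genome.fasta", bundle.contigs)
    sio.write_gff3(outdir / "genes.gff3", bundle.models,
                   {c: len(s) for c, s in bundle.contigs.items()})
    sio.write_fasta(outdir / "proteins.fasta", bundle.masked_proteins)
    _write_truth_genes(outdir / "truth_genes.tsv", bundle.truths)

    if config.n_orthogroups > 0:
        msadir = outdir / "msa"
        msadir.mkdir(exist_ok=True)
        msas, col_truth = simulate_orthogroups(config, bundle)
        for og_id, rows in msas.items():
            sio.write_fasta(msadir / f"{og_id}.fasta", rows)
        _write_truth_og(outdir / "truth_og_columns.tsv", col_truth)

    eval_tables = sorted({1, config.query_table_id})
    for tid in eval_tables:
        write_paf(outdir / f"alignments.table{tid}.paf",
                  simulate_alignments(config, bundle, tid))

    trna_bundle = simulate_trnas(config)
    write_trnascan(outdir / "trnas.tsv", trna_bundle.trnas)
    sio.write_fasta(outdir / "trna_contigs.fasta", trna_bundle.contigs)
    sio.write_fasta(outdir / "trnas.fasta",
                    {t.trna_id: t.sequence for t in trna_bundle.trnas})
    write_structures(outdir / "trnas_structure.tsv", trna_bundle.trnas)
    _write_truth_trna(outdir / "truth_trnas.tsv", trna_bundle.truths)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    manifest = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
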