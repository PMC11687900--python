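"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately re-reads the raw files with its own minimal
logic (hand parsing + Biopython translation) and shares no code path with
the stopshift package internals beyond the file formats themselves.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path

from Bio.Seq import Seq
from scipy.stats import binom

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def parse_fasta(path):
    seqs = {}
    name = None
    parts = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def parse_gff_genes(path):
    """gene_id -> (contig, strand, [(start0, end0), ...]) from CDS rows."""
    genes = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs["Parent"].rsplit(".t1", 1)[0]
            genes.setdefault(gid, (f[0], f[6], []))[2].append(
                (int(f[3]) - 1, int(f[4])))
    return genes


def masked_protein(genome, contig, strand, segments, table_id,
                   mask=("TAA", "TAG", "TGA")):
    """Translate a gene with candidate codons masked; Biopython does the codes.

    Returns (protein, codons, complete) where ``codons`` excludes the
    terminal stop and ``complete`` means start + terminal stop + in frame.
    """
    parts = [genome[contig][a:b] for a, b in sorted(segments)]
    seq = "".join(parts)
    if strand == "-":
        seq = rc(seq)
    if len(seq) % 3:
        return None, None, False
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    stops = {"TAA", "TAG", "TGA"} - {
        c for c in ("TAA", "TAG", "TGA")
        if str(Seq(c).translate(table=table_id)) != "*"}
    has_stop = codons and codons[-1] in stops
    body = codons[:-1] if has_stop else codons
    has_start = bool(codons) and codons[0] == "ATG"
    prot = []
    for c in body:
        if c in mask:
            prot.append("X")
        elif c in stops:
            return None, None, False  # internal stop: excluded
        else:
            prot.append(str(Seq(c).translate(table=table_id)))
    return "".join(prot), body, has_start and has_stop


def recount_aa_counts(bundle_dir, table_id, threshold=0.70, min_depth=4,
                      codon="TAG"):
    """Brute-force recount of conserved-site votes for one codon.

    Re-reads genome.fasta, genes.gff3 and every msa/*.fasta from scratch and
    tallies the modal background residue at each alignment column holding a
    masked occurrence of ``codon``, applying the identity threshold.
    """
    bundle_dir = Path(bundle_dir)
    genome = parse_fasta(bundle_dir / "genome.fasta")
    genes = parse_gff_genes(bundle_dir / "genes.gff3")
    votes = Counter()
    for msa_path in sorted((bundle_dir / "msa").glob("*.fasta")):
        msa = parse_fasta(msa_path)
        query_id = next(n for n in msa if n in genes)
        contig, strand, segs = genes[query_id]
        prot, body, complete = masked_protein(genome, contig, strand, segs,
                                              table_id)
        if not complete:
            continue
        row = msa[query_id]
        assert row.replace("-", "") == prot
        residue = 0
        for col, ch in enumerate(row):
            if ch == "-":
                continue
            if ch == "X" and body[residue] == codon:
                column = [msa[n][col] for n in msa if n != query_id]
                column = [c for c in column if c not in "-X."]
                if len(column) >= min_depth:
                    counts = Counter(column).most_common()
                    if len(counts) == 1 or counts[0][1] > counts[1][1]:
                        aa, n = counts[0]
                        if n / len(column) >= threshold - 1e-9:
                            votes[aa] += 1
            residue += 1
    return dict(votes)


def binom_ci_contains(k: int, n: int, p: float, conf: float = 0.99) -> bool:
    """Is ``k`` successes within the central ``conf`` interval of Bin(n, p)?"""
    alpha = (1 - conf) / 2
    lo = binom.ppf(alpha, n, p)
    hi = binom.ppf(1 - alpha, n, p)
    return lo <= k <= hi
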