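"""Stop-codon usage, relative synonymous usage, internal-codon prevalence, GC.

All gene-level statistics are restricted to complete gene models (predicted
start and stop codon, in frame, no internal stop under the applied table);
partial models would otherwise bias the stop-codon denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .genetic_code import (CodingSequence, GeneticCodeTable, STANDARD_STOPS,
                           dna_to_rna, rna_to_dna)

log = logging.getLogger(__name__)


@dataclass
class UsageReport:
    genome_id: str
    n_complete_genes: int
    stop_fractions: Dict[str, float]
    family_usage: Dict[str, float]
    internal_prevalence: float
    gc: float


def stop_usage(cds_list: Iterable[CodingSequence],
               table: GeneticCodeTable) -> Dict[str, float]:
    """Fraction of complete genes terminating with each stop codon.

    Denominators count complete genes whose terminal codon is a stop under
    the applied table; a "complete" gene ending in a non-stop codon is
    excluded and logged.  Keys cover every stop codon of the table (plus any
    standard stop, reported as 0 when reassigned).
    """
    counts = {c: 0 for c in sorted(set(STANDARD_STOPS) | set(table.stop_codons))}
    n = 0
    for cds in cds_list:
        if not cds.complete:
            continue
        terminal = cds.codons[-1]
        if not table.is_stop(terminal):
            log.warning("%s: complete gene ends %s, not a stop under table %d; "
                        "excluded", cds.gene_id, terminal, table.table_id)
            continue
        counts[terminal] += 1
        n += 1
    if n == 0:
        raise ValueError("no complete genes with a recognized stop codon")
    return {c: counts[c] / n for c in counts}


def synonymous_usage(cds_list: Iterable[CodingSequence],
                     table: GeneticCodeTable, amino_acid: str,
                     include_codon: str) -> Dict[str, float]:
    """Relative usage of each codon within one amino acid's family.

    Family membership follows the applied table (so TAG is the 7th leucine
    codon under table 16 and the 3rd glutamine codon under table 15).  Only
    internal codons count; the terminal stop is excluded.
    """
    include_codon = rna_to_dna(include_codon)
    if table.codon_map.get(include_codon) != amino_acid:
        raise ValueError(
            f"{include_codon} maps to {table.codon_map.get(include_codon)!r}, "
            f"not {amino_acid!r}, under table {table.table_id}")
    family = table.family(amino_acid)
    if not family:
        raise ValueError(f"no codons for {amino_acid!r} under table {table.table_id}")
    counts = {c: 0 for c in family}
    for cds in cds_list:
        if not cds.complete:
            continue
        for c in cds.internal_codons:
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no internal {amino_acid} codons observed")
    return {c: counts[c] / total for c in sorted(counts)}


def internal_codon_prevalence(cds_list: Iterable[CodingSequence],
                              codon: str) -> float:
    """Fraction of complete genes containing >= 1 internal occurrence."""
    codon = rna_to_dna(codon)
    complete = [c for c in cds_list if c.complete]
    if not complete:
        raise ValueError("no complete genes")
    with_hit = sum(1 for c in complete if codon in c.internal_codons)
    return with_hit / len(complete)


def gc_content(genome: Mapping[str, str]) -> float:
    """(G+C)/(A+C+G+T) over all contigs; N excluded from the denominator."""
    gc = 0
    atgc = 0
    for seq in genome.values():
        s = (str(seq.seq) if hasattr(seq, "seq") else str(seq)).upper()
        gc += s.count("G") + s.count("C")
        atgc += sum(s.count(b) for b in "ACGT")
    if atgc == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return gc / atgc


def usage_report(genome_id: str, genome: Mapping[str, str],
                 cds_list: Sequence[CodingSequence],
                 table: GeneticCodeTable,
                 target_codon: str = "TAG",
                 family_aa: Optional[str] = None) -> UsageReport:
    """Assemble the per-genome usage report.

    ``family_aa`` defaults to the target codon's meaning under the table
    when it is sense there; family usage is omitted when the target is a
    stop codon under the applied table.
    """
    target_codon = rna_to_dna(target_codon)
    complete = [c for c in cds_list if c.complete]
    stops = stop_usage(cds_list, table)
    fam: Dict[str, float] = {}
    if family_aa is None and not table.is_stop(target_codon):
        family_aa = table.codon_map[target_codon]
    if family_aa is not None:
        fam = synonymous_usage(cds_list, table, family_aa, target_codon)
    return UsageReport(
        genome_id=genome_id,
        n_complete_genes=len(complete),
        stop_fractions={dna_to_rna(c): f for c, f in stops.items()},
        family_usage={dna_to_rna(c): f for c, f in fam.items()},
        internal_prevalence=internal_codon_prevalence(cds_list, target_codon),
        gc=gc_content(genome))


def write_usage_tsv(path, reports: Sequence[UsageReport]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tn_complete_genes\tgc\tinternal_prevalence\t"
                 "stop_fractions\tfamily_usage\n")
        for r in reports:
            stops = ",".join(f"{k}:{v:.4f}" for k, v in sorted(r.stop_fractions.items()))
            fam = ",".join(f"{k}:{v:.4f}" for k, v in sorted(r.family_usage.items()))
            fh.write(f"{r.genome_id}\t{r.n_complete_genes}\t{r.gc:.4f}\t"
                     f"{r.internal_prevalence:.4f}\t{stops}\t{fam}\n")
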