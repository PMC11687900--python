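"""Codon tables, CDS extraction, and masked translation.

The package works with four NCBI nuclear translation tables that matter for
ciliate genetic-code evolution:

* table 1  -- the standard code (UAA/UAG/UGA stop);
* table 6  -- the ciliate nuclear code (UAA/UAG -> Gln, UGA stop);
* table 15 -- UAG -> Gln, UAA/UGA stop;
* table 16 -- UAG -> Leu, UAA/UGA stop.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive.  Sequences are DNA (T, not U) internally; report writers may render
codons with U.  Translation supports *masking*: internal occurrences of a
candidate codon (e.g. TAG in a genome suspected of UAG reassignment) are
rendered as ``X`` so that downstream conserved-column voting can locate them
in orthogroup alignments without committing to an amino-acid meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP = "*"
SUPPORTED_TABLE_IDS = (1, 6, 15, 16)
STANDARD_STOPS = ("TAA", "TAG", "TGA")

_BASES = "TCAG"
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-insensitive)."""
    return str(Seq(seq).reverse_complement())


def dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCodeTable:
    """A 64-codon -> amino-acid map keyed by NCBI translation-table number."""

    table_id: int
    codon_map: Mapping[str, str]  # codon -> one-letter aa, or "*" for stop
    start_codons: frozenset
    name: str = ""

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_map.items() if aa == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon.upper()) == STOP

    def family(self, amino_acid: str) -> tuple:
        """All codons translated to ``amino_acid`` under this table."""
        return tuple(c for c in CODONS if self.codon_map[c] == amino_acid)


def load_table(table_id: int) -> GeneticCodeTable:
    """Load an NCBI translation table as a :class:`GeneticCodeTable`.

    Only the nuclear tables relevant here (1, 6, 15, 16) are supported; any
    other id raises ``ValueError`` naming the supported set.
    """
    if table_id not in SUPPORTED_TABLE_IDS:
        raise ValueError(
            f"unsupported translation table {table_id!r}; "
            f"supported ids: {list(SUPPORTED_TABLE_IDS)}"
        )
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    codon_map = {c: bio.forward_table.get(c, STOP) for c in CODONS}
    table = GeneticCodeTable(
        table_id=table_id,
        codon_map=codon_map,
        start_codons=frozenset(bio.start_codons),
        name=bio.names[0] if bio.names else "",
    )
    assert len(table.codon_map) == 64
    return table


@dataclass
class GeneModel:
    """A protein-coding gene model on a genome assembly.

    ``cds_segments`` are 0-based half-open genomic intervals sorted by
    genomic start; for minus-strand genes transcript order is the reverse.
    ``phase`` is the GFF3 phase of the first segment in transcript order
    (number of bases to discard before the first complete codon).
    """

    gene_id: str
    seq_id: str
    strand: str
    cds_segments: list
    phase: int = 0
    has_start: Optional[bool] = None  # None = infer at extraction
    has_stop: Optional[bool] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        segs = sorted(tuple(s) for s in self.cds_segments)
        for (a, b), (c, d) in zip(segs, segs[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        self.cds_segments = segs

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]


@dataclass
class CodingSequence:
    """Strand-resolved codon list extracted for one gene model."""

    gene_id: str
    codons: list  # trinucleotides, terminal stop included when present
    has_start: bool = False
    has_stop: bool = False
    frame_error: bool = False  # spliced length not divisible by 3
    truncated: bool = False  # internal unmasked stop seen at translation
    protein: str = ""

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop and not self.frame_error and not self.truncated

    @property
    def internal_codons(self) -> list:
        """Codons excluding the terminal stop (when present)."""
        return self.codons[:-1] if self.has_stop else list(self.codons)


def _contig_str(genome: Mapping, seq_id: str) -> str:
    seq = genome[seq_id]
    return str(seq.seq) if hasattr(seq, "seq") else str(seq)


def extract_cds(genome: Mapping, model: GeneModel,
                table: GeneticCodeTable) -> CodingSequence:
    """Extract the spliced, strand-resolved codon list for ``model``.

    ``genome`` maps contig id -> sequence (plain string or SeqRecord).
    Completeness flags are inferred against ``table`` (first codon a start
    codon; last codon a stop) unless the model carries explicit flags.
    Out-of-bounds coordinates raise; a spliced length not divisible by 3
    sets ``frame_error`` (the gene is then excluded from complete-gene
    statistics downstream).
    """
    if model.seq_id not in genome:
        raise KeyError(f"{model.gene_id}: contig {model.seq_id!r} not in genome")
    contig = _contig_str(genome, model.seq_id).upper()
    for a, b in model.cds_segments:
        if a < 0 or b > len(contig) or a >= b:
            raise ValueError(
                f"{model.gene_id}: segment ({a},{b}) outside contig "
                f"{model.seq_id} of length {len(contig)}"
            )
    parts = [contig[a:b] for a, b in model.cds_segments]
    if model.strand == "-":
        spliced = "".join(revcomp(p) for p in reversed(parts))
    else:
        spliced = "".join(parts)
    spliced = spliced[model.phase:]
    n_rem = len(spliced) % 3
    frame_error = n_rem != 0
    if frame_error:
        log.warning("%s: spliced length %d not divisible by 3",
                    model.gene_id, len(spliced) + model.phase)
        spliced = spliced[: len(spliced) - n_rem]
    codons = [spliced[i:i + 3] for i in range(0, len(spliced), 3)]
    has_start = (model.has_start if model.has_start is not None
                 else bool(codons) and codons[0] in table.start_codons)
    has_stop = (model.has_stop if model.has_stop is not None
                else bool(codons) and table.is_stop(codons[-1]))
    return CodingSequence(
        gene_id=model.gene_id, codons=codons,
        has_start=has_start, has_stop=has_stop, frame_error=frame_error,
    )


def translate(cds: CodingSequence, table: GeneticCodeTable,
              mask_codon=None) -> str:
    """Translate ``cds`` under ``table``, masking candidate codons to ``X``.

    ``mask_codon`` is a single codon, an iterable of codons, or None.  Every
    *internal* occurrence of a masked codon yields ``X`` regardless of the
    table.  The terminal stop codon yields no residue.  Codons containing N
    (or other non-ACGT characters) yield ``X``.  An internal stop under the
    applied table that is not masked is rendered ``*``, logged, and sets
    ``cds.truncated`` (the gene then drops out of complete-gene statistics).

    The protein string is returned and also stored on ``cds.protein``.
    """
    if mask_codon is None:
        mask = frozenset()
    elif isinstance(mask_codon, str):
        mask = frozenset({rna_to_dna(mask_codon)})
    else:
        mask = frozenset(rna_to_dna(c) for c in mask_codon)
    body = cds.internal_codons
    out = []
    truncated = False
    for i, codon in enumerate(body):
        if codon in mask:
            out.append("X")
        elif any(b not in "ACGT" for b in codon):
            out.append("X")
        elif table.is_stop(codon):
            log.warning("%s: internal stop %s at codon %d under table %d",
                        cds.gene_id, codon, i, table.table_id)
            truncated = True
            out.append(STOP)
        else:
            out.append(table.codon_map[codon])
    cds.truncated = truncated
    cds.protein = "".join(out)
    return cds.protein
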