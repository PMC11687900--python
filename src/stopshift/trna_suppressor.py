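"""Suppressor-tRNA detection and leucine identity-element analysis.

A stop codon can only be read as sense if a tRNA decodes it.  This module
screens tRNA gene predictions (tRNAscan-SE tabular output) for anticodons
complementary to stop codons (CTA reading UAG; TTA reading UAA and, by
wobble, UAG; TCA reading UGA), derives a canonical position numbering from
the cloverleaf secondary structure, and checks the nucleotides and base
pairs that leucyl-tRNA synthetases recognise: the discriminator base A
(display label A72), the acceptor-stem determinants A4-U69 and G5-C68, a
long variable region (the type-II arm characteristic of Leu/Ser tRNAs),
and the invariant loop nucleotides G18, G19, A21, U33, U54, U55, C56, A58.

Element positions are evaluated structurally -- the discriminator is the
last unpaired 3' residue before any CCA tail, and the acceptor pairs are
the 4th and 5th base pairs of the acceptor stem -- so the checks do not
depend on any particular published numbering convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Align import PairwiseAligner

from .genetic_code import revcomp

log = logging.getLogger(__name__)

#: anticodon (DNA) -> stop codons decoded; TTA decodes both UAA and UAG by wobble
SUPPRESSOR_ANTICODONS = {
    "CTA": ("TAG",),
    "TTA": ("TAA", "TAG"),
    "TCA": ("TGA",),
}

TELOMERE_UNIT = "CCCCAAA"


@dataclass
class TRNAGene:
    """One predicted tRNA gene (coordinates 0-based half-open, explicit strand)."""

    seq_id: str
    begin: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    score: float
    trna_id: str = ""
    sequence: str = ""
    structure: str = ""
    intron: Optional[Tuple[int, int]] = None  # genomic, 0-based half-open
    decodes: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        self.anticodon = self.anticodon.upper().replace("U", "T")
        if self.sequence and self.structure and \
                len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.trna_id or self.seq_id}: sequence and "
                             "structure lengths differ")


def parse_trnascan(path) -> List[TRNAGene]:
    """Parse tRNAscan-SE tabular output.

    tRNAscan reports 1-based inclusive coordinates with begin > end on the
    minus strand; both are normalized here.  Malformed rows are skipped with
    their line numbers logged.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = re.split(r"\t|\s{2,}", line.rstrip("\n"))
            f = [x.strip() for x in f if x.strip()]
            if lineno <= 3 and (not f or not f[1:2] or not _is_int(f[1] if len(f) > 1 else "")):
                continue  # header / ruler lines
            if len(f) < 9 or not (_is_int(f[2]) and _is_int(f[3])):
                log.warning("%s line %d: malformed row skipped", path, lineno)
                continue
            begin, end = int(f[2]), int(f[3])
            if begin <= end:
                strand, b0, e0 = "+", begin - 1, end
            else:
                strand, b0, e0 = "-", end - 1, begin
            ib, ie = int(f[6]), int(f[7])
            intron = None
            if ib and ie:
                intron = (min(ib, ie) - 1, max(ib, ie))
            out.append(TRNAGene(
                seq_id=f[0], begin=b0, end=e0, strand=strand, isotype=f[4],
                anticodon=f[5], score=float(f[8]),
                trna_id=f"{f[0]}.trna{f[1]}", intron=intron))
    return out


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_trnascan(path, trnas: Iterable[TRNAGene]) -> None:
    """Write tRNAscan-SE-style tabular output (inverse of :func:`parse_trnascan`)."""
    with open(path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n")
        fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n")
        fh.write("--------\t------\t-----\t----\t----\t-----\t-----\t----\t-----\n")
        counters: Dict[str, int] = {}
        for t in trnas:
            counters[t.seq_id] = counters.get(t.seq_id, 0) + 1
            num = t.trna_id.rsplit("trna", 1)[-1] if t.trna_id else str(counters[t.seq_id])
            if t.strand == "+":
                begin, end = t.begin + 1, t.end
            else:
                begin, end = t.end, t.begin + 1
            ib, ie = (t.intron[0] + 1, t.intron[1]) if t.intron else (0, 0)
            fh.write(f"{t.seq_id}\t{num}\t{begin}\t{end}\t{t.isotype}\t"
                     f"{t.anticodon}\t{ib}\t{ie}\t{t.score:.1f}\n")


def attach_structures(trnas: Sequence[TRNAGene], path) -> None:
    """Attach sequences/structures from a 3-column TSV (id, sequence, structure)."""
    table = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                table[f[0]] = (f[1].upper(), f[2])
    for t in trnas:
        if t.trna_id in table:
            t.sequence, t.structure = table[t.trna_id]


def write_structures(path, trnas: Iterable[TRNAGene]) -> None:
    with open(path, "w") as fh:
        fh.write("trna_id\tsequence\tstructure\n")
        for t in trnas:
            fh.write(f"{t.trna_id}\t{t.sequence}\t{t.structure}\n")


def find_suppressors(trnas: Iterable[TRNAGene]) -> List[TRNAGene]:
    """tRNAs whose anticodon is complementary to a stop codon.

    Each returned gene is annotated with the stop codon(s) it decodes; a
    TTA anticodon is tagged as decoding both UAA and UAG (wobble pairing).
    """
    out = []
    for t in trnas:
        decoded = SUPPRESSOR_ANTICODONS.get(t.anticodon)
        if decoded:
            t.decodes = decoded
            out.append(t)
    return out


class CloverleafError(ValueError):
    """The structure string does not decompose into a cloverleaf."""


def _pair_table(structure: str) -> List[Tuple[int, int]]:
    stack = []
    pairs = []
    for i, ch in enumerate(structure):
        if ch == ">":
            stack.append(i)
        elif ch == "<":
            if not stack:
                raise CloverleafError("unbalanced structure string")
            pairs.append((stack.pop(), i))
        elif ch not in ".":
            raise CloverleafError(f"unexpected structure character {ch!r}")
    if stack:
        raise CloverleafError("unbalanced structure string")
    return sorted(pairs)


def _helices(pairs: Sequence[Tuple[int, int]]) -> List[List[Tuple[int, int]]]:
    helices = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


@dataclass
class Cloverleaf:
    """Index spans (half-open) of the cloverleaf segments of one tRNA."""

    acc5: Tuple[int, int]
    dstem5: Tuple[int, int]
    dloop: Tuple[int, int]
    dstem3: Tuple[int, int]
    acstem5: Tuple[int, int]
    acloop: Tuple[int, int]
    acstem3: Tuple[int, int]
    variable: Tuple[int, int]
    tstem5: Tuple[int, int]
    tloop: Tuple[int, int]
    tstem3: Tuple[int, int]
    acc3: Tuple[int, int]
    discriminator: int


def decompose(structure: str) -> Cloverleaf:
    """Decompose a dot/arrow structure string into cloverleaf segments.

    Expects an acceptor helix enclosing three hairpins (D, anticodon, T);
    a fourth hairpin between the anticodon and T arms is treated as a
    variable-region arm (type-II tRNAs).  Anything else raises
    :class:`CloverleafError`.
    """
    helices = _helices(_pair_table(structure))
    if len(helices) not in (4, 5):
        raise CloverleafError(f"{len(helices)} helices; expected 4 (or 5 with "
                              "a variable arm)")
    helices.sort(key=lambda h: h[0][0])
    acc = helices[0]
    inner = helices[1:]
    acc_open = (acc[0][0], acc[-1][0] + 1)
    acc_close = (acc[-1][1], acc[0][1] + 1)
    for h in inner:
        if not (acc_open[1] <= h[0][0] and h[0][1] < acc_close[0]):
            raise CloverleafError("inner helix not nested inside acceptor stem")
    if len(inner) == 3:
        d, ac, t = inner
        var_span = (ac[0][1] + 1, t[0][0])
    else:
        d, ac, varm, t = inner
        var_span = (ac[0][1] + 1, t[0][0])  # variable arm span included
    def spans(h):
        return ((h[0][0], h[-1][0] + 1),       # 5' strand
                (h[-1][0] + 1, h[-1][1]),      # loop
                (h[-1][1], h[0][1] + 1))       # 3' strand
    d5, dl, d3 = spans(d)
    a5, al, a3 = spans(ac)
    t5, tl, t3 = spans(t)
    if al[1] - al[0] < 5:
        raise CloverleafError("anticodon loop shorter than 5 nt")
    trailing = structure[acc_close[1]:]
    disc = acc_close[1] + len(trailing) - 1
    # ignore a genomically-encoded CCA tail when present
    return Cloverleaf(acc5=acc_open, dstem5=d5, dloop=dl, dstem3=d3,
                      acstem5=a5, acloop=al, acstem3=a3, variable=var_span,
                      tstem5=t5, tloop=tl, tstem3=t3, acc3=acc_close,
                      discriminator=disc)


def assign_numbering(trna: TRNAGene) -> Dict[str, int]:
    """Map canonical cloverleaf positions to sequence indices.

    Labels: acceptor 5' strand ``1..a``; linker from ``8``; D-stem from
    ``10``; D-loop from ``14``; D-stem 3' from ``22``; ``26``; anticodon
    stem from ``27``, loop ``32..38`` (anticodon 34-36), stem 3' from
    ``39``; variable region ``v1..vN``; T-stem from ``49``, loop from
    ``54``, stem 3' from ``61``; acceptor 3' strand ending at ``72`` (so
    base pairs sum to 73); discriminator ``disc``.  tRNAs with an intron
    must have it removed (:func:`remove_intron`) first.
    """
    if not trna.sequence or not trna.structure:
        raise CloverleafError(f"{trna.trna_id or trna.seq_id}: no structure")
    seq = trna.sequence.upper()
    cl = decompose(trna.structure)
    numbering: Dict[str, int] = {}

    def span_labels(span, first_label):
        for k, idx in enumerate(range(*span)):
            numbering[str(first_label + k)] = idx

    a = cl.acc5[1] - cl.acc5[0]
    span_labels(cl.acc5, 1)
    span_labels((cl.acc5[1], cl.dstem5[0]), 8)
    span_labels(cl.dstem5, 10)
    span_labels(cl.dloop, 14)
    span_labels(cl.dstem3, 22)
    span_labels((cl.dstem3[1], cl.acstem5[0]), 26)
    span_labels(cl.acstem5, 27)
    span_labels(cl.acloop, 32)
    span_labels(cl.acstem3, 39)
    for k, idx in enumerate(range(*cl.variable)):
        numbering[f"v{k + 1}"] = idx
    span_labels(cl.tstem5, 49)
    span_labels(cl.tloop, 54)
    span_labels(cl.tstem3, 61)
    span_labels(cl.acc3, 73 - a)
    # discriminator: last unpaired 3' residue before any CCA tail
    tail_start = cl.acc3[1]
    tail = seq[tail_start:]
    if tail.endswith("CCA") and len(tail) > 3:
        disc_idx = len(seq) - 4
    elif tail == "CCA":
        raise CloverleafError("no discriminator before CCA tail")
    else:
        disc_idx = len(seq) - 1
    if disc_idx < tail_start:
        raise CloverleafError("no residue 3' of the acceptor stem")
    numbering["disc"] = disc_idx
    # consistency: anticodon loop positions 34-36 hold the reported anticodon
    anticodon = "".join(seq[numbering[str(p)]] for p in (34, 35, 36)
                        if str(p) in numbering)
    if trna.anticodon and anticodon and anticodon != trna.anticodon:
        log.warning("%s: structure anticodon %s != reported %s",
                    trna.trna_id or trna.seq_id, anticodon, trna.anticodon)
    return numbering


def remove_intron(trna: TRNAGene) -> TRNAGene:
    """Return a copy with the intron span cut out of sequence and structure."""
    if trna.intron is None:
        return trna
    if trna.strand == "+":
        rel = (trna.intron[0] - trna.begin, trna.intron[1] - trna.begin)
    else:
        rel = (trna.end - trna.intron[1], trna.end - trna.intron[0])
    a, b = rel
    return replace(trna, sequence=trna.sequence[:a] + trna.sequence[b:],
                   structure=trna.structure[:a] + trna.structure[b:],
                   intron=None)


@dataclass
class IdentityElementReport:
    """Leucine identity-element evaluation for one tRNA.

    ``elements`` maps element name -> True/False/None (None = unevaluable,
    excluded from ``overall_pass``); elements in ``optional`` do not gate
    the overall verdict.
    """

    elements: Dict[str, Optional[bool]]
    optional: Tuple[str, ...]

    @property
    def overall_pass(self) -> bool:
        return all(v for name, v in self.elements.items()
                   if v is not None and name not in self.optional)


#: (element name, check kind, parameters); U written as T (DNA alphabet)
LEU_IDENTITY_ELEMENTS = (
    ("discriminator_A72", "position", ("disc", "A")),
    ("pair_A4_U69", "pair", ("4", "69", "A", "T")),
    ("pair_G5_C68", "pair", ("5", "68", "G", "C")),
    ("variable_region", "varlen", ()),
    ("G18", "position", ("18", "G")),
    ("G19", "position", ("19", "G")),
    ("A21", "position", ("21", "A")),
    ("U33", "position", ("33", "T")),
    ("U54", "position", ("54", "T")),
    ("U55", "position", ("55", "T")),
    ("C56", "position", ("56", "C")),
    ("A58", "position", ("58", "A")),
)

DEFAULT_OPTIONAL_ELEMENTS = ("pair_A4_U69",)
MIN_VARIABLE_REGION = 10


def check_identity_elements(trna: TRNAGene,
                            elements=LEU_IDENTITY_ELEMENTS,
                            optional=DEFAULT_OPTIONAL_ELEMENTS,
                            min_variable_region: int = MIN_VARIABLE_REGION
                            ) -> IdentityElementReport:
    """Evaluate the leucine identity elements on one tRNA.

    The A4-U69 acceptor pair is optional by default: naturally occurring
    suppressors can carry the swapped U4-A69 pair without losing leucine
    identity.
    """
    numbering = assign_numbering(trna)
    seq = trna.sequence.upper()
    n_var = sum(1 for k in numbering if k.startswith("v"))
    results: Dict[str, Optional[bool]] = {}
    for name, kind, params in elements:
        if kind == "position":
            label, want = params
            idx = numbering.get(label)
            results[name] = None if idx is None else seq[idx] == want
        elif kind == "pair":
            l5, l3, w5, w3 = params
            i5, i3 = numbering.get(l5), numbering.get(l3)
            if i5 is None or i3 is None:
                results[name] = None
            else:
                results[name] = seq[i5] == w5 and seq[i3] == w3
        elif kind == "varlen":
            results[name] = n_var >= min_variable_region
        else:
            raise ValueError(f"unknown element kind {kind!r}")
    return IdentityElementReport(elements=results, optional=tuple(optional))


def write_element_report_tsv(path, reports: Mapping[str, IdentityElementReport]) -> None:
    names = [e[0] for e in LEU_IDENTITY_ELEMENTS]
    with open(path, "w") as fh:
        fh.write("trna_id\t" + "\t".join(names) + "\toverall_pass\n")
        for trna_id in sorted(reports):
            rep = reports[trna_id]
            vals = ["NA" if rep.elements.get(n) is None else str(rep.elements[n])
                    for n in names]
            fh.write(f"{trna_id}\t" + "\t".join(vals)
                     + f"\t{rep.overall_pass}\n")


def _aligner(match: float = 1, mismatch: float = -1,
             gap_open: float = -2, gap_extend: float = -1) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, **scores
                      ) -> Tuple[float, int, int]:
    """Global-alignment percent identity between two nucleotide sequences.

    Returns ``(identity_percent, n_differences, alignment_length)`` where
    identity = matches / alignment columns and differences count mismatches
    plus gapped columns.  For equal-length sequences with no gaps this
    reduces to a plain Hamming comparison.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _aligner(**scores).align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    matches, mismatches, gaps = counts.identities, counts.mismatches, counts.gaps
    length = matches + mismatches + gaps
    return 100.0 * matches / length, mismatches + gaps, length


def nearest_isotype(suppressor: TRNAGene, canon: Sequence[TRNAGene]
                    ) -> Tuple[TRNAGene, float]:
    """The canonical tRNA most similar in sequence to a suppressor.

    Ties break by higher tRNAscan score, then lexicographic id.
    """
    if not canon:
        raise ValueError("empty canonical tRNA set")
    best = None
    best_key = None
    for t in sorted(canon, key=lambda t: t.trna_id):
        ident, _, _ = pairwise_identity(suppressor.sequence, t.sequence)
        key = (-ident, -t.score, t.trna_id)
        if best_key is None or key < best_key:
            best, best_key = (t, ident), key
    return best


def telomere_capped(contig: str, repeat_unit: str = TELOMERE_UNIT,
                    min_copies: int = 2, window: int = 100) -> bool:
    """True iff both contig ends carry tandem telomeric repeats.

    Each end must contain >= ``min_copies`` tandem copies of the repeat unit
    (or its reverse complement) within ``window`` nt of the contig end.
    """
    if not contig:
        raise ValueError("empty contig")
    contig = contig.upper()
    unit = repeat_unit.upper()
    # either strand may carry the repeat, and a window can start anywhere in
    # the repeat phase, so match every rotation of the unit and its complement
    rotations = {u[i:] + u[:i]
                 for u in (unit, revcomp(unit)) for i in range(len(u))}
    pattern = "|".join(f"(?:{re.escape(r)}){{{min_copies},}}"
                       for r in sorted(rotations))
    head = re.search(pattern, contig[:window]) is not None
    tail = re.search(pattern, contig[-window:]) is not None
    return head and tail
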