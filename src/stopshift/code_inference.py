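"""Infer the amino-acid meaning of candidate codons from orthogroup alignments.

The procedure: translate every gene model with the candidate stop codons
masked to ``X``; locate each masked residue in its orthogroup's multiple
sequence alignment; at each such column, ask what the other (background)
sequences say.  If the column is highly conserved -- the modal background
residue reaches a configurable identity threshold (default 70%, inclusive) --
the site casts one vote for that residue as the codon's meaning.  A codon
with enough qualifying sites and a dominant residue is called *sense* for
that residue; otherwise it remains *stop/undetermined*.

The identity denominator excludes the query row, gap characters, and ``X``
residues.  Modal ties discard the site (votes stay integer-valued and
conservative).  Columns with fewer than ``min_depth`` background residues are
ignored: a mode over a handful of residues is noise.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .genetic_code import (CodingSequence, GeneticCodeTable, STANDARD_STOPS,
                           extract_cds, load_table, rna_to_dna, translate)

log = logging.getLogger(__name__)

#: hits with identity >= this fraction qualify (inclusive at the boundary)
DEFAULT_THRESHOLD = 0.70
#: minimum non-gap background residues for a column to be informative
DEFAULT_MIN_DEPTH = 4
#: minimum qualifying sites before a sense call is attempted
DEFAULT_MIN_SITES = 20
#: minimum share of the top residue for a sense call
DEFAULT_CALL_FRACTION = 0.5

# guard against float representation of thresholds like 0.70
_EPS = 1e-9


@dataclass(frozen=True)
class ConservedSiteHit:
    """One masked in-frame codon mapped to one conserved alignment column."""

    orthogroup_id: str
    gene_id: str
    column_index: int
    query_codon: str
    n_background: int
    modal_aa: str
    identity: float


@dataclass
class CodonMeaningSummary:
    """Vote tally for one candidate codon over all qualifying conserved sites."""

    codon: str
    n_sites: int
    aa_counts: Dict[str, int]
    threshold: float = DEFAULT_THRESHOLD

    @property
    def top_aa(self) -> Optional[str]:
        if not self.aa_counts:
            return None
        # deterministic tie-break: count desc, then residue
        return min(self.aa_counts, key=lambda aa: (-self.aa_counts[aa], aa))

    @property
    def top_fraction(self) -> Optional[float]:
        if self.n_sites == 0:
            return None
        return self.aa_counts[self.top_aa] / self.n_sites

    @property
    def insufficient_evidence(self) -> bool:
        return self.n_sites == 0


def map_codons_to_columns(cds: CodingSequence, msa: Mapping[str, str],
                          query_id: str) -> List[Tuple[int, str]]:
    """Locate each masked (``X``) residue of the query in its alignment.

    Returns ``(column_index, codon)`` pairs, one per masked residue.  Gap
    characters in the query row consume no codon.  The ungapped query row
    must equal the masked protein residue-for-residue.
    """
    if query_id not in msa:
        raise KeyError(f"query {query_id!r} not in alignment")
    row = msa[query_id]
    ungapped = row.replace("-", "")
    if ungapped != cds.protein:
        raise ValueError(
            f"{cds.gene_id}: ungapped alignment row (len {len(ungapped)}) "
            f"does not match masked protein (len {len(cds.protein)})"
        )
    body = cds.internal_codons
    out = []
    residue_i = 0
    for col, ch in enumerate(row):
        if ch == "-":
            continue
        if ch == "X":
            out.append((col, body[residue_i]))
        residue_i += 1
    return out


def column_conservation(msa: Mapping[str, str], column_index: int,
                        query_id: str, min_depth: int = DEFAULT_MIN_DEPTH
                        ) -> Optional[Tuple[str, float, int]]:
    """Modal residue and identity at one column, over background rows only.

    The query row, gaps, and ``X`` residues are excluded.  Returns
    ``(modal_aa, identity, n_background)`` or ``None`` when the column is
    shallower than ``min_depth`` or the mode is tied.
    """
    counts = Counter()
    for name, row in msa.items():
        if name == query_id:
            continue
        ch = row[column_index]
        if ch in ("-", "X", "."):
            continue
        counts[ch] += 1
    n_background = sum(counts.values())
    if n_background < min_depth:
        return None
    ranked = counts.most_common(2)
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None  # modal tie: site discarded
    modal_aa, modal_n = ranked[0]
    return modal_aa, modal_n / n_background, n_background


def infer_codon_meaning(hits: Iterable[ConservedSiteHit], codon: str,
                        threshold: float = DEFAULT_THRESHOLD
                        ) -> CodonMeaningSummary:
    """Tally modal residues over hits whose identity meets the threshold."""
    codon = rna_to_dna(codon)
    aa_counts: Dict[str, int] = {}
    for hit in hits:
        if rna_to_dna(hit.query_codon) != codon:
            raise ValueError(f"hit codon {hit.query_codon} != {codon}")
        if hit.identity >= threshold - _EPS:
            aa_counts[hit.modal_aa] = aa_counts.get(hit.modal_aa, 0) + 1
    n_sites = sum(aa_counts.values())
    if n_sites == 0:
        log.info("codon %s: insufficient evidence (0 qualifying sites)", codon)
    return CodonMeaningSummary(codon=codon, n_sites=n_sites,
                               aa_counts=aa_counts, threshold=threshold)


def logo_counts(summary: CodonMeaningSummary) -> Dict[str, float]:
    """Residue frequencies (summing to 1) for sequence-logo rendering."""
    if summary.n_sites == 0:
        raise ValueError(f"codon {summary.codon}: no qualifying sites to plot")
    return {aa: n / summary.n_sites
            for aa, n in sorted(summary.aa_counts.items())}


def write_logo_counts(path, summary: CodonMeaningSummary) -> None:
    freqs = logo_counts(summary)
    with open(path, "w") as fh:
        fh.write("residue\tcount\tfrequency\n")
        for aa, f in freqs.items():
            fh.write(f"{aa}\t{summary.aa_counts[aa]}\t{f:.6f}\n")


@dataclass
class CodonCall:
    """A genetic-code call for one codon, with its evidence."""

    summary: CodonMeaningSummary
    call: str  # e.g. "sense:L" or "stop/undetermined"


def collect_hits(cds_by_gene: Mapping[str, CodingSequence],
                 msas: Mapping[str, Mapping[str, str]],
                 min_depth: int = DEFAULT_MIN_DEPTH
                 ) -> Dict[str, List[ConservedSiteHit]]:
    """Map every masked residue of every query to its conserved column.

    ``cds_by_gene`` must hold coding sequences whose ``protein`` was produced
    with the candidate codons masked.  Returns hits grouped by codon.
    """
    hits: Dict[str, List[ConservedSiteHit]] = {}
    for og_id in sorted(msas):
        msa = msas[og_id]
        query_ids = [name for name in msa if name in cds_by_gene]
        for query_id in query_ids:
            cds = cds_by_gene[query_id]
            for col, codon in map_codons_to_columns(cds, msa, query_id):
                cons = column_conservation(msa, col, query_id, min_depth)
                if cons is None:
                    continue
                modal_aa, identity, n_bg = cons
                hits.setdefault(codon, []).append(ConservedSiteHit(
                    orthogroup_id=og_id, gene_id=query_id, column_index=col,
                    query_codon=codon, n_background=n_bg,
                    modal_aa=modal_aa, identity=identity))
    return hits


def scan_all_codons(genome: Mapping[str, str], gene_models,
                    msas: Mapping[str, Mapping[str, str]],
                    table_id: int = 1,
                    candidate_codons=STANDARD_STOPS,
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    threshold: float = DEFAULT_THRESHOLD,
                    min_sites: int = DEFAULT_MIN_SITES,
                    call_fraction: float = DEFAULT_CALL_FRACTION
                    ) -> Dict[str, CodonCall]:
    """Run the masked-translation + conserved-column voting procedure.

    All candidate codons are masked in a single working translation, hits
    are grouped by the underlying codon, and each codon is called
    ``"sense:<aa>"`` when it accrues at least ``min_sites`` qualifying sites
    with a top residue share of at least ``call_fraction``; otherwise
    ``"stop/undetermined"``.  Only complete gene models vote.
    """
    candidates = tuple(rna_to_dna(c) for c in candidate_codons)
    table = load_table(table_id)
    cds_by_gene = {}
    n_partial = 0
    for model in gene_models:
        cds = extract_cds(genome, model, table)
        translate(cds, table, mask_codon=candidates)
        if cds.complete:
            cds_by_gene[model.gene_id] = cds
        else:
            n_partial += 1
    log.info("scan: %d complete gene models (%d excluded as partial/flagged)",
             len(cds_by_gene), n_partial)
    hits = collect_hits(cds_by_gene, msas, min_depth=min_depth)
    out = {}
    for codon in candidates:
        summary = infer_codon_meaning(hits.get(codon, []), codon, threshold)
        if (summary.n_sites >= min_sites
                and summary.top_fraction >= call_fraction):
            call = f"sense:{summary.top_aa}"
        else:
            call = "stop/undetermined"
        out[codon] = CodonCall(summary=summary, call=call)
    return out


def write_hits(path, hits: Mapping[str, List[ConservedSiteHit]]) -> None:
    with open(path, "w") as fh:
        fh.write("codon\torthogroup_id\tgene_id\tcolumn_index\t"
                 "n_background\tmodal_aa\tidentity\n")
        for codon in sorted(hits):
            for h in hits[codon]:
                fh.write(f"{codon}\t{h.orthogroup_id}\t{h.gene_id}\t"
                         f"{h.column_index}\t{h.n_background}\t{h.modal_aa}\t"
                         f"{h.identity:.4f}\n")
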