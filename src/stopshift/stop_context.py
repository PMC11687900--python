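"""Dual-meaning (stop vs. sense) tests that are independent of the annotation.

Two lines of evidence distinguish a genuinely reassigned codon from a codon
with a context-dependent dual meaning:

* **C-terminus tally** -- align reference proteins to the genome with a
  spliced protein aligner; wherever a query's C-terminus aligns, read the
  in-frame codon immediately 3' of the last aligned residue.  In a genome
  where a codon is pure stop, that flanking codon is almost always a stop
  codon; re-aligning under a table that treats the candidate as sense should
  *increase* the number of full-C-terminus alignments if the candidate never
  terminates translation.

* **Gene-body profile** -- if a codon moonlights as a stop, its in-frame
  occurrences should be depleted near the annotated stop codon.  The profile
  bins each internal occurrence by relative position and compares the
  candidate's terminal-tail mass against that of its synonymous codons,
  with a bootstrap over genes for the interval estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genetic_code import (CodingSequence, GeneticCodeTable, dna_to_rna,
                           revcomp, rna_to_dna)

log = logging.getLogger(__name__)

PAF_COLUMNS = ("query_id", "query_len", "query_start", "query_end", "strand",
               "target_id", "target_len", "target_start", "target_end",
               "n_match", "alignment_len", "mapq")


@dataclass(frozen=True)
class AlignmentRecord:
    """One protein-to-genome alignment (protein-query PAF dialect).

    Query coordinates are residues, target coordinates nucleotides; both
    half-open.  ``n_match`` is the aligner's residue-match count, used only
    to pick a best alignment per query.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int = 0
    alignment_len: int = 0
    mapq: int = 255

    @property
    def reaches_cterm(self) -> bool:
        return self.query_end == self.query_len


def read_paf(path) -> List[AlignmentRecord]:
    """Read a PAF file in the protein-query dialect (12 core columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                log.warning("%s line %d: %d columns, expected >=12; skipped",
                            path, lineno, len(f))
                continue
            out.append(AlignmentRecord(
                query_id=f[0], query_len=int(f[1]), query_start=int(f[2]),
                query_end=int(f[3]), strand=f[4], target_id=f[5],
                target_len=int(f[6]), target_start=int(f[7]),
                target_end=int(f[8]), n_match=int(f[9]),
                alignment_len=int(f[10]), mapq=int(f[11])))
    return out


def write_paf(path, records: Iterable[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(str(getattr(r, c)) for c in PAF_COLUMNS) + "\n")


def read_alignment_tsv(path) -> List[AlignmentRecord]:
    """Read the documented simplified tabular dialect (header + named columns)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            kwargs = {}
            for name in PAF_COLUMNS:
                if name in idx:
                    val = f[idx[name]]
                    kwargs[name] = val if name in ("query_id", "strand",
                                                   "target_id") else int(val)
            out.append(AlignmentRecord(**kwargs))
    return out


def best_per_query(records: Iterable[AlignmentRecord]) -> List[AlignmentRecord]:
    """Keep the single best alignment per query (by match count, then span)."""
    best: Dict[str, AlignmentRecord] = {}
    for r in records:
        cur = best.get(r.query_id)
        key = (r.n_match, r.query_end - r.query_start)
        if cur is None or key > (cur.n_match, cur.query_end - cur.query_start):
            best[r.query_id] = r
    return [best[q] for q in sorted(best)]


@dataclass
class StopContextTally:
    """Codon counts at positions immediately 3' of full-C-terminus alignments."""

    counts: Dict[str, int]
    n_cterm_alignments: int
    n_non_cterm: int
    n_truncated_at_contig_end: int

    @property
    def fractions(self) -> Dict[str, float]:
        if self.n_cterm_alignments == 0:
            return {}
        return {c: n / self.n_cterm_alignments
                for c, n in sorted(self.counts.items())}

    def fraction(self, codon: str) -> float:
        codon = rna_to_dna(codon)
        if self.n_cterm_alignments == 0:
            return 0.0
        return self.counts.get(codon, 0) / self.n_cterm_alignments


def tally_cterm_codons(alignments: Iterable[AlignmentRecord],
                       genome: Mapping[str, str],
                       best_hit_only: bool = True) -> StopContextTally:
    """Tally the in-frame codon just past each full-C-terminus alignment.

    Only records whose query aligns through its last residue contribute.
    The tallied codon is the trinucleotide immediately 3' of the last aligned
    codon in alignment orientation (reverse-complemented for minus-strand
    records).  A post-alignment codon falling off the contig goes to the
    ``truncated_at_contig_end`` bucket.  Every record lands in exactly one of
    {contributes, non-C-terminal, truncated-at-contig-end}.
    """
    records = list(alignments)
    if best_hit_only:
        records = best_per_query(records)
    counts: Dict[str, int] = {}
    n_cterm = 0
    n_non = 0
    n_trunc = 0
    for r in records:
        if not r.reaches_cterm:
            n_non += 1
            continue
        contig = genome[r.target_id]
        contig = str(contig.seq) if hasattr(contig, "seq") else str(contig)
        if r.strand == "+":
            a, b = r.target_end, r.target_end + 3
            if b > len(contig):
                n_trunc += 1
                continue
            codon = contig[a:b].upper()
        else:
            a, b = r.target_start - 3, r.target_start
            if a < 0:
                n_trunc += 1
                continue
            codon = revcomp(contig[a:b].upper())
        counts[codon] = counts.get(codon, 0) + 1
        n_cterm += 1
    return StopContextTally(counts=counts, n_cterm_alignments=n_cterm,
                            n_non_cterm=n_non,
                            n_truncated_at_contig_end=n_trunc)


def compare_tables(alignment_sets: Mapping[int, Iterable[AlignmentRecord]],
                   genome: Mapping[str, str],
                   stop_codons=("TAA", "TAG", "TGA"),
                   best_hit_only: bool = True):
    """Per-table full-C-terminus counts and stop-codon fractions.

    Returns ``(rows, best_table_id)`` where each row is a dict with the
    table id, the count of full-C-terminus alignments, and the fraction of
    tallied codons equal to each standard stop.  The flagged table is the one
    maximizing the C-terminus count (ties to the lowest id).
    """
    if len(alignment_sets) < 2:
        raise ValueError("compare_tables needs alignments under >= 2 tables")
    rows = []
    for table_id in sorted(alignment_sets):
        tally = tally_cterm_codons(alignment_sets[table_id], genome,
                                   best_hit_only=best_hit_only)
        row = {"table_id": table_id,
               "n_cterm_alignments": tally.n_cterm_alignments}
        for codon in stop_codons:
            row[f"frac_{dna_to_rna(codon)}"] = tally.fraction(codon)
        rows.append(row)
    best = max(rows, key=lambda r: (r["n_cterm_alignments"], -r["table_id"]))
    return rows, best["table_id"]


@dataclass
class GeneBodyProfile:
    """Positional frequency profile of a codon across gene bodies.

    Internal codons only (the terminal stop is excluded); occurrence ``i`` of
    a gene with ``L`` internal codons goes to bin ``floor(n_bins * i / L)``.
    ``freqs`` is normalized per codon to sum to 1; ``companions`` holds one
    normalized profile per synonymous codon.  Per-gene occurrence counts are
    retained so the depletion test can bootstrap over genes.
    """

    codon: str
    n_bins: int
    counts: np.ndarray
    companions: Dict[str, np.ndarray]
    per_gene_target: np.ndarray  # (n_genes, n_bins) occurrence counts
    per_gene_syn: np.ndarray     # pooled synonymous counts, same shape

    @property
    def n_occurrences(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)

    def companion_freqs(self, codon: str) -> np.ndarray:
        c = self.companions[rna_to_dna(codon)]
        total = c.sum()
        return c / total if total else c.astype(float)


def gene_body_profile(cds_list: Iterable[CodingSequence], codon: str,
                      synonymous_set: Sequence[str],
                      n_bins: int = 20) -> GeneBodyProfile:
    """Binned positional profile of ``codon`` and its synonymous companions.

    Only complete genes contribute.  Genes shorter than ``n_bins`` codons are
    binned by the same formula (some bins simply stay empty for them).
    """
    codon = rna_to_dna(codon)
    syn = [rna_to_dna(c) for c in synonymous_set]
    complete = [c for c in cds_list if c.complete]
    n_genes = len(complete)
    per_gene_target = np.zeros((n_genes, n_bins), dtype=np.int64)
    per_gene_syn = np.zeros((n_genes, n_bins), dtype=np.int64)
    companions = {c: np.zeros(n_bins, dtype=np.int64) for c in syn}
    for g, cds in enumerate(sorted(complete, key=lambda c: c.gene_id)):
        body = cds.internal_codons
        L = len(body)
        if L == 0:
            continue
        for i, c in enumerate(body):
            b = min(n_bins - 1, (n_bins * i) // L)
            if c == codon:
                per_gene_target[g, b] += 1
            elif c in companions:
                companions[c][b] += 1
                per_gene_syn[g, b] += 1
    return GeneBodyProfile(
        codon=codon, n_bins=n_bins,
        counts=per_gene_target.sum(axis=0),
        companions=companions,
        per_gene_target=per_gene_target, per_gene_syn=per_gene_syn)


@dataclass
class DepletionResult:
    ratio: float
    ci_low: float
    ci_high: float
    verdict: str  # "depleted" / "not depleted" / "insufficient data"
    n_occurrences: int
    tail_fraction: float


def depletion_test(profile: GeneBodyProfile, tail_fraction: float = 0.1,
                   n_boot: int = 1000, seed: Optional[int] = None,
                   min_occurrences: int = 50,
                   ci_level: float = 0.95) -> DepletionResult:
    """Terminal-tail depletion of the target codon relative to its synonyms.

    The statistic is the ratio of the target codon's profile mass in the
    terminal ``tail_fraction`` of bins to the pooled synonymous codons' mass
    in the same bins.  The interval is a percentile bootstrap over genes.
    Verdict is "depleted" iff the CI upper bound is below 1.
    """
    n_occ = profile.n_occurrences
    if n_occ < min_occurrences:
        return DepletionResult(float("nan"), float("nan"), float("nan"),
                               "insufficient data", n_occ, tail_fraction)
    n_tail = max(1, int(round(tail_fraction * profile.n_bins)))
    tail = slice(profile.n_bins - n_tail, profile.n_bins)

    tgt = profile.per_gene_target
    syn = profile.per_gene_syn
    n_genes = tgt.shape[0]

    def _ratio(tgt_mat, syn_mat):
        t_total = tgt_mat.sum()
        s_total = syn_mat.sum()
        if t_total == 0 or s_total == 0:
            return float("nan")
        t_tail = tgt_mat[..., tail].sum() / t_total
        s_tail = syn_mat[..., tail].sum() / s_total
        if s_tail == 0:
            return float("inf")
        return t_tail / s_tail

    ratio = _ratio(tgt, syn)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_genes, size=(n_boot, n_genes))
    # vectorized resample: per-bootstrap totals via fancy indexing
    t_tail_b = tgt[:, tail].sum(axis=1)[idx].sum(axis=1)
    t_tot_b = tgt.sum(axis=1)[idx].sum(axis=1)
    s_tail_b = syn[:, tail].sum(axis=1)[idx].sum(axis=1)
    s_tot_b = syn.sum(axis=1)[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (t_tail_b / t_tot_b) / (s_tail_b / s_tot_b)
    ratios = ratios[np.isfinite(ratios) | np.isposinf(ratios)]
    alpha = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(ratios, [alpha, 1.0 - alpha])
    verdict = "depleted" if ci_high < 1.0 else "not depleted"
    return DepletionResult(float(ratio), float(ci_low), float(ci_high),
                           verdict, n_occ, tail_fraction)


def write_tally_tsv(path, tally: StopContextTally) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tcount\tfraction\n")
        for codon in sorted(tally.counts):
            fh.write(f"{dna_to_rna(codon)}\t{tally.counts[codon]}\t"
                     f"{tally.fraction(codon):.6f}\n")
        fh.write(f"#n_cterm_alignments\t{tally.n_cterm_alignments}\n")
        fh.write(f"#n_non_cterm\t{tally.n_non_cterm}\n")
        fh.write(f"#n_truncated_at_contig_end\t{tally.n_truncated_at_contig_end}\n")


def write_profile_tsv(path, profile: GeneBodyProfile) -> None:
    with open(path, "w") as fh:
        fh.write("bin\t" + dna_to_rna(profile.codon) + "\t"
                 + "\t".join(dna_to_rna(c) for c in sorted(profile.companions))
                 + "\n")
        freqs = profile.freqs
        comp = {c: profile.companion_freqs(c) for c in profile.companions}
        for b in range(profile.n_bins):
            row = [str(b), f"{freqs[b]:.6f}"]
            row += [f"{comp[c][b]:.6f}" for c in sorted(comp)]
            fh.write("\t".join(row) + "\n")


def plot_profiles(profile: GeneBodyProfile, path) -> None:
    """Optional line plot of the target profile against its synonyms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(profile.n_bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in sorted(profile.companions):
        ax.plot(x, profile.companion_freqs(c), color="0.7", lw=1,
                label=dna_to_rna(c))
    ax.plot(x, profile.freqs, color="crimson", lw=2,
            label=dna_to_rna(profile.codon))
    ax.set_xlabel("relative position bin")
    ax.set_ylabel("frequency")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
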