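"""Shared FASTA / GFF3 / MSA readers and writers.

FASTA goes through Bio.SeqIO; GFF3 through gffutils (in-memory database,
restricted to gene/mRNA/CDS features with ID/Parent attributes).  Writers are
deliberately plain so that seeded synthetic runs are byte-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import gffutils
from Bio import SeqIO

from .genetic_code import GeneModel

log = logging.getLogger(__name__)


def read_fasta(path) -> Dict[str, str]:
    """Read a (possibly line-wrapped, multi-contig) FASTA into id -> sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_msa(path) -> Dict[str, str]:
    """Read one aligned FASTA; all rows must have equal length."""
    msa = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in msa.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: unequal row lengths {sorted(lengths)}")
    return msa


def read_msa_dir(directory) -> Dict[str, Dict[str, str]]:
    """Read every ``*.fa``/``*.fasta`` alignment in a directory, keyed by stem."""
    directory = Path(directory)
    out = {}
    for p in sorted(directory.glob("*.fa")) + sorted(directory.glob("*.fasta")):
        out[p.stem] = read_msa(p)
    return out


def read_gene_models(gff_path) -> List[GeneModel]:
    """Parse gene models (gene/mRNA/CDS) from a GFF3 file.

    CDS phase is honored when present; absent phase is taken as 0 and logged.
    Returns one :class:`GeneModel` per gene, using the first mRNA when a gene
    has several.
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds:
            cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            log.warning("gene %s has no CDS features; skipped", gene.id)
            continue
        segments = [(f.start - 1, f.end) for f in cds]  # GFF3 1-based inclusive
        first = cds[-1] if gene.strand == "-" else cds[0]
        if first.frame in ("0", "1", "2"):
            phase = int(first.frame)
        else:
            phase = 0
            log.debug("gene %s: CDS phase absent, assuming 0", gene.id)

        def _flag(feature, key):
            vals = feature.attributes.get(key)
            if not vals:
                return None
            return vals[0].lower() in ("1", "true", "yes")

        models.append(GeneModel(
            gene_id=gene.id, seq_id=gene.seqid, strand=gene.strand,
            cds_segments=segments, phase=phase,
            has_start=_flag(gene, "has_start"), has_stop=_flag(gene, "has_stop"),
        ))
    return models


def write_gff3(path, models: Iterable[GeneModel],
               contig_lengths: Mapping[str, int]) -> None:
    """Write gene models as gene/mRNA/CDS rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in contig_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for m in models:
            attrs = [f"ID={m.gene_id}"]
            if m.has_start is not None:
                attrs.append(f"has_start={str(m.has_start).lower()}")
            if m.has_stop is not None:
                attrs.append(f"has_stop={str(m.has_stop).lower()}")
            fh.write("\t".join([
                m.seq_id, "stopshift", "gene", str(m.start + 1), str(m.end),
                ".", m.strand, ".", ";".join(attrs)]) + "\n")
            mrna_id = f"{m.gene_id}.t1"
            fh.write("\t".join([
                m.seq_id, "stopshift", "mRNA", str(m.start + 1), str(m.end),
                ".", m.strand, ".", f"ID={mrna_id};Parent={m.gene_id}"]) + "\n")
            segs = m.cds_segments if m.strand == "+" else list(reversed(m.cds_segments))
            phase = m.phase
            rows = []
            for a, b in segs:
                rows.append((a, b, phase))
                phase = (3 - ((b - a - phase) % 3)) % 3
            for i, (a, b, ph) in enumerate(sorted(rows)):
                fh.write("\t".join([
                    m.seq_id, "stopshift", "CDS", str(a + 1), str(b),
                    ".", m.strand, str(ph),
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}"]) + "\n")
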