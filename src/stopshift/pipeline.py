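"""End-to-end orchestration: run every analysis stage on one or more genomes.

The pipeline executes, per genome: CDS extraction and masked translation ->
conserved-column codon-meaning voting -> C-terminus stop-context tally and
gene-body depletion test -> codon-usage statistics -> suppressor-tRNA
screening.  Sections whose optional inputs (orthogroup alignments,
protein-to-genome alignments, tRNA predictions) are absent are marked
"not run" rather than failing.  Reports are written as deterministic JSON
(plus TSV side files); every call carries its evidence counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from . import io as sio
from .code_inference import scan_all_codons
from .codon_usage import usage_report
from .genetic_code import load_table, rna_to_dna, extract_cds, translate
from .stop_context import (compare_tables, depletion_test, gene_body_profile,
                           read_paf, tally_cterm_codons, write_profile_tsv,
                           write_tally_tsv)
from .trna_suppressor import (attach_structures, check_identity_elements,
                              find_suppressors, nearest_isotype,
                              parse_trnascan, telomere_capped,
                              write_element_report_tsv)

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "conservation": 0.70,
    "min_depth": 4,
    "min_sites": 20,
    "call_fraction": 0.5,
    "tail_fraction": 0.1,
    "n_bins": 20,
    "n_boot": 1000,
}


@dataclass
class GenomeInputs:
    genome_id: str
    fasta: str
    gff3: str
    table_id: int = 1
    target_codon: str = "TAG"
    msa_dir: Optional[str] = None
    alignments: Optional[Dict[int, str]] = None  # table_id -> PAF path
    trnascan: Optional[str] = None
    trna_structures: Optional[str] = None
    trna_contigs: Optional[str] = None


@dataclass
class RunConfig:
    genomes: List[GenomeInputs]
    output_dir: str
    seed: int = 0
    candidate_codons: tuple = ("TAA", "TAG", "TGA")
    thresholds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self):
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds or {})
        self.thresholds = merged
        for key in ("conservation", "call_fraction", "tail_fraction"):
            if not 0.0 <= self.thresholds[key] <= 1.0:
                raise ValueError(f"threshold {key} outside [0,1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        genomes = []
        for g in data.pop("genomes"):
            if "alignments" in g and g["alignments"]:
                g["alignments"] = {int(k): v for k, v in g["alignments"].items()}
            genomes.append(GenomeInputs(**g))
        return cls(genomes=genomes, **data)

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "candidate_codons": list(self.candidate_codons),
            "thresholds": self.thresholds,
            "genomes": [g.__dict__ for g in self.genomes],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _analyze_genome(inputs: GenomeInputs, config: RunConfig, outdir: Path) -> dict:
    th = config.thresholds
    table = load_table(inputs.table_id)
    target = rna_to_dna(inputs.target_codon)
    candidates = tuple(rna_to_dna(c) for c in config.candidate_codons)
    genome = sio.read_fasta(inputs.fasta)
    models = sio.read_gene_models(inputs.gff3)
    cds_list = []
    for m in models:
        cds = extract_cds(genome, m, table)
        translate(cds, table, mask_codon=candidates)
        cds_list.append(cds)
    n_complete = sum(1 for c in cds_list if c.complete)
    log.info("%s: %d gene models, %d complete", inputs.genome_id,
             len(models), n_complete)
    report: dict = {
        "genome_id": inputs.genome_id,
        "table_id": inputs.table_id,
        "n_gene_models": len(models),
        "n_complete_genes": n_complete,
    }

    # --- conserved-column codon meaning ------------------------------------
    if inputs.msa_dir:
        msas = sio.read_msa_dir(inputs.msa_dir)
        calls = scan_all_codons(
            genome, models, msas, table_id=inputs.table_id,
            candidate_codons=candidates,
            min_depth=int(th["min_depth"]), threshold=th["conservation"],
            min_sites=int(th["min_sites"]), call_fraction=th["call_fraction"])
        report["genetic_code"] = {
            rna_to_dna(c): {
                "call": cc.call,
                "n_sites": cc.summary.n_sites,
                "top_aa": cc.summary.top_aa,
                "top_fraction": cc.summary.top_fraction,
                "aa_counts": dict(sorted(cc.summary.aa_counts.items())),
            } for c, cc in calls.items()}
    else:
        report["genetic_code"] = "not run"

    # --- stop-context tests -------------------------------------------------
    if inputs.alignments:
        sets = {tid: read_paf(p) for tid, p in sorted(inputs.alignments.items())}
        tallies = {}
        for tid, records in sets.items():
            tally = tally_cterm_codons(records, genome)
            tallies[str(tid)] = {
                "n_cterm_alignments": tally.n_cterm_alignments,
                "n_non_cterm": tally.n_non_cterm,
                "n_truncated_at_contig_end": tally.n_truncated_at_contig_end,
                "fractions": tally.fractions,
            }
            write_tally_tsv(outdir / f"{inputs.genome_id}.cterm_table{tid}.tsv",
                            tally)
        report["stop_context"] = {"tallies": tallies}
        if len(sets) >= 2:
            rows, best = compare_tables(sets, genome)
            report["stop_context"]["comparison"] = rows
            report["stop_context"]["best_table"] = best
    else:
        report["stop_context"] = "not run"

    # --- gene-body depletion -----------------------------------------------
    if not table.is_stop(target):
        family_aa = table.codon_map[target]
        synonyms = [c for c in table.family(family_aa) if c != target]
        profile = gene_body_profile(cds_list, target, synonyms,
                                    n_bins=int(th["n_bins"]))
        result = depletion_test(profile, tail_fraction=th["tail_fraction"],
                                n_boot=int(th["n_boot"]), seed=config.seed)
        write_profile_tsv(outdir / f"{inputs.genome_id}.gene_body.tsv", profile)
        report["gene_body"] = {
            "codon": rna_to_dna(target), "ratio": result.ratio,
            "ci": [result.ci_low, result.ci_high],
            "verdict": result.verdict,
            "n_occurrences": result.n_occurrences,
        }
    else:
        report["gene_body"] = "not run (target is a stop codon here)"

    # --- codon usage ---------------------------------------------------------
    usage = usage_report(inputs.genome_id, genome, cds_list, table,
                         target_codon=target)
    report["codon_usage"] = {
        "n_complete_genes": usage.n_complete_genes,
        "stop_fractions": usage.stop_fractions,
        "family_usage": usage.family_usage,
        "internal_prevalence": usage.internal_prevalence,
        "gc": usage.gc,
    }

    # --- suppressor tRNAs ----------------------------------------------------
    if inputs.trnascan:
        trnas = parse_trnascan(inputs.trnascan)
        if inputs.trna_structures:
            attach_structures(trnas, inputs.trna_structures)
        suppressors = find_suppressors(trnas)
        canon = [t for t in trnas if t not in suppressors]
        trna_contigs = (sio.read_fasta(inputs.trna_contigs)
                        if inputs.trna_contigs else {})
        sup_reports = []
        element_reports = {}
        for s in suppressors:
            entry = {
                "trna_id": s.trna_id, "anticodon": s.anticodon,
                "isotype": s.isotype, "decodes": list(s.decodes or ()),
                "score": s.score,
            }
            if s.sequence and s.structure:
                rep = check_identity_elements(s)
                element_reports[s.trna_id] = rep
                entry["identity_elements"] = {
                    k: v for k, v in rep.elements.items()}
                entry["identity_elements_pass"] = rep.overall_pass
                with_seq = [t for t in canon if t.sequence]
                if with_seq:
                    best, ident = nearest_isotype(s, with_seq)
                    entry["nearest_canonical"] = {
                        "trna_id": best.trna_id, "isotype": best.isotype,
                        "anticodon": best.anticodon,
                        "identity_percent": ident}
            if s.seq_id in trna_contigs:
                entry["contig_telomere_capped"] = telomere_capped(
                    trna_contigs[s.seq_id])
            sup_reports.append(entry)
        if element_reports:
            write_element_report_tsv(
                outdir / f"{inputs.genome_id}.trna_elements.tsv",
                element_reports)
        report["trna"] = {"n_trnas": len(trnas),
                          "suppressors": sup_reports}
    else:
        report["trna"] = "not run"

    return report


def run_analysis(config: RunConfig) -> List[dict]:
    """Run the full analysis; returns one report dict per genome.

    Writes ``<genome_id>.report.json`` and TSV side files into the output
    directory, plus a markdown summary of the genetic-code calls.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "stopshift_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    reports = []
    for inputs in config.genomes:
        report = _analyze_genome(inputs, config, outdir)
        report["provenance"] = provenance
        with open(outdir / f"{inputs.genome_id}.report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        reports.append(report)
    with open(outdir / "summary.md", "w") as fh:
        fh.write("# stopshift genetic-code calls\n\n")
        fh.write("| genome | codon | call | sites | top fraction |\n")
        fh.write("|---|---|---|---|---|\n")
        for r in reports:
            gc = r["genetic_code"]
            if gc == "not run":
                fh.write(f"| {r['genome_id']} | - | not run | - | - |\n")
                continue
            for codon in sorted(gc):
                e = gc[codon]
                tf = ("-" if e["top_fraction"] is None
                      else f"{e['top_fraction']:.3f}")
                fh.write(f"| {r['genome_id']} | {codon} | {e['call']} | "
                         f"{e['n_sites']} | {tf} |\n")
    return reports
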