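import numpy as np
import pytest

from stopshift.genetic_code import CodingSequence, load_table
from stopshift.stop_context import (AlignmentRecord, compare_tables,
                                    depletion_test, gene_body_profile,
                                    read_alignment_tsv, read_paf,
                                    tally_cterm_codons, write_paf)


def _rec(**kw):
    base = dict(query_id="q1", query_len=3, query_start=0, query_end=3,
                strand="+", target_id="c", target_len=100, target_start=0,
                target_end=9, n_match=3, alignment_len=3, mapq=60)
    base.update(kw)
    return AlignmentRecord(**base)


class TestPafIO:
    def test_round_trip(self, tmp_path):
        records = [_rec(), _rec(query_id="q2", strand="-", target_start=30,
                              target_end=39)]
        path = tmp_path / "a.paf"
        write_paf(path, records)
        assert read_paf(path) == records

    def test_short_rows_skipped(self, tmp_path):
        path = tmp_path / "a.paf"
        path.write_text("q1\t3\t0\n")
        assert read_paf(path) == []

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text(
            "query_id\tquery_len\tquery_start\tquery_end\tstrand\t"
            "target_id\ttarget_len\ttarget_start\ttarget_end\n"
            "q1\t3\t0\t3\t+\tc\t100\t0\t9\n")
        (rec,) = read_alignment_tsv(path)
        assert rec.query_id == "q1" and rec.target_end == 9


class TestTallyCterm:
    def test_plus_strand_counts_following_codon(self):
        genome = {"c": "ATGAAATTT" + "TAA" + "G" * 10}
        tally = tally_cterm_codons([_rec()], genome)
        assert tally.counts == {"TAA": 1}
        assert tally.n_cterm_alignments == 1

    def test_non_cterm_record_excluded(self):
        genome = {"c": "ATGAAATTTTAA" + "G" * 10}
        tally = tally_cterm_codons([_rec(query_end=2)], genome)
        assert tally.counts == {} and tally.n_non_cterm == 1

    def test_minus_strand_reverse_complement(self):
        # plus-strand flank reads TTA; the gene on the minus strand ends TAA
        genome = {"c": "G" * 10 + "TTA" + "TTTCATAAA"}
        rec = _rec(strand="-", target_start=13, target_end=22)
        tally = tally_cterm_codons([rec], genome)
        assert tally.counts == {"TAA": 1}

    def test_contig_end_goes_to_truncated_bucket(self):
        genome = {"c": "ATGAAATTT"}
        tally = tally_cterm_codons([_rec(target_len=9)], genome)
        assert tally.n_truncated_at_contig_end == 1
        assert tally.n_cterm_alignments == 0

    def test_every_record_classified_once(self, table16_bundle):
        from stopshift.synthdata import simulate_alignments
        records = simulate_alignments(table16_bundle.config, table16_bundle, 1)
        tally = tally_cterm_codons(records, table16_bundle.contigs)
        assert (tally.n_cterm_alignments + tally.n_non_cterm
                + tally.n_truncated_at_contig_end) == len(records)

    def test_best_hit_filter_keeps_one_per_query(self):
        genome = {"c": "ATGAAATTT" + "TAA" + "G" * 10}
        dup = [_rec(n_match=2, query_end=2), _rec(n_match=3)]
        tally = tally_cterm_codons(dup, genome)
        assert tally.counts == {"TAA": 1} and tally.n_non_cterm == 0


class TestCompareTables:
    def test_identical_sets_identical_rows(self):
        genome = {"c": "ATGAAATTT" + "TAA" + "G" * 10}
        rows, best = compare_tables({1: [_rec()], 16: [_rec()]}, genome)
        assert rows[0]["n_cterm_alignments"] == rows[1]["n_cterm_alignments"]
        assert rows[0]["frac_UAA"] == rows[1]["frac_UAA"] == 1.0
        assert best == 1  # tie resolves to the lowest table id

    def test_requires_two_tables(self):
        with pytest.raises(ValueError):
            compare_tables({1: []}, {})


_gene_counter = iter(range(10**6))


def _cds_with(codons, gene_id=None):
    cds = CodingSequence(gene_id or f"g{next(_gene_counter):06d}",
                        list(codons) + ["TAA"],
                        has_start=True, has_stop=True)
    cds.protein = "A" * len(codons)
    return cds


class TestGeneBodyProfile:
    def test_hand_binning_final_bin(self):
        codons = ["CTT"] * 9 + ["TAG"]  # target at index 9 of 10
        profile = gene_body_profile([_cds_with(codons)], "TAG", ["CTT"],
                                    n_bins=10)
        assert profile.counts[9] == 1 and profile.counts.sum() == 1

    def test_uniform_occurrences_near_flat(self):
        rng = np.random.default_rng(0)
        cds_list = []
        for g in range(300):
            codons = ["GCT"] * 100
            for i in rng.integers(0, 100, size=10):
                codons[i] = "TAG"
            cds_list.append(_cds_with(codons))
        profile = gene_body_profile(cds_list, "TAG", ["CTT"], n_bins=10)
        freqs = profile.freqs
        assert freqs.max() - freqs.min() < 0.05

    def test_input_order_invariance(self):
        genes = [_cds_with(["TAG"] + ["CTT"] * 5),
                 _cds_with(["CTT"] * 5 + ["TAG"])]
        a = gene_body_profile(genes, "TAG", ["CTT"], n_bins=5)
        b = gene_body_profile(genes[::-1], "TAG", ["CTT"], n_bins=5)
        assert (a.counts == b.counts).all()
        assert (a.per_gene_target == b.per_gene_target).all()

    def test_incomplete_genes_excluded(self):
        cds = _cds_with(["TAG"] * 5)
        cds.has_stop = False
        profile = gene_body_profile([cds], "TAG", ["CTT"], n_bins=5)
        assert profile.n_occurrences == 0


class TestDepletionTest:
    def test_identical_profiles_ratio_one(self):
        genes = []
        rng = np.random.default_rng(1)
        for g in range(80):
            codons = ["GCT"] * 60
            for i in rng.integers(0, 60, size=2):
                codons[i] = "TAG"
            # mirror each target occurrence with a synonymous one
            for i, c in enumerate(list(codons)):
                if c == "TAG" and i + 1 < 60:
                    codons[i - 1] = "CTT"
            genes.append(_cds_with(codons))
        profile = gene_body_profile(genes, "TAG", ["CTT"], n_bins=10)
        result = depletion_test(profile, seed=0)
        assert result.verdict == "not depleted"

    def test_insufficient_data_verdict(self):
        profile = gene_body_profile([_cds_with(["TAG"] + ["CTT"] * 9)],
                                    "TAG", ["CTT"], n_bins=5)
        assert depletion_test(profile).verdict == "insufficient data"

    def test_hard_depletion_detected(self):
        rng = np.random.default_rng(2)
        genes = []
        for g in range(200):
            codons = ["GCT"] * 100
            for i in rng.integers(0, 85, size=3):  # never in final 15%
                codons[i] = "TAG"
            for i in rng.integers(0, 100, size=12):
                codons[i] = "CTT"
            genes.append(_cds_with(codons))
        profile = gene_body_profile(genes, "TAG", ["CTT"], n_bins=20)
        result = depletion_test(profile, tail_fraction=0.1, seed=0)
        assert result.verdict == "depleted"
        assert result.ratio < 0.5
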