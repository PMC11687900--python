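from collections import Counter

import pytest

from stopshift.genetic_code import load_table
from stopshift.synthdata import (SynthConfig, leu_template, run_synth,
                                 simulate_alignments, simulate_genome,
                                 simulate_orthogroups, simulate_trnas)

from oracles import binom_ci_contains


class TestConfig:
    def test_stop_usage_on_sense_codon_rejected(self):
        with pytest.raises(ValueError, match="sense codon"):
            SynthConfig(query_table_id=16,
                        stop_usage={"TAA": 0.9, "TAG": 0.1})

    def test_stop_usage_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            SynthConfig(stop_usage={"TAA": 0.5, "TGA": 0.4})

    def test_default_stop_usage_follows_table(self):
        assert SynthConfig(query_table_id=16).stop_usage == {
            "TAA": 0.95, "TGA": 0.05}


class TestSimulateGenome:
    def test_seeded_regeneration_is_byte_identical(self, tmp_path):
        cfg = dict(seed=5, query_table_id=16, genes_per_genome=30,
                   n_orthogroups=3, suppressor_trna=True)
        m1 = run_synth(SynthConfig(**cfg), tmp_path / "a")
        m2 = run_synth(SynthConfig(**cfg), tmp_path / "b")
        assert m1 == m2  # manifests carry sha256 of every file

    def test_degenerate_stop_distribution(self):
        cfg = SynthConfig(seed=1, genes_per_genome=50, partial_gene_fraction=0,
                          stop_usage={"TAA": 1.0})
        bundle = simulate_genome(cfg)
        assert all(t.stop_codon == "TAA" for t in bundle.truths)

    def test_complete_genes_start_with_atg(self, table16_bundle):
        for t in table16_bundle.truths:
            if t.has_start:
                assert t.internal_codons[0] == "ATG"
            else:
                assert t.internal_codons[0] != "ATG"

    def test_reassigned_family_usage_within_binomial_ci(self):
        # ~1e4 leucine sites at 10% TAG usage
        cfg = SynthConfig(seed=2, query_table_id=16, genes_per_genome=1500,
                          mean_gene_len_codons=150,
                          reassigned_codon_family_usage=0.1)
        bundle = simulate_genome(cfg)
        table = load_table(16)
        leu = set(table.family("L"))  # includes TAG
        counts = Counter(c for t in bundle.truths for c in t.internal_codons
                         if c in leu)
        n = sum(counts.values())
        assert n > 10_000
        assert binom_ci_contains(counts["TAG"], n, 0.1)

    def test_telomere_caps_flank_every_contig(self):
        cfg = SynthConfig(seed=3, genes_per_genome=20, telomere_cap=True)
        bundle = simulate_genome(cfg)
        for seq in bundle.contigs.values():
            assert seq.startswith("CCCCAAA" * 2)
            assert seq.endswith("GGGGTTT" * 2)


class TestSimulateOrthogroups:
    def test_monomorphic_when_fully_conserved(self):
        cfg = SynthConfig(seed=4, genes_per_genome=10, n_orthogroups=3,
                          conserved_column_fraction=1.0,
                          column_identity_at_conserved=1.0,
                          gap_rate=0.0, query_gap_rate=0.0)
        bundle = simulate_genome(cfg)
        msas, _ = simulate_orthogroups(cfg, bundle)
        for rows in msas.values():
            query_id = next(n for n in rows if n.startswith("g"))
            bg = [rows[n] for n in rows if n != query_id]
            for col in range(len(bg[0])):
                assert len({row[col] for row in bg}) == 1

    def test_passing_fraction_tracks_configured_fraction(self):
        cfg = SynthConfig(seed=5, query_table_id=16, genes_per_genome=60,
                          n_orthogroups=50, conserved_column_fraction=0.4,
                          column_identity_at_conserved=0.85,
                          gap_rate=0.0, query_gap_rate=0.0)
        bundle = simulate_genome(cfg)
        msas, _ = simulate_orthogroups(cfg, bundle)
        n_pass = n_cols = 0
        for rows in msas.values():
            query_id = next(n for n in rows if n.startswith("g"))
            bg = [rows[n] for n in rows if n != query_id]
            for col in range(len(bg[0])):
                column = [row[col] for row in bg]
                top = Counter(column).most_common(1)[0][1]
                n_cols += 1
                n_pass += top / len(column) >= 0.70
        # every conserved column passes by construction; noise columns
        # essentially never do at depth 9
        assert binom_ci_contains(n_pass, n_cols, 0.4)

    def test_shallow_taxon_set_rejected(self, table16_bundle):
        cfg = SynthConfig(seed=1, n_taxa=4)
        with pytest.raises(ValueError, match="n_taxa"):
            simulate_orthogroups(cfg, table16_bundle)


class TestSimulateAlignments:
    @pytest.fixture(scope="class")
    def aligned(self, table16_bundle):
        cfg = table16_bundle.config
        return (simulate_alignments(cfg, table16_bundle, 1),
                simulate_alignments(cfg, table16_bundle, 16),
                table16_bundle.truths)

    def test_truncation_only_at_internal_stops_under_table(self, aligned):
        alns1, alns16, truths = aligned
        for r1, r16, t in zip(alns1, alns16, truths):
            has_tag = "TAG" in t.internal_codons
            if t.has_stop:
                assert r16.reaches_cterm
                assert r1.reaches_cterm == (not has_tag)
                if has_tag:
                    assert r1.query_end == t.internal_codons.index("TAG")
            else:
                assert not r1.reaches_cterm and not r16.reaches_cterm

    def test_cterm_count_increases_under_generating_table(self, aligned):
        alns1, alns16, truths = aligned
        n1 = sum(r.reaches_cterm for r in alns1)
        n16 = sum(r.reaches_cterm for r in alns16)
        assert any("TAG" in t.internal_codons for t in truths)
        assert n16 > n1


class TestSimulateTrnas:
    def test_no_suppressors_unless_configured(self):
        bundle = simulate_trnas(SynthConfig(seed=6, suppressor_trna=False))
        assert all(t.anticodon not in ("CTA", "TTA", "TCA")
                   for t in bundle.trnas)

    def test_configured_number_of_cta_records(self):
        bundle = simulate_trnas(SynthConfig(seed=6, suppressor_trna=True,
                                            n_suppressors=3))
        assert sum(t.anticodon == "CTA" for t in bundle.trnas) == 3

    def test_hamming_distances_by_construction(self):
        bundle = simulate_trnas(SynthConfig(seed=6, suppressor_trna=True,
                                            suppressor_mutations=5))
        sup1, sup2 = [t for t in bundle.trnas if t.anticodon == "CTA"]
        template, _ = leu_template("CAA")
        d_template = sum(a != b for a, b in zip(sup1.sequence, template))
        d_pair = sum(a != b for a, b in zip(sup1.sequence, sup2.sequence))
        assert d_template == 1  # anticodon switch only
        assert d_pair == 5
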