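import pytest

from stopshift.synthdata import (SynthConfig, gln_decoy, leu_template,
                                 simulate_trnas)
from stopshift.trna_suppressor import (CloverleafError, TRNAGene,
                                       assign_numbering,
                                       check_identity_elements,
                                       find_suppressors, nearest_isotype,
                                       pairwise_identity, parse_trnascan,
                                       telomere_capped, write_trnascan)


def _leu_trna(anticodon="CTA", mutate=None):
    seq, struct = leu_template(anticodon)
    if mutate:
        pos, base = mutate
        seq = seq[:pos] + base + seq[pos + 1:]
    return TRNAGene(seq_id="c", begin=0, end=len(seq), strand="+",
                    isotype="Leu", anticodon=anticodon, score=60.0,
                    trna_id="c.trna1", sequence=seq, structure=struct)


class TestParseTrnascan:
    def test_minus_strand_coordinates_normalized(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n"
            "Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
            "----\t----\t----\t----\t----\t----\t----\t----\t----\n"
            "c1\t1\t100\t30\tLeu\tCAA\t0\t0\t55.0\n")
        (t,) = parse_trnascan(path)
        assert (t.strand, t.begin, t.end) == ("-", 29, 100)

    def test_empty_after_header(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("Sequence\nName\n----\n")
        assert parse_trnascan(path) == []

    def test_writer_round_trip(self, tmp_path):
        bundle = simulate_trnas(SynthConfig(seed=8, suppressor_trna=True))
        path = tmp_path / "t.tsv"
        write_trnascan(path, bundle.trnas)
        parsed = parse_trnascan(path)
        for orig, back in zip(bundle.trnas, parsed):
            assert (orig.seq_id, orig.begin, orig.end, orig.strand,
                    orig.isotype, orig.anticodon, orig.score) == \
                   (back.seq_id, back.begin, back.end, back.strand,
                    back.isotype, back.anticodon, back.score)


class TestFindSuppressors:
    @pytest.mark.parametrize("anticodon,decodes", [
        ("CTA", ("TAG",)), ("TTA", ("TAA", "TAG")), ("TCA", ("TGA",))])
    def test_suppressor_anticodons(self, anticodon, decodes):
        (hit,) = find_suppressors([_leu_trna(anticodon)])
        assert hit.decodes == decodes

    def test_canonical_anticodon_not_returned(self):
        assert find_suppressors([_leu_trna("AAG")]) == []


class TestAssignNumbering:
    def test_discriminator_and_acceptor_pairs(self):
        trna = _leu_trna()
        numbering = assign_numbering(trna)
        seq = trna.sequence
        assert numbering["disc"] == len(seq) - 1
        assert seq[numbering["disc"]] == "A"
        # the 4th/5th acceptor base pairs carry A-U and G-C
        assert (seq[numbering["4"]], seq[numbering["69"]]) == ("A", "T")
        assert (seq[numbering["5"]], seq[numbering["68"]]) == ("G", "C")

    def test_anticodon_maps_to_positions_34_36(self):
        trna = _leu_trna("CTA")
        numbering = assign_numbering(trna)
        seq = trna.sequence
        assert "".join(seq[numbering[str(p)]] for p in (34, 35, 36)) == "CTA"

    def test_leu_variable_region_is_long(self):
        numbering = assign_numbering(_leu_trna())
        assert sum(1 for k in numbering if k.startswith("v")) >= 10

    def test_non_cloverleaf_structure_errors(self):
        trna = _leu_trna()
        trna.structure = "." * len(trna.sequence)
        with pytest.raises(CloverleafError):
            assign_numbering(trna)


class TestIdentityElements:
    def test_element_complete_template_passes(self):
        assert check_identity_elements(_leu_trna()).overall_pass

    def test_gln_decoy_fails(self):
        seq, struct = gln_decoy()
        trna = TRNAGene(seq_id="c", begin=0, end=len(seq), strand="+",
                        isotype="Gln", anticodon="TTG", score=50.0,
                        trna_id="c.trna2", sequence=seq, structure=struct)
        report = check_identity_elements(trna)
        assert not report.overall_pass
        assert report.elements["variable_region"] is False
        assert report.elements["G18"] is False

    def test_single_invariant_mutation_fails(self):
        trna = _leu_trna()
        g18 = assign_numbering(trna)["18"]
        report = check_identity_elements(_leu_trna(mutate=(g18, "A")))
        assert report.elements["G18"] is False
        assert not report.overall_pass

    def test_swapped_4_69_pair_is_tolerated(self):
        trna = _leu_trna()
        numbering = assign_numbering(trna)
        seq = list(trna.sequence)
        seq[numbering["4"]], seq[numbering["69"]] = "T", "A"
        trna.sequence = "".join(seq)
        report = check_identity_elements(trna)
        assert report.elements["pair_A4_U69"] is False
        assert report.overall_pass  # the pair is optional by default


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        ident, diff, length = pairwise_identity("ACGTACGT", "ACGTACGT")
        assert (ident, diff, length) == (100.0, 0, 8)

    def test_hand_alignment_single_mismatch(self):
        assert pairwise_identity("ACGT", "ACGA") == (75.0, 1, 4)

    def test_symmetry(self):
        a, b = "ACGTACGTTT", "ACGAACGT"
        assert pairwise_identity(a, b)[0] == pairwise_identity(b, a)[0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestNearestIsotype:
    def test_template_wins(self):
        bundle = simulate_trnas(SynthConfig(seed=8, suppressor_trna=True))
        sup = [t for t in bundle.trnas if t.anticodon == "CTA"][0]
        canon = [t for t in bundle.trnas if t.anticodon != "CTA"]
        best, ident = nearest_isotype(sup, canon)
        assert best.isotype == "Leu" and best.anticodon == "CAA"
        assert ident > 95

    def test_single_candidate(self):
        sup, only = _leu_trna("CTA"), _leu_trna("CAA")
        assert nearest_isotype(sup, [only])[0] is only

    def test_order_invariance(self):
        bundle = simulate_trnas(SynthConfig(seed=8, suppressor_trna=True))
        sup = [t for t in bundle.trnas if t.anticodon == "CTA"][0]
        canon = [t for t in bundle.trnas if t.anticodon != "CTA"]
        a = nearest_isotype(sup, canon)
        b = nearest_isotype(sup, canon[::-1])
        assert a[0].trna_id == b[0].trna_id


class TestTelomereCapped:
    def test_capped_both_ends(self):
        seq = "CCCCAAA" * 2 + "G" * 300 + "GGGGTTT" * 2
        assert telomere_capped(seq)

    def test_random_sequence_uncapped(self):
        assert not telomere_capped("ACGT" * 100)

    def test_one_end_only_insufficient(self):
        assert not telomere_capped("CCCCAAA" * 3 + "ACGT" * 100)
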