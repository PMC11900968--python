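"""Consequence-prediction tests: annotation arithmetic, translation, and
frameshift logic, cross-checked against a naive re-translation oracle."""

import numpy as np
import pytest

from bsamap import (
    CdsIndel,
    GeneModel,
    annotate_variant,
    consequence_for_genomic_variant,
    gene_model_from_gff,
    predict_consequence,
    spliced_cds,
    translate,
)
from bsamap.consequence import apply_cds_indel, genomic_to_cds_offset

from conftest import TOY_MODEL, oracle_translate, random_complete_cds, revcomp


class TestAnnotateVariant:
    @pytest.mark.parametrize(
        "pos, region, exon, offset",
        [
            (150, "CDS", 1, 50),
            (101, "CDS", 1, 1),
            (200, "CDS", 1, 100),
            (301, "CDS", 2, 101),
            (250, "intron", None, None),
            (50, "intergenic", None, None),
            (450, "intergenic", None, None),
        ],
    )
    def test_plus_strand_coordinates(self, pos, region, exon, offset):
        ann = annotate_variant(("chrT", pos, "A", "T"), TOY_MODEL)
        assert (ann.region, ann.exon, ann.cds_offset) == (region, exon, offset)

    def test_other_chromosome_is_intergenic(self):
        ann = annotate_variant(("chrX", 150, "A", "T"), TOY_MODEL)
        assert ann.region == "intergenic"

    def test_minus_strand_offsets_count_from_start_codon(self):
        model = GeneModel("g", "chrT", "-", ((101, 200), (301, 400)), ((101, 200), (301, 400)))
        # on the minus strand exon 2 (genomic 301-400) is the first exon
        ann = annotate_variant(("chrT", 400, "A", "T"), model)
        assert (ann.region, ann.exon, ann.cds_offset) == ("CDS", 1, 1)
        ann = annotate_variant(("chrT", 101, "A", "T"), model)
        assert (ann.region, ann.exon, ann.cds_offset) == ("CDS", 2, 200)

    def test_exonic_position_outside_cds_is_utr(self):
        model = GeneModel("g", "chrT", "+", ((101, 200), (301, 400)), ((151, 200), (301, 350)))
        ann = annotate_variant(("chrT", 120, "A", "T"), model)
        assert (ann.region, ann.exon) == ("UTR", 1)
        assert annotate_variant(("chrT", 160, "A", "T"), model).cds_offset == 10


class TestTranslate:
    def test_minimal_orf(self):
        res = translate("ATGTAA")
        assert (res.protein, res.no_stop_found) == ("M", False)

    def test_full_length_cds_obeys_length_law(self, rng):
        # a complete 3258-nt ORF encodes 3258/3 - 1 = 1085 residues
        cds = random_complete_cds(rng, 1086)
        assert len(cds) == 3258
        res = translate(cds)
        assert res.length == 1085 and not res.no_stop_found

    def test_missing_stop_is_flagged(self):
        res = translate("ATGCCC")
        assert res.no_stop_found and res.protein == "MP"

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            translate("ATGNNNTAA")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")

    def test_agrees_with_independent_codon_walk(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 60))
            seq = "".join(rng.choice(list("ACGT"), size=3 * n))
            res = translate(seq)
            protein, no_stop = oracle_translate(seq)
            assert (res.protein, res.no_stop_found) == (protein, no_stop)


class TestPredictConsequence:
    def test_single_base_insertion_causes_premature_stop(self):
        # MKE stop; inserting T after offset 6 shifts the frame onto TGA
        report = predict_consequence("ATGAAAGAATAA", CdsIndel(6, "ins", "T"))
        assert report.effect == "frameshift"
        assert report.frameshift and report.premature_termination
        assert (report.wt_protein_length, report.mut_protein_length) == (3, 2)

    def test_in_frame_codon_deletion_preserves_frame(self):
        report = predict_consequence("ATGAAAGAATAA", CdsIndel(4, "del", "AAA"))
        assert report.effect == "frame-preserved"
        assert not report.frameshift
        assert report.mut_protein_length == report.wt_protein_length - 1

    def test_frameshift_with_no_downstream_stop_is_flagged(self):
        # deleting one base of CCC shifts every downstream codon to CC* sense
        report = predict_consequence("ATGCCCCCCTAA", CdsIndel(4, "del", "C"))
        assert report.effect == "no-stop-found"
        assert report.mut_protein_length is None

    def test_in_frame_stop_gain_detected(self):
        # inserting a whole stop codon at a codon boundary truncates in frame
        report = predict_consequence("ATGAAAGTCTGA", CdsIndel(6, "ins", "TAA"))
        assert report.effect == "stop-gain"
        assert not report.frameshift and report.premature_termination
        assert (report.wt_protein_length, report.mut_protein_length) == (3, 2)

    def test_stop_loss_extends_into_supplied_three_prime(self):
        report = predict_consequence(
            "ATGAAATAA", CdsIndel(7, "del", "TAA"), three_prime_seq="GAAGAATGA"
        )
        assert report.effect == "stop-loss"
        assert report.mut_protein_length == 4  # M K E E

    def test_deleted_bases_must_match_reference(self):
        with pytest.raises(ValueError, match="mismatch"):
            predict_consequence("ATGAAATAA", CdsIndel(4, "del", "CCC"))

    def test_edit_beyond_cds_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            predict_consequence("ATGAAATAA", CdsIndel(8, "del", "AAA"))

    def test_frameshift_depends_only_on_length_mod_three(self, rng):
        cds = random_complete_cds(rng, 40)
        for k in range(1, 7):
            bases = "".join(rng.choice(list("ACGT"), size=k))
            report = predict_consequence(cds, CdsIndel(30, "ins", bases))
            assert report.frameshift == (k % 3 != 0)

    def test_matches_brute_force_retranslation(self, rng):
        """Randomized equivalence: mutant protein length always equals naive
        re-translation of the edited sequence."""
        for _ in range(300):
            n_codons = int(rng.integers(10, 100))
            cds = random_complete_cds(rng, n_codons)
            if rng.random() < 0.5:
                k = int(rng.integers(1, 7))
                start = int(rng.integers(1, len(cds) - k + 1))
                indel = CdsIndel(start, "del", cds[start - 1 : start - 1 + k])
            else:
                bases = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
                indel = CdsIndel(int(rng.integers(0, len(cds))), "ins", bases)
            report = predict_consequence(cds, indel)
            protein, no_stop = oracle_translate(apply_cds_indel(cds, indel))
            if no_stop:
                assert report.mut_protein_length is None
            else:
                assert report.mut_protein_length == len(protein)


class TestGenomicRoute:
    def test_gff_model_round_trip(self, toy_genome):
        model = gene_model_from_gff(toy_genome.gff, "gene_plus")
        assert model.strand == "+" and model.n_exons == 2
        assert spliced_cds(model, toy_genome.fasta) == toy_genome.plus_cds

    def test_minus_strand_cds_extraction(self, toy_genome):
        model = gene_model_from_gff(toy_genome.gff, "gene_minus")
        assert spliced_cds(model, toy_genome.fasta) == toy_genome.minus_cds

    def test_genomic_deletion_matches_direct_cds_route(self, toy_genome):
        model = gene_model_from_gff(toy_genome.gff, "gene_plus")
        # delete the genomic base at 151 = CDS offset 51 (anchor at 150)
        cds = toy_genome.plus_cds
        anchor, deleted = cds[49], cds[50]
        ann, report = consequence_for_genomic_variant(
            ("chrT", 150, anchor + deleted, anchor), model, toy_genome.fasta
        )
        assert (ann.region, ann.cds_offset) == ("CDS", 50)
        direct = predict_consequence(cds, CdsIndel(51, "del", deleted))
        assert report == direct
        assert report.frameshift

    def test_minus_strand_genomic_deletion(self, toy_genome):
        model = gene_model_from_gff(toy_genome.gff, "gene_minus")
        cds = toy_genome.minus_cds
        # genomic 350 on chrM maps into CDS exon 1 (genomic 301-401, '-')
        offset = genomic_to_cds_offset(model, 350)
        g = revcomp(cds)  # genomic orientation
        # delete genomic base 350; anchor base sits at genomic 349
        anchor, deleted = g[349 - 301 + 100], g[350 - 301 + 100]
        ann, report = consequence_for_genomic_variant(
            ("chrM", 349, anchor + deleted, anchor), model, toy_genome.fasta
        )
        assert ann.region == "CDS"
        direct = predict_consequence(cds, CdsIndel(offset, "del", cds[offset - 1]))
        assert report == direct

    def test_intronic_variant_gets_no_report(self, toy_genome):
        model = gene_model_from_gff(toy_genome.gff, "gene_plus")
        ann, report = consequence_for_genomic_variant(
            ("chrT", 250, "AT", "A"), model, toy_genome.fasta
        )
        assert ann.region == "intron" and report is None
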