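"""Domain types, file readers, gene assignment and the consequence caller."""

import textwrap

import pytest

from mitoburden.model import (
    Allele,
    AlleleObservation,
    MT_GENOME_LENGTH,
    ParseError,
    ValidationError,
    call_consequence,
    complement,
    read_variant_table,
    reverse_complement,
    write_variant_table,
)


class TestAlleleInvariants:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValidationError):
            Allele(100, "A", "A")

    def test_position_outside_genome_rejected(self):
        with pytest.raises(ValidationError):
            Allele(MT_GENOME_LENGTH + 1, "A", "G")

    def test_non_base_rejected(self):
        with pytest.raises(ValidationError):
            Allele(100, "N", "G")

    def test_mutant_reads_bounded_by_depth(self):
        with pytest.raises(ValidationError):
            AlleleObservation("S1", Allele(100, "A", "G"), 11, 10)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValidationError):
            AlleleObservation("S1", Allele(100, "A", "G"), 0, 0)

    def test_gene_strand_label(self):
        a = Allele(5814, "T", "C")
        assert a.label == "m.5814T>C"
        assert a.gene_strand_label("L") == "m.5814A>G"


class TestVariantTableIO:
    def test_tsv_row_maps_directly(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("sample,pos,ref,alt,mutant_reads,total_reads\nS1,9957,T,C,9935,10000\n")
        (obs,) = read_variant_table(p)
        assert obs.sample_id == "S1"
        assert obs.allele.key == (9957, "T", "C")
        assert (obs.mutant_reads, obs.total_reads) == (9935, 10000)

    def test_empty_file_yields_empty_collection(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_variant_table(p) == []

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample\tpos\tref\talt\tmutant_reads\ttotal_reads\n"
            "S1\t100\tA\tG\t5\t10\n"
            "S2\t100\tA\tA\t5\t10\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_variant_table(p)

    def test_mutant_exceeding_total_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample\tpos\tref\talt\tmutant_reads\ttotal_reads\nS1\t100\tA\tG\t20\t10\n"
        )
        with pytest.raises(ParseError):
            read_variant_table(p)

    def test_tsv_round_trip_lossless(self, tmp_path, default_cohort):
        dataset, _ = default_cohort
        p = tmp_path / "rt.tsv"
        write_variant_table(dataset.observations, p)
        back = read_variant_table(p)
        orig = [
            (o.sample_id, o.allele.key, o.mutant_reads, o.total_reads)
            for o in dataset.observations
        ]
        redo = [(o.sample_id, o.allele.key, o.mutant_reads, o.total_reads) for o in back]
        assert redo == orig

    def test_vcf_allelic_depth_parsing(self, tmp_path):
        # AD-based depth is the sum of the allelic depths: 65 + 9935 = 10000
        vcf = textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=chrM,length=16569>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
            chrM\t9957\t.\tT\tC\t.\tPASS\t.\tGT:AD\t1:65,9935
            """
        )
        p = tmp_path / "v.vcf"
        p.write_text(vcf)
        (obs,) = read_variant_table(p, dialect="vcf")
        assert obs.allele.key == (9957, "T", "C")
        assert (obs.mutant_reads, obs.total_reads) == (9935, 10000)

    def test_multiallelic_vcf_split_per_alt(self, tmp_path):
        vcf = textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=chrM,length=16569>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
            chrM\t150\t.\tA\tG,C\t.\tPASS\t.\tGT:AD\t1:80,15,5
            """
        )
        p = tmp_path / "v.vcf"
        p.write_text(vcf)
        obs = read_variant_table(p, dialect="vcf")
        assert {(o.allele.alt, o.mutant_reads) for o in obs} == {("G", 15), ("C", 5)}
        assert all(o.total_reads == 100 for o in obs)

    def test_vcf_round_trip_against_tsv(self, tmp_path, default_cohort):
        from mitoburden.synthetic import write_vcf

        dataset, _ = default_cohort
        p = tmp_path / "cohort.vcf"
        write_vcf(dataset, p)
        back = read_variant_table(p, dialect="vcf")
        orig = {
            (o.sample_id, o.allele.key, o.mutant_reads, o.total_reads)
            for o in dataset.observations
        }
        redo = {(o.sample_id, o.allele.key, o.mutant_reads, o.total_reads) for o in back}
        assert redo == orig


class TestGeneAssignment:
    def test_overlap_returns_both_genes(self, gene_map):
        assert gene_map.assign_gene(8530) == ["MT-ATP8", "MT-ATP6"]

    def test_9957_in_co3(self, gene_map):
        assert gene_map.assign_gene(9957) == ["MT-CO3"]

    def test_dloop_is_noncoding(self, gene_map):
        assert gene_map.assign_gene(200) == ["noncoding"]

    def test_every_position_has_a_label(self, gene_map):
        # spot-sample the genome: labels exist everywhere, overlaps only
        # where the annotation declares two genes
        for pos in range(1, MT_GENOME_LENGTH + 1, 97):
            labels = gene_map.assign_gene(pos)
            assert 1 <= len(labels) <= 2

    def test_gene_map_completeness(self, gene_map):
        by_class = {
            cls: len(gene_map.genes_of_class(cls))
            for cls in ("protein", "tRNA", "rRNA")
        }
        assert by_class == {"protein": 13, "tRNA": 22, "rRNA": 2}


class TestConsequenceCaller:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (9438, "G", "A", "G78S"),
            (9490, "C", "T", "A95V"),
            (9755, "G", "C", "E183D"),
            (9856, "T", "C", "I217T"),
            (9957, "T", "C", "F251L"),
        ],
    )
    def test_co3_amino_acid_changes(self, gene_map, reference, pos, ref, alt, expected):
        res = call_consequence(Allele(pos, ref, alt), gene_map["MT-CO3"], reference)
        assert res.effect == "nonsynonymous"
        assert res.amino_acid_change == expected

    def test_wobble_position_synonymous(self, gene_map, reference):
        # find a third-codon-position change in MT-CO1 that preserves the
        # amino acid (fourfold-degenerate codon families exist in table 2)
        region = gene_map["MT-CO1"]
        for codon_number in range(2, 100):
            pos = region.start + 3 * (codon_number - 1) + 2  # third position
            ref = reference[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                res = call_consequence(Allele(pos, ref, alt), region, reference)
                if res.effect == "synonymous":
                    assert res.ref_aa == res.alt_aa
                    return
        pytest.fail("no synonymous wobble change found in 100 codons")

    def test_l_strand_gene_reads_complement(self, gene_map, reference):
        """MT-ND6 codons are read on the light strand, against a manual oracle."""
        from Bio.Seq import Seq

        region = gene_map["MT-ND6"]
        pos = region.end - 3  # first codon position of codon 2 on gene strand
        ref = reference[pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        res = call_consequence(Allele(pos, ref, alt), region, reference)
        gene_seq = str(
            Seq(reference[region.start - 1 : region.end]).reverse_complement()
        )
        codon = gene_seq[3:6]
        assert res.ref_codon == codon
        assert res.codon_number == 2

    def test_incomplete_terminal_codon_rejected(self, gene_map, reference):
        # MT-CO3 spans 784 bp = 261 codons + 1 trailing base
        region = gene_map["MT-CO3"]
        ref = reference[region.end - 1]
        alt = next(b for b in "ACGT" if b != ref)
        with pytest.raises(ValidationError, match="incomplete"):
            call_consequence(Allele(region.end, ref, alt), region, reference)

    def test_reference_mismatch_rejected(self, gene_map, reference):
        region = gene_map["MT-CO3"]
        wrong_ref = next(b for b in "ACGT" if b != reference[9956])
        with pytest.raises(ValidationError, match="reference"):
            call_consequence(Allele(9957, wrong_ref, "C"), region, reference)


def test_complement_involution():
    assert reverse_complement(reverse_complement("ACGTTG")) == "ACGTTG"
    assert complement("A") == "T" and complement("G") == "C"
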