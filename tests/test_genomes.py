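"""Genome container, name normalisation, flat-file round trips."""

import pytest

from mitocomp import (
    AnnotatedGenome,
    GeneFeature,
    extract_feature_sequence,
    read_gene_table,
    read_genbank,
    write_gene_table,
)
from mitocomp.genomes import normalize_gene_name, reverse_complement


@pytest.mark.parametrize("raw,expected", [
    ("COI", "cox1"),
    ("COX3", "cox3"),
    ("ND5", "nad5"),
    ("ND4L", "nad4L"),
    ("CYTB", "cytb"),
    ("s-rRNA", "12S"),
    ("l-rRNA", "16S"),
    ("16S ribosomal RNA", "16S"),
    ("D-loop", "CR"),
    ("tRNA-Trp", "trnW"),
    ("tRNA-Leu(UUR)", "trnL2"),
    ("tRNA-Ser(AGN)", "trnS1"),
    ("trnM", "trnM"),
    ("ATP8", "atp8"),
])
def test_name_normalization(raw, expected):
    assert normalize_gene_name(raw) == expected


class TestFeatureAndGenome:
    def test_feature_validation(self):
        with pytest.raises(ValueError):
            GeneFeature("", "PCG", 1, 10, "H")
        with pytest.raises(ValueError):
            GeneFeature("cox1", "bogus", 1, 10, "H")
        with pytest.raises(ValueError):
            GeneFeature("cox1", "PCG", 0, 10, "H")

    def test_genome_rejects_bad_sequence_and_coords(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            AnnotatedGenome("g", "ACGTX")
        with pytest.raises(ValueError, match="outside genome"):
            AnnotatedGenome("g", "ACGT", True, [GeneFeature("cox1", "PCG", 1, 10, "H")])

    def test_wrap_requires_circular(self):
        with pytest.raises(ValueError, match="linear"):
            AnnotatedGenome("g", "ACGTACGTAC", False,
                            [GeneFeature("cox1", "PCG", 9, 2, "H")])


class TestExtract:
    def test_forward_strand(self):
        g = AnnotatedGenome("g", "ATGC", False)
        assert extract_feature_sequence(g, GeneFeature("x", "tRNA", 1, 3, "H")) == "ATG"

    def test_reverse_strand_is_reverse_complement(self):
        g = AnnotatedGenome("g", "ATGC", False)
        assert extract_feature_sequence(g, GeneFeature("x", "tRNA", 1, 4, "L")) == "GCAT"

    def test_origin_wrap_matches_concatenation_oracle(self):
        seq = "ACGTACGTAG"
        g = AnnotatedGenome("g", seq, True)
        got = extract_feature_sequence(g, GeneFeature("x", "tRNA", 9, 2, "H"))
        # oracle: explicit concatenation of tail + head
        assert got == seq[8:] + seq[:2]
        assert len(got) == 4

    def test_L_strand_is_revcomp_of_H_on_same_span(self, sim_genome):
        for f in sim_genome.features[:6]:
            h = extract_feature_sequence(
                sim_genome, GeneFeature(f.name, f.gclass, f.start, f.end, "H"))
            l = extract_feature_sequence(
                sim_genome, GeneFeature(f.name, f.gclass, f.start, f.end, "L"))
            assert l == reverse_complement(h)


class TestGeneTableIO:
    def test_round_trip_preserves_everything(self, tmp_gene_table, ewen_genome):
        fa, tsv = tmp_gene_table
        back = read_gene_table(fa, tsv)
        assert back.sequence == ewen_genome.sequence
        assert [(f.name, f.start, f.end, f.strand) for f in back.features] == \
               [(f.name, f.start, f.end, f.strand) for f in ewen_genome.features]

    def test_typed_in_organisation_table_has_38_features(self, ewen_genome):
        assert len(ewen_genome.features) == 38  # 37 genes + control region
        assert len(ewen_genome.pcgs) == 13
        assert len(ewen_genome.features_of_class("tRNA")) == 22
        assert len(ewen_genome.features_of_class("rRNA")) == 2

    def test_coordinates_outside_sequence_rejected(self, tmp_path):
        (tmp_path / "s.fasta").write_text(">s\nACGTACGT\n")
        (tmp_path / "t.tsv").write_text("gene\tclass\tstart\tend\tstrand\ncox1\tPCG\t1\t99\tH\n")
        with pytest.raises(ValueError, match="outside sequence"):
            read_gene_table(tmp_path / "s.fasta", tmp_path / "t.tsv")

    def test_duplicate_names_rejected(self, tmp_path):
        (tmp_path / "s.fasta").write_text(">s\nACGTACGTACGT\n")
        (tmp_path / "t.tsv").write_text(
            "gene\tclass\tstart\tend\tstrand\n"
            "cox1\tPCG\t1\t6\tH\ncox1\tPCG\t7\t12\tH\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_table(tmp_path / "s.fasta", tmp_path / "t.tsv")

    def test_wrap_on_linear_rejected(self, tmp_path):
        (tmp_path / "s.fasta").write_text(">s\nACGTACGTACGT\n")
        (tmp_path / "t.tsv").write_text("gene\tclass\tstart\tend\tstrand\ncox1\tPCG\t10\t2\tH\n")
        with pytest.raises(ValueError, match="linear"):
            read_gene_table(tmp_path / "s.fasta", tmp_path / "t.tsv", circular=False)


GENBANK_FIXTURE = """\
LOCUS       TESTMITO                 120 bp    DNA     circular INV 01-JAN-2021
DEFINITION  synthetic test mitogenome fragment.
ACCESSION   TESTMITO
FEATURES             Location/Qualifiers
     source          1..120
                     /organism="Testus testus"
     CDS             1..30
                     /gene="COI"
     tRNA            31..50
                     /product="tRNA-Trp"
     CDS             complement(51..80)
                     /gene="ND5"
     rRNA            81..100
                     /product="s-rRNA"
     D-loop          101..120
ORIGIN
        1 atgaaaccca tgaaacccat gaaaccctaa gggtttggga tttcccggga aatttcccgg
       61 gaaatttccc gggaaatttt atatatatat atatatatat gcgcgcgcgc aaaaattttt
//
"""


class TestGenBank:
    def test_fixture_parses_with_normalized_names(self, tmp_path):
        p = tmp_path / "t.gb"
        p.write_text(GENBANK_FIXTURE)
        g = read_genbank(p)
        names = [f.name for f in g.features]
        assert names == ["cox1", "trnW", "nad5", "12S", "CR"]
        assert len(g) == 120 and g.circular

    def test_complement_cds_gets_L_strand(self, tmp_path):
        p = tmp_path / "t.gb"
        p.write_text(GENBANK_FIXTURE)
        g = read_genbank(p)
        by_name = {f.name: f for f in g.features}
        assert by_name["nad5"].strand == "L"
        assert by_name["cox1"].strand == "H"

    def test_non_iupac_origin_rejected(self, tmp_path):
        p = tmp_path / "bad.gb"
        p.write_text(GENBANK_FIXTURE.replace("atgaaaccca", "atgaaQccca"))
        with pytest.raises(ValueError):
            read_genbank(p)

    def test_zero_features_rejected(self, tmp_path):
        text = GENBANK_FIXTURE
        head, origin = text.split("ORIGIN")
        head = head.split("FEATURES")[0]
        p = tmp_path / "empty.gb"
        p.write_text(head + "FEATURES             Location/Qualifiers\n"
                     "     source          1..120\n"
                     "                     /organism=\"Testus testus\"\nORIGIN" + origin)
        with pytest.raises(ValueError, match="no gene features"):
            read_genbank(p)
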