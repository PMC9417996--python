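"""Gene/transcript model: parsing, coordinate maps, UTR derivation and
region labelling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ripcall as rc
from ripcall.annotation import AnnotationParseError, GenomeIndex

from conftest import make_gene

GTF_ONE_GENE = """\
chr1\tsrc\tgene\t100\t400\t.\t+\t.\tgene_id "G1"; gene_name "ALPHA"; gene_biotype "protein_coding";
chr1\tsrc\ttranscript\t100\t400\t.\t+\t.\tgene_id "G1"; transcript_id "G1T1";
chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "G1T1";
chr1\tsrc\texon\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "G1T1";
chr1\tsrc\tCDS\t151\t180\t.\t+\t0\tgene_id "G1"; transcript_id "G1T1";
"""


@pytest.fixture
def one_gene_gtf(tmp_path):
    p = tmp_path / "one.gtf"
    p.write_text(GTF_ONE_GENE)
    return str(p)


class TestLoadAnnotation:
    def test_coordinate_conversion(self, one_gene_gtf):
        """1-based closed GTF exons [100,200],[300,400] become 0-based
        half-open [99,200),[299,400); gene span covers both."""
        (gene,) = rc.load_annotation(one_gene_gtf)
        assert gene.gene_id == "G1"
        assert gene.biotype == "protein_coding"
        tx = gene.representative_transcript()
        assert tx.exons == [(99, 200), (299, 400)]
        assert gene.span == (99, 400)

    def test_utr_derivation_plus_strand(self, one_gene_gtf):
        """CDS [150,180) inside exon [99,200) on + strand: 5'UTR is the
        low-coordinate exonic side, 3'UTR the rest."""
        (gene,) = rc.load_annotation(one_gene_gtf)
        tx = gene.representative_transcript()
        assert tx.cds == [(150, 180)]
        assert tx.utr5 == [(99, 150)]
        assert tx.utr3 == [(180, 200), (299, 400)]

    def test_utr_sides_swap_on_minus_strand(self, tmp_path):
        p = tmp_path / "minus.gtf"
        p.write_text(GTF_ONE_GENE.replace("\t+\t", "\t-\t"))
        (gene,) = rc.load_annotation(str(p))
        tx = gene.representative_transcript()
        assert tx.utr5 == [(180, 200), (299, 400)]  # 5'UTR on the high-coordinate side
        assert tx.utr3 == [(99, 150)]

    def test_missing_biotype_becomes_unknown(self, tmp_path, caplog):
        p = tmp_path / "nobio.gtf"
        p.write_text(GTF_ONE_GENE.replace(' gene_biotype "protein_coding";', ""))
        (gene,) = rc.load_annotation(str(p))
        assert gene.biotype == "unknown"

    def test_malformed_line_reported_with_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(GTF_ONE_GENE + "chr1\tonly\tthree\n")
        with pytest.raises(AnnotationParseError, match="line 6"):
            rc.load_annotation(str(p))


class TestCoordinateMaps:
    def test_plus_strand_cumulative_offset(self):
        g = make_gene("G", "+", exons=[(0, 10), (20, 30)])
        tx = g.representative_transcript()
        assert tx.genome_to_transcript(22) == 12
        assert tx.locate(15) == ("intronic", None)
        assert tx.locate(500) == ("outside", None)

    def test_minus_strand_matches_bruteforce_enumeration(self):
        """Transcript order on '-' is the reversed list of exonic bases."""
        exons = [(0, 10), (20, 30)]
        g = make_gene("G", "-", exons=exons)
        tx = g.representative_transcript()
        bases_plus = [p for s, e in exons for p in range(s, e)]
        order = bases_plus[::-1]
        assert tx.genome_to_transcript(22) == order.index(22) == 7
        for t, pos in enumerate(order):
            assert tx.genome_to_transcript(pos) == t
            assert tx.transcript_to_genome(t) == pos

    @given(
        data=st.data(),
        strand=st.sampled_from("+-"),
        n_exons=st.integers(1, 5),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_roundtrip_property(self, data, strand, n_exons):
        """genome->transcript->genome is the identity on every exonic base."""
        pos = 0
        exons = []
        for _ in range(n_exons):
            pos += data.draw(st.integers(0, 20))
            ln = data.draw(st.integers(1, 30))
            exons.append((pos, pos + ln))
            pos += ln + 1  # keep exons disjoint, allow 1bp introns
        g = make_gene("G", strand, exons=exons)
        tx = g.representative_transcript()
        for s, e in exons:
            for p in range(s, e):
                t = tx.genome_to_transcript(p)
                assert t is not None
                assert tx.transcript_to_genome(t) == p

    def test_utr_cds_lengths_partition_exonic_length(self, coding_gene):
        tx = coding_gene.representative_transcript()
        u5, cds, u3 = tx.utr_lengths
        assert u5 + cds + u3 == tx.exonic_length


class TestLabelPosition:
    def test_precedence_and_partition(self):
        # gene A coding; gene B overlapping with A's CDS via its intron
        a = make_gene("A", "+", exons=[(0, 100)], cds=[(40, 60)])
        b = make_gene("B", "+", exons=[(30, 40), (90, 120)])  # intron [40,90)
        b.biotype = "lincRNA"
        idx = GenomeIndex([a, b])
        assert idx.label_position("chrT", 50, "+") == "CDS"      # CDS beats B's intron
        assert idx.label_position("chrT", 35, "+") == "5UTR"     # A's 5UTR beats B's noncoding exon
        assert idx.label_position("chrT", 110, "+") == "noncoding_exon"
        assert idx.label_position("chrT", 500, "+") == "intergenic"
        assert idx.label_position("chrT", 50, "-") == "intergenic"  # strand-aware

    def test_every_base_gets_exactly_one_label(self):
        a = make_gene("A", "+", exons=[(10, 50), (80, 120)], cds=[(20, 50), (80, 100)])
        idx = GenomeIndex([a])
        labels = [idx.label_position("chrT", p, "+") for p in range(0, 130)]
        assert all(isinstance(l, str) for l in labels)
        seen = set(labels)
        assert seen == {"intergenic", "5UTR", "CDS", "3UTR", "intron"}

    def test_noncoding_gene_exon_label(self):
        linc = make_gene("L", "+", exons=[(0, 100)], biotype="lincRNA")
        idx = GenomeIndex([linc])
        assert idx.label_position("chrT", 10, "+") == "noncoding_exon"


def test_precedence_5utr_vs_noncoding_exon():
    """The default precedence ranks a coding gene's UTR above another gene's
    noncoding exon."""
    a = make_gene("A", "+", exons=[(0, 100)], cds=[(40, 60)])
    linc = make_gene("L", "+", exons=[(0, 100)], biotype="lincRNA")
    idx = GenomeIndex([a, linc])
    assert idx.label_position("chrT", 35, "+") == "5UTR"
    assert idx.label_position("chrT", 70, "+") == "3UTR"
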