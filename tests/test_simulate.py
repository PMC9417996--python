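"""Synthetic data generator: annotation round-trip, read placement,
accounting, motif planting and seed determinism."""

import numpy as np
import pytest

import ripcall as rc
from ripcall.simulate import (
    plant_motifs,
    simulate_genes,
    simulate_genome_sequence,
    site_sequences,
    write_gtf,
    write_reads_bed,
)


def small_cfg(**kw):
    base = dict(n_genes=12, n_target_genes=3, seed=9)
    base.update(kw)
    return rc.SimConfig(**base)


class TestAnnotationSimulation:
    def test_all_protein_coding_genes_have_cds_and_utrs(self):
        cfg = small_cfg(biotype_mix={"protein_coding": 1.0}, n_genes=10)
        genes = simulate_genes(cfg)
        assert len(genes) == 10
        for g in genes:
            tx = g.representative_transcript()
            u5, cds, u3 = tx.utr_lengths
            assert u5 > 0 and cds > 0 and u3 > 0
            assert cds % 3 == 0

    def test_gtf_roundtrip_reproduces_model(self, tmp_path):
        cfg = small_cfg()
        genes = simulate_genes(cfg)
        path = str(tmp_path / "sim.gtf")
        write_gtf(genes, path)
        loaded = rc.load_annotation(path)
        assert len(loaded) == len(genes)
        by_id = {g.gene_id: g for g in loaded}
        for g in genes:
            l = by_id[g.gene_id]
            assert l.span == g.span
            assert l.biotype == g.biotype
            ltx, gtx = l.representative_transcript(), g.representative_transcript()
            assert ltx.exons == gtx.exons
            assert ltx.cds == gtx.cds

    def test_biotype_mix_within_multinomial_tolerance(self):
        cfg = rc.SimConfig(n_genes=100, n_target_genes=0,
                           biotype_mix={"protein_coding": 0.8, "lincRNA": 0.2}, seed=4)
        genes = simulate_genes(cfg)
        n_pc = sum(g.biotype == "protein_coding" for g in genes)
        # binomial(100, 0.8): 4 sigma band around 80
        assert abs(n_pc - 80) <= 16

    def test_infeasible_packing_raises_with_suggestion(self):
        with pytest.raises(ValueError, match="chrom_length"):
            simulate_genes(small_cfg(chrom_length=1000))

    def test_genes_do_not_overlap(self):
        genes = simulate_genes(small_cfg(n_genes=30))
        spans = sorted(g.span for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestSiteAndReadSimulation:
    def test_sites_lie_in_cds_exons_and_targets_flagged(self):
        sim = rc.simulate_dataset(small_cfg())
        by_id = {g.gene_id: g for g in sim.genes}
        for row in sim.sites.itertuples():
            tx = by_id[row.gene_id].representative_transcript()
            assert any(s <= row.start and row.end <= e for s, e in tx.cds)
            assert row.region == "CDS"
        truth = sim.gene_table.set_index("gene_id")
        assert set(sim.sites.gene_id) == set(truth.index[truth.n_sites > 0])
        assert sim.true_targets == set(sim.sites[~sim.sites.present_in_input].gene_id)

    def test_fixed_read_length_is_honoured(self):
        sim = rc.simulate_dataset(small_cfg(read_length=150))
        assert all(r.length == 150 for r in sim.ip_reads)
        assert all(r.length == 150 for r in sim.input_reads)

    def test_read_accounting_is_exact(self):
        sim = rc.simulate_dataset(small_cfg())
        t = sim.gene_table
        assert len(sim.ip_reads) == int((t.n_background_ip + t.n_site_ip).sum())
        assert len(sim.input_reads) == int((t.n_background_input + t.n_site_input).sum())
        assert int(t.n_site_ip.sum()) == int(sim.sites.n_ip_reads.sum())

    def test_reads_lie_within_single_exons(self):
        sim = rc.simulate_dataset(small_cfg(n_genes=8))
        exons = [(g.chrom, g.strand, s, e) for g in sim.genes for s, e in g.merged_exons()]
        for r in sim.ip_reads[:500]:
            assert any(c == r.chrom and st == r.strand and s <= r.start and r.end <= e
                       for c, st, s, e in exons)

    def test_zero_depth_zero_sites_yield_empty_libraries(self):
        cfg = small_cfg(background_depth=0.0, input_depth=0.0, n_target_genes=0)
        sim = rc.simulate_dataset(cfg)
        assert sim.ip_reads == [] and sim.input_reads == []

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        a, b = (rc.simulate_dataset(small_cfg()) for _ in range(2))
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_reads_bed(a.ip_reads, str(pa))
        write_reads_bed(b.ip_reads, str(pb))
        assert pa.read_bytes() == pb.read_bytes()
        assert a.sites.equals(b.sites)
        ga, gb = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(a.genes, str(ga))
        write_gtf(b.genes, str(gb))
        assert ga.read_bytes() == gb.read_bytes()

    def test_different_seeds_differ(self):
        a = rc.simulate_dataset(small_cfg(seed=1))
        b = rc.simulate_dataset(small_cfg(seed=2))
        assert [r.start for r in a.ip_reads[:50]] != [r.start for r in b.ip_reads[:50]]


class TestMotifPlanting:
    def test_motif_written_at_site_center(self):
        seqs = {"c": "A" * 100}
        out = plant_motifs(seqs, [("c", 40, 60, "+")], "GGAC")
        assert out["c"][48:52] == "GGAC"
        assert out["c"].count("G") == 2

    def test_minus_strand_plants_reverse_complement(self):
        seqs = {"c": "A" * 100}
        out = plant_motifs(seqs, [("c", 40, 60, "-")], "GGAC")
        assert out["c"][48:52] == "GTCC"  # revcomp(GGAC)

    def test_no_sites_leaves_sequences_unchanged(self):
        seqs = {"c": "ACGTACGT"}
        assert plant_motifs(seqs, [], "GGAC") == seqs

    def test_overlapping_plants_warn_and_later_wins(self, caplog):
        seqs = {"c": "A" * 30}
        with caplog.at_level("WARNING"):
            out = plant_motifs(seqs, [("c", 8, 12, "+"), ("c", 10, 14, "+")], "GGGG")
        assert "overlap" in caplog.text.lower()
        assert out["c"][10:14] == "GGGG"

    def test_planted_foreground_exceeds_background_frequency(self):
        cfg = small_cfg(n_genes=60, n_target_genes=20, seed=13)
        genes = simulate_genes(cfg)
        sites = rc.plan_sites(genes, cfg)
        seqs = simulate_genome_sequence(genes, cfg, sites, motif="GGAC")
        fg = site_sequences(seqs, sites)
        fg_freq = sum(s.count("GGAC") for s in fg) / sum(len(s) - 3 for s in fg)
        assert fg_freq > 5 * (1 / 256)  # planted + random vs random expectation
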