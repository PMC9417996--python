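"""Shared fixtures: hand-built toy gene models and session-scoped synthetic
pipeline runs reused across test modules (the heavy permutation runs are
computed once)."""

from __future__ import annotations

import pytest

import ripcall as rc


def make_gene(
    gene_id: str = "GX",
    strand: str = "+",
    exons=((0, 100), (200, 300)),
    cds=None,
    biotype: str = "protein_coding",
    chrom: str = "chrT",
) -> rc.Gene:
    tx = rc.Transcript(f"{gene_id}T1", chrom, strand, list(exons), list(cds) if cds else None)
    return rc.Gene(gene_id=gene_id, gene_name=gene_id, biotype=biotype,
                   chrom=chrom, strand=strand, transcripts={tx.transcript_id: tx})


@pytest.fixture
def coding_gene() -> rc.Gene:
    # exon1 [99,200), exon2 [299,400); CDS [150,180) in exon1 (+ strand)
    return make_gene("GC", "+", exons=[(99, 200), (299, 400)], cds=[(150, 180)])


@pytest.fixture(scope="session")
def recovery_run():
    """Planted-site run at the study conditions: 8x footprint enrichment,
    50 bp footprints, 20 target genes among 200, 500 permutations."""
    cfg = rc.SimConfig(n_genes=200, n_target_genes=20, seed=5)
    sim = rc.simulate_dataset(cfg)
    result = rc.run_rip_pipeline(sim.ip_reads, sim.input_reads, sim.genes,
                                 n_sims=500, seed=5)
    return sim, result


@pytest.fixture(scope="session")
def calibration_run():
    """No-signal run (background only, IP and input exchangeable)."""
    cfg = rc.SimConfig(n_genes=200, n_target_genes=0, seed=11)
    sim = rc.simulate_dataset(cfg)
    result = rc.run_rip_pipeline(sim.ip_reads, sim.input_reads, sim.genes,
                                 n_sims=500, seed=11)
    return sim, result
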