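#!/usr/bin/env python
"""Simulate the study dataset: a synthetic transcriptome and two replicate
IP/input library pairs with planted IGF2BP2-style binding footprints.

200 genes (80% protein_coding), 20 target genes with one 50 bp footprint
each planted in CDS, 8x footprint enrichment over a uniform exonic
background of 0.2 reads/base, 150 bp reads.  Both replicates share the
annotation and footprint plan but draw independent libraries.  A genome
FASTA carries the GGAC consensus written at each footprint center.

Writes results/data/{annotation.gtf, genome.fa, truth_*.tsv} and
results/data/rep{1,2}/{ip,input}.bed.
"""

import dataclasses
import os

import ripcall as rc
from ripcall.simulate import simulate_genome_sequence, write_fasta, write_gtf, write_reads_bed

SEED = 42
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")


def main() -> None:
    cfg = rc.SimConfig(n_genes=200, n_target_genes=20, seed=SEED)
    genes = rc.simulate_genes(cfg)
    sites = rc.plan_sites(genes, cfg)
    os.makedirs(OUT, exist_ok=True)
    write_gtf(genes, os.path.join(OUT, "annotation.gtf"))
    sites.to_csv(os.path.join(OUT, "truth_sites.tsv"), sep="\t", index=False)

    for rep in (1, 2):
        rep_cfg = dataclasses.replace(cfg, seed=SEED + rep)
        sim = rc.simulate_reads(genes, sites, rep_cfg)
        d = os.path.join(OUT, f"rep{rep}")
        os.makedirs(d, exist_ok=True)
        write_reads_bed(sim.ip_reads, os.path.join(d, "ip.bed"))
        write_reads_bed(sim.input_reads, os.path.join(d, "input.bed"))
        sim.gene_table.to_csv(os.path.join(d, "truth_genes.tsv"), sep="\t", index=False)
        print(f"replicate {rep}: {len(sim.ip_reads)} IP reads, "
              f"{len(sim.input_reads)} input reads, {len(sim.true_targets)} true targets")

    seqs = simulate_genome_sequence(genes, cfg, sites, motif="GGAC")
    write_fasta(seqs, os.path.join(OUT, "genome.fa"))
    print(f"annotation: {len(genes)} genes, {len(sites)} planted footprints -> {OUT}")


if __name__ == "__main__":
    main()
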