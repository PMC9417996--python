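# ripcall

Peak discovery for RIP-seq / iRIP-seq experiments: find where an
RNA-binding protein (for example an m⁶A reader such as IGF2BP2) sits on
the transcriptome, given an immunoprecipitated (IP) read library and a
matched input control, and characterise the recovered targets.

The package is aimed at analysts of protein–RNA interaction sequencing
data who want the classic permutation-null peak-calling recipe as an
inspectable, deterministic, tested library rather than a black box — and
at anyone who needs a ground-truth simulator to benchmark such a caller.

## The method

For each gene, reads with ≥1 bp mutual overlap are clustered into
candidate peaks; a peak's height *h* is its maximum per-base coverage.
Significance comes from a per-gene permutation null: each of *N* = 500
permutations re-places the same number of reads with the same length
multiset uniformly over the gene's exonic space and records the maximum
peak height *M₁, …, M_N*. The empirical p-value of a peak is

    p = #{ i : M_i ≥ h } / N

and, by default, a peak is selected when *h* > max(M₁, …, M_N) — the
observed pile-up is taller than anything 500 random re-placements of the
same reads produced (`select_rule="empirical_p"`, p < α, is also
available). IP and input are analysed independently; selected IP peaks
overlapping a selected input peak are discarded, and the genes owning the
retained peaks are the protein's target genes.

Around the caller: biotype read ranking, metagene profiles over a
normalised 5′UTR|CDS|3′UTR axis, peak region distributions, multi-list
target intersection, and k-mer (e.g. GGAC) enrichment under peaks. A
synthetic-data module generates annotation, IP/input libraries and genome
sequence with planted binding footprints, so every stage is testable with
a known answer key. See `docs/methods.md` for the full model description.

## Worked example

```python
import ripcall as rc

# synthetic experiment: 200 genes, 20 of them carrying one 50 bp
# footprint with 8x read enrichment over a 0.2 reads/base background
cfg = rc.SimConfig(n_genes=200, n_target_genes=20, seed=5)
sim = rc.simulate_dataset(cfg)
res = rc.run_rip_pipeline(sim.ip_reads, sim.input_reads, sim.genes,
                          n_sims=500, seed=5)

true, called = sim.true_targets, res.targets
tp = len(true & called)
print(f"{len(res.retained)} retained peaks in {len(called)} target genes")
print(f"recall {tp/len(true):.2f}  precision {tp/len(called):.2f}")
```

prints

```
21 retained peaks in 21 target genes
recall 1.00  precision 0.95
```

— all 20 planted targets are recovered (one unbound gene sneaks in at
this seed). Profiling the retained peaks:

```python
idx = rc.GenomeIndex(sim.genes)
print(rc.metagene(res.retained, idx).region_fractions())
print(rc.region_distribution(res.retained, idx).modal_label())
```

```
{'5UTR': 0.1, 'CDS': 0.9, '3UTR': 0.0}
CDS
```

90% of peak mass sits in CDS bins, where the footprints were planted.

The same steps are available from the shell
(`ripcall simulate | call | profile | intersect | kmer`), and
`analysis/01…05` run the full narrative — simulate two replicate library
pairs, call peaks, profile binding, intersect the replicate target sets
with two expression-derived gene lists, and rank k-mers under the peaks
(GGAC comes out first, Bonferroni-significant) — writing tables under
`results/`.

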