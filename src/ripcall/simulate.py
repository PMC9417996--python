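"""Synthetic RIP-seq data generator with planted ground truth.

Generates everything the pipeline consumes, with a known answer key: a
transcript annotation (genes with biotypes, exon/CDS/UTR structure on a
synthetic chromosome), protein-binding footprints planted in the CDS of
chosen target genes, an IP read library whose coverage at footprints is a
configurable multiple of the uniform exonic background, a matched input
library without footprint enrichment (optionally sharing "confounder"
footprints with the IP), and optionally a genome sequence with a consensus
motif written at each footprint.

The generative model:

* background reads start uniformly over the transcript (mature-mRNA) space
  of each gene, at ``background_depth`` expected reads per exonic base
  (Poisson count per gene); emitted reads are unspliced, i.e. each read is
  one contiguous genomic interval within a single exon, exactly the
  placement model the peak caller's permutation null uses;
* each planted footprint of width ``w`` receives an extra Poisson number of
  IP reads with mean ``(enrichment - 1) * background_depth * w``, centred on
  the footprint with uniform jitter of +/- half a read length, so footprint
  read density is ``enrichment`` times background;
* footprints flagged ``present_in_input`` receive the same boost in the
  input library, emulating non-specific signal that input subtraction must
  remove; a gene is a true target iff it owns at least one IP-specific
  footprint.

All randomness flows from ``SimConfig.seed`` through per-gene child streams,
so outputs are byte-identical across runs and independent of iteration
order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, Transcript
from .peaks import place_reads_contiguous
from .reads import AlignedRead, reads_to_bed_frame
from .targets import reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic RIP experiment."""

    n_genes: int = 200
    #: gene biotype mix (fractions must sum to 1)
    biotype_mix: dict[str, float] = field(
        default_factory=lambda: {"protein_coding": 0.8, "lincRNA": 0.15, "misc_RNA": 0.05}
    )
    tx_length_range: tuple[int, int] = (1800, 3000)
    n_exons_range: tuple[int, int] = (2, 4)
    min_exon_length: int = 260
    intron_length_range: tuple[int, int] = (200, 800)
    intergenic_gap_range: tuple[int, int] = (1000, 3000)
    #: 5'UTR and 3'UTR fractions of a coding transcript (CDS gets the rest)
    utr5_frac: float = 0.15
    utr3_frac: float = 0.25
    #: footprint planting
    n_target_genes: int = 20
    n_sites_per_gene: int = 1
    footprint_width: int = 50
    enrichment: float = 8.0
    #: fraction of planted footprints also boosted in the input library
    frac_sites_in_input: float = 0.0
    #: library depths, expected reads per exonic base
    background_depth: float = 0.2
    input_depth: float = 0.2
    #: read length: a fixed int, or {length: probability}
    read_length: int | dict[int, float] = 150
    chrom_name: str = "chrS1"
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.biotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype_mix fractions must sum to 1 (got {total})")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.background_depth < 0 or self.input_depth < 0:
            raise ValueError("depths must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if isinstance(d["read_length"], dict):
            d["read_length"] = {str(k): v for k, v in d["read_length"].items()}
        return json.dumps(d, indent=2, sort_keys=True)


def _rng(cfg_seed: int, *streams) -> np.random.Generator:
    entropy = [int(cfg_seed)]
    for s in streams:
        entropy.append(zlib.crc32(s.encode()) if isinstance(s, str) else int(s))
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# annotation


def _t_interval_to_segments(exons: list[tuple[int, int]], strand: str,
                            a: int, b: int) -> list[tuple[int, int]]:
    """Genomic segments covered by transcript-space interval [a, b)."""
    total = sum(e - s for s, e in exons)
    if strand == "+":
        ua, ub = a, b
    else:
        ua, ub = total - b, total - a
    segs = []
    cum = 0
    for s, e in exons:
        lo = max(ua, cum)
        hi = min(ub, cum + (e - s))
        if lo < hi:
            segs.append((s + lo - cum, s + hi - cum))
        cum += e - s
    return segs


def simulate_genes(cfg: SimConfig) -> list[Gene]:
    """Lay out ``n_genes`` non-overlapping genes along a synthetic chromosome.

    Each gene carries one transcript; protein_coding genes get a CDS flanked
    by UTRs at the configured fractions, other biotypes are noncoding.
    """
    genes: list[Gene] = []
    cursor = cfg.intergenic_gap_range[0]
    biotypes = sorted(cfg.biotype_mix)
    probs = np.array([cfg.biotype_mix[b] for b in biotypes])
    layout_rng = _rng(cfg.seed, "layout")
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        rng = _rng(cfg.seed, gid, "structure")
        biotype = str(rng.choice(biotypes, p=probs))
        strand = str(rng.choice(["+", "-"]))
        n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        L = int(rng.integers(cfg.tx_length_range[0], cfg.tx_length_range[1] + 1))
        if n_exons * cfg.min_exon_length > L:
            raise ValueError(
                f"{gid}: cannot fit {n_exons} exons of >= {cfg.min_exon_length} bp into a "
                f"{L} bp transcript; lower min_exon_length or n_exons_range"
            )
        # broad exon-size spectrum (Dirichlet proportions): splice junctions
        # land at irregular transcript positions, as in real gene models
        spare = L - n_exons * cfg.min_exon_length
        props = rng.dirichlet(np.ones(n_exons))
        extra = np.floor(props * spare).astype(np.int64)
        extra[0] += spare - int(extra.sum())
        exon_lens = cfg.min_exon_length + extra
        intron_lens = rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1,
                                   size=n_exons - 1)
        exons = []
        pos = cursor
        for j, xl in enumerate(exon_lens):
            exons.append((pos, pos + int(xl)))
            pos += int(xl)
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cds = None
        if biotype == "protein_coding":
            u5 = int(round(cfg.utr5_frac * L))
            u3 = int(round(cfg.utr3_frac * L))
            cds_len = L - u5 - u3 - (L - u5 - u3) % 3  # keep a whole number of codons
            cds = _t_interval_to_segments(exons, strand, u5, u5 + cds_len)
        tx = Transcript(f"{gid}T1", cfg.chrom_name, strand, exons, cds)
        genes.append(Gene(gene_id=gid, gene_name=f"SYN{gid}", biotype=biotype,
                          chrom=cfg.chrom_name, strand=strand,
                          transcripts={tx.transcript_id: tx}))
        cursor = pos + int(layout_rng.integers(cfg.intergenic_gap_range[0],
                                               cfg.intergenic_gap_range[1] + 1))
    if cfg.chrom_length is not None and cursor > cfg.chrom_length:
        raise ValueError(
            f"genes need {cursor} bp but chrom_length is {cfg.chrom_length}; "
            f"raise chrom_length to >= {cursor} or reduce n_genes/transcript lengths"
        )
    return genes


def chromosome_length(genes: list[Gene], cfg: SimConfig) -> int:
    if cfg.chrom_length is not None:
        return cfg.chrom_length
    return max(g.span[1] for g in genes) + cfg.intergenic_gap_range[0]


_GTF_ATTR = '{key} "{value}";'


def write_gtf(genes: list[Gene], path: str, source: str = "ripcall_sim") -> None:
    """Write the gene models as GTF (1-based closed coordinates)."""

    def attrs(**kv) -> str:
        return " ".join(_GTF_ATTR.format(key=k, value=v) for k, v in kv.items())

    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            s, e = g.span
            base = dict(gene_id=g.gene_id, gene_name=g.gene_name, gene_biotype=g.biotype)
            fh.write(f"{g.chrom}\t{source}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs(**base)}\n")
            for t in sorted(g.transcripts.values(), key=lambda t: t.transcript_id):
                ta = dict(base, transcript_id=t.transcript_id)
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{t.exons[0][0] + 1}\t{t.exons[-1][1]}\t.\t"
                    f"{g.strand}\t.\t{attrs(**ta)}\n"
                )
                for xs, xe in t.exons:
                    fh.write(f"{g.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{attrs(**ta)}\n")
                cds_order = t.cds if g.strand == "+" else list(reversed(t.cds))
                cum = 0
                for cs, ce in cds_order:
                    frame = (3 - cum % 3) % 3
                    fh.write(f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{frame}\t{attrs(**ta)}\n")
                    cum += ce - cs


# ---------------------------------------------------------------------------
# footprint planting


def plan_sites(genes: list[Gene], cfg: SimConfig) -> pd.DataFrame:
    """Choose target genes and plant footprint intervals in their CDS.

    Each footprint lies entirely within the CDS portion of a single exon, so
    its genomic interval is contiguous and its midpoint labels as CDS.
    """
    rng = _rng(cfg.seed, "sites")
    coding = [g for g in genes if g.biotype == "protein_coding" and g.is_coding]
    if cfg.n_target_genes > len(coding):
        raise ValueError(f"n_target_genes={cfg.n_target_genes} but only {len(coding)} coding genes")
    ids = sorted(g.gene_id for g in coding)
    chosen = sorted(rng.choice(ids, size=cfg.n_target_genes, replace=False))
    by_id = {g.gene_id: g for g in genes}
    w = cfg.footprint_width
    rows = []
    for gid in chosen:
        gene = by_id[gid]
        grng = _rng(cfg.seed, gid, "plant")
        tx = gene.representative_transcript()
        segs = [(s, e) for s, e in tx.cds if e - s >= w + 10]
        if not segs:
            raise ValueError(f"{gid}: no CDS exon long enough for a {w} bp footprint")
        taken: list[tuple[int, int]] = []
        for j in range(cfg.n_sites_per_gene):
            for _ in range(50):
                s, e = segs[int(grng.integers(len(segs)))]
                center = int(grng.integers(s + w // 2, e - w // 2))
                start, end = center - w // 2, center - w // 2 + w
                if all(end <= ts or start >= te for ts, te in taken):
                    taken.append((start, end))
                    break
            else:
                raise ValueError(f"{gid}: could not place {cfg.n_sites_per_gene} non-overlapping sites")
            rows.append(
                {
                    "site_id": f"{gid}_s{j + 1}",
                    "gene_id": gid,
                    "chrom": gene.chrom,
                    "start": taken[-1][0],
                    "end": taken[-1][1],
                    "strand": gene.strand,
                    "region": "CDS",
                    "enrichment": cfg.enrichment,
                    "present_in_input": bool(grng.random() < cfg.frac_sites_in_input),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "gene_id", "chrom", "start", "end", "strand",
                 "region", "enrichment", "present_in_input"],
    )


# ---------------------------------------------------------------------------
# reads


def _draw_lengths(rng: np.random.Generator, n: int, read_length) -> np.ndarray:
    if isinstance(read_length, dict):
        lens = np.array(sorted(read_length), dtype=np.int64)
        probs = np.array([read_length[int(l)] for l in lens], dtype=float)
        return rng.choice(lens, size=n, p=probs / probs.sum())
    return np.full(n, int(read_length), dtype=np.int64)


def _place_uniform(tx: Transcript, rng: np.random.Generator, n: int, read_length):
    """Background reads: uniform over contiguous start slots of the exonic
    space (emitted reads are unspliced, so each lies within one exon)."""
    lens = _draw_lengths(rng, n, read_length)
    return place_reads_contiguous(tx, rng, lens)


def _place_at_site(tx: Transcript, rng: np.random.Generator, n: int, read_length,
                   site_center: int):
    """Footprint reads: centred on the site with uniform jitter of +/- half
    a read length, clamped into the exon containing the site."""
    lens = _draw_lengths(rng, n, read_length)
    exon = next((x for x in tx.exons if x[0] <= site_center < x[1]), None)
    if exon is None:
        raise ValueError(f"site center {site_center} not exonic in {tx.transcript_id}")
    xs, xe = exon
    jitter = rng.integers(-(lens // 2), lens // 2 + 1)
    gs = np.clip(site_center - lens // 2 + jitter, xs, np.maximum(xe - lens, xs))
    ge = np.minimum(gs + lens, xe)
    return gs, ge


@dataclass
class SimResult:
    """Everything one simulated experiment produced, plus the answer key."""

    cfg: SimConfig
    genes: list[Gene]
    sites: pd.DataFrame          # planted-footprint truth table
    gene_table: pd.DataFrame     # per-gene truth: biotype, is_target, read accounting
    ip_reads: list[AlignedRead]
    input_reads: list[AlignedRead]

    @property
    def true_targets(self) -> set[str]:
        return set(self.gene_table.loc[self.gene_table.is_target, "gene_id"])

    def write(self, outdir: str) -> dict[str, str]:
        """Write GTF, BED6 libraries, truth tables and the config echo."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "gtf": os.path.join(outdir, "annotation.gtf"),
            "ip_bed": os.path.join(outdir, "ip.bed"),
            "input_bed": os.path.join(outdir, "input.bed"),
            "sites": os.path.join(outdir, "truth_sites.tsv"),
            "genes": os.path.join(outdir, "truth_genes.tsv"),
            "config": os.path.join(outdir, "sim_config.json"),
        }
        write_gtf(self.genes, paths["gtf"])
        write_reads_bed(self.ip_reads, paths["ip_bed"])
        write_reads_bed(self.input_reads, paths["input_bed"])
        self.sites.to_csv(paths["sites"], sep="\t", index=False)
        self.gene_table.to_csv(paths["genes"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            fh.write(self.cfg.to_json() + "\n")
        return paths


def write_reads_bed(reads: list[AlignedRead], path: str) -> None:
    df = reads_to_bed_frame(reads, score=255)
    df = df.sort_values(["chrom", "start", "end", "name"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False)


def simulate_reads(genes: list[Gene], sites: pd.DataFrame, cfg: SimConfig) -> SimResult:
    """Emit the IP and input libraries plus exact read accounting."""
    sites_by_gene = {gid: df for gid, df in sites.groupby("gene_id")} if len(sites) else {}
    ip_reads: list[AlignedRead] = []
    input_reads: list[AlignedRead] = []
    gene_rows = []
    site_counts = {sid: {"n_ip_reads": 0, "n_input_reads": 0} for sid in sites.get("site_id", [])}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        gid = gene.gene_id
        tx = gene.representative_transcript()
        L = tx.exonic_length
        accounting = {"gene_id": gid, "biotype": gene.biotype}
        for lib, depth, out, stream in (
            ("ip", cfg.background_depth, ip_reads, "ip"),
            ("input", cfg.input_depth, input_reads, "input"),
        ):
            rng = _rng(cfg.seed, gid, stream)
            n_bg = int(rng.poisson(depth * L))
            gs, ge = _place_uniform(tx, rng, n_bg, cfg.read_length)
            for i in range(n_bg):
                out.append(AlignedRead(gene.chrom, int(gs[i]), int(ge[i]), gene.strand,
                                       f"{lib}_{gid}_b{i}"))
            accounting[f"n_background_{lib}"] = n_bg
            n_site_total = 0
            for row in sites_by_gene.get(gid, pd.DataFrame()).itertuples(index=False):
                if lib == "input" and not row.present_in_input:
                    continue
                mean_extra = (row.enrichment - 1.0) * depth * cfg.footprint_width
                n_extra = int(rng.poisson(mean_extra))
                gs2, ge2 = _place_at_site(tx, rng, n_extra, cfg.read_length,
                                          (row.start + row.end) // 2)
                for i in range(n_extra):
                    out.append(AlignedRead(gene.chrom, int(gs2[i]), int(ge2[i]), gene.strand,
                                           f"{lib}_{row.site_id}_{i}"))
                site_counts[row.site_id][f"n_{lib}_reads"] = n_extra
                n_site_total += n_extra
            accounting[f"n_site_{lib}"] = n_site_total
        gsites = sites_by_gene.get(gid)
        accounting["n_sites"] = 0 if gsites is None else len(gsites)
        accounting["is_target"] = bool(gsites is not None and (~gsites.present_in_input).any())
        gene_rows.append(accounting)
    gene_table = pd.DataFrame(gene_rows)
    sites = sites.copy()
    if len(sites):
        sites["n_ip_reads"] = [site_counts[s]["n_ip_reads"] for s in sites.site_id]
        sites["n_input_reads"] = [site_counts[s]["n_input_reads"] for s in sites.site_id]
    return SimResult(cfg=cfg, genes=genes, sites=sites, gene_table=gene_table,
                     ip_reads=ip_reads, input_reads=input_reads)


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Annotation + footprint plan + both read libraries, in one call."""
    genes = simulate_genes(cfg)
    sites = plan_sites(genes, cfg) if cfg.n_target_genes > 0 else pd.DataFrame(
        columns=["site_id", "gene_id", "chrom", "start", "end", "strand",
                 "region", "enrichment", "present_in_input"]
    )
    return simulate_reads(genes, sites, cfg)


# ---------------------------------------------------------------------------
# sequences and motif planting


def plant_motifs(sequences: dict[str, str], sites, motif: str) -> dict[str, str]:
    """Write ``motif`` at the center of each site; overlapping plants warn
    and the later plant wins.

    ``sites`` is an iterable of (seq_name, start, end, strand) tuples or
    objects/rows with those fields; minus-strand sites receive the reverse
    complement so the motif reads in transcript sense.
    """
    seqs = {k: list(v) for k, v in sequences.items()}
    planted: dict[str, list[tuple[int, int]]] = {k: [] for k in sequences}
    for site in sites:
        if hasattr(site, "chrom"):
            name, start, end, strand = site.chrom, site.start, site.end, site.strand
        else:
            name, start, end, strand = site
        if name not in seqs:
            raise KeyError(f"no sequence named {name!r}")
        center = (start + end) // 2
        m = motif if strand == "+" else reverse_complement(motif)
        lo = center - len(m) // 2
        hi = lo + len(m)
        if lo < 0 or hi > len(seqs[name]):
            raise ValueError(f"motif at {name}:{lo}-{hi} falls outside the sequence")
        if any(lo < pe and ps < hi for ps, pe in planted[name]):
            logger.warning("overlapping motif plant at %s:%d-%d; later plant wins", name, lo, hi)
        planted[name].append((lo, hi))
        seqs[name][lo:hi] = m
    return {k: "".join(v) for k, v in seqs.items()}


def simulate_genome_sequence(genes: list[Gene], cfg: SimConfig,
                             sites: pd.DataFrame | None = None,
                             motif: str | None = "GGAC") -> dict[str, str]:
    """Random chromosome sequence, with the consensus motif planted at each
    footprint center when ``motif`` is given."""
    rng = _rng(cfg.seed, "sequence")
    length = chromosome_length(genes, cfg)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    seqs = {cfg.chrom_name: seq}
    if motif and sites is not None and len(sites):
        seqs = plant_motifs(seqs, sites.itertuples(index=False), motif)
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def site_sequences(seqs: dict[str, str], sites: pd.DataFrame, flank: int = 0) -> list[str]:
    """Transcript-sense sequences of the planted footprints (+/- flank)."""
    out = []
    for row in sites.itertuples(index=False):
        s = seqs[row.chrom][max(row.start - flank, 0) : row.end + flank]
        out.append(reverse_complement(s) if row.strand == "-" else s)
    return out


def background_windows(seqs: dict[str, str], genes: list[Gene], n: int, width: int,
                       rng: np.random.Generator,
                       exclude_genes: set[str] | None = None) -> list[str]:
    """Random transcript-sense exonic windows, for use as k-mer background."""
    pool = [g for g in genes if not exclude_genes or g.gene_id not in exclude_genes]
    exons = [(g.chrom, s, e, g.strand) for g in pool for s, e in g.merged_exons() if e - s >= width]
    if not exons:
        raise ValueError("no exon long enough for background windows")
    out = []
    for _ in range(n):
        chrom, s, e, strand = exons[int(rng.integers(len(exons)))]
        start = int(rng.integers(s, e - width + 1))
        w = seqs[chrom][start : start + width]
        out.append(reverse_complement(w) if strand == "-" else w)
    return out
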