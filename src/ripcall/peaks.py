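"""Permutation-null peak calling for RIP/CLIP-style IP libraries.

The procedure, per gene:

1. reads with >=1 bp mutual overlap are clustered into candidate peaks
   (transitive closure); a peak's height is its maximum per-base coverage;
2. a null distribution of the maximum peak height is built by repeatedly
   re-placing reads with the same count and length multiset uniformly at
   random over the gene (500 permutations by default) and re-clustering;
3. each observed peak receives an empirical p-value against that null and
   peaks are selected at ``alpha`` (or, under the ``strict_max`` rule, when
   the observed height exceeds every permutation maximum);
4. IP and input libraries are analysed independently and IP peaks that
   overlap any selected input peak are discarded;
5. target genes are the genes owning at least one retained peak.

Results are deterministic for a given master seed: every gene draws its own
RNG stream keyed on (seed, gene_id), so gene iteration order is irrelevant.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .annotation import Gene, GenomeIndex, Transcript
from .reads import AlignedRead, assign_reads

logger = logging.getLogger(__name__)

DEFAULT_N_SIMS = 500
DEFAULT_ALPHA = 0.05
DEFAULT_SELECT_RULE = "strict_max"


@dataclass
class Peak:
    """A clustered read region with height and permutation significance."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str = ""
    height: int = 0
    support: int = 0
    summit: int | None = None        # center of the leftmost max-coverage run
    p_empirical: float | None = None
    selected: bool = False

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class NullModel:
    """Per-gene permutation null of the maximum peak height."""

    gene_id: str
    n_sims: int
    sim_max_heights: np.ndarray          # shape (n_sims,), int
    read_lengths: np.ndarray             # multiset of observed peak-read lengths
    seed_entropy: tuple
    placements: list[np.ndarray] | None = None  # per-sim (start, end) spans if kept

    def __post_init__(self) -> None:
        assert len(self.sim_max_heights) == self.n_sims


def gene_rng(master_seed: int, gene_id: str, stream: int = 0) -> np.random.Generator:
    """Deterministic per-gene RNG, independent of gene iteration order."""
    entropy = (int(master_seed), zlib.crc32(gene_id.encode()), int(stream))
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# clustering


def max_coverage(starts: np.ndarray, ends: np.ndarray) -> tuple[int, int]:
    """Maximum per-base coverage of a set of half-open intervals and a
    summit position: the center of the leftmost run of bases attaining the
    maximum (coverage is piecewise constant between read boundaries)."""
    if len(starts) == 0:
        return 0, 0
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(len(starts), np.int64), -np.ones(len(ends), np.int64)])
    order = np.lexsort((delta, pos))  # ends before starts at equal pos
    sorted_pos = pos[order]
    cov = np.cumsum(delta[order])
    i = int(np.argmax(cov))  # run extends to the next event position
    return int(cov[i]), int(sorted_pos[i] + sorted_pos[i + 1]) // 2


def cluster_reads(reads: list[AlignedRead]) -> list[Peak]:
    """Cluster reads sharing >=1 bp overlap (transitively) into peaks.

    All reads must lie on one chromosome and strand.  Book-ended reads
    (zero-base overlap under half-open coordinates) start separate peaks.
    The peak interval is the union span of its reads; height is the maximum
    per-base coverage within the cluster.
    """
    if not reads:
        return []
    chroms = {r.chrom for r in reads}
    strands = {r.strand for r in reads}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("cluster_reads expects reads from one chromosome and strand")
    order = sorted(range(len(reads)), key=lambda i: (reads[i].start, reads[i].end))
    peaks: list[Peak] = []
    members: list[list[int]] = []
    cur_end = None
    for i in order:
        r = reads[i]
        if cur_end is not None and r.start < cur_end:
            members[-1].append(i)
            cur_end = max(cur_end, r.end)
            peaks[-1].end = cur_end
        else:
            peaks.append(Peak(r.chrom, r.start, r.end, r.strand))
            members.append([i])
            cur_end = r.end
    for pk, idx in zip(peaks, members):
        s = np.array([reads[i].start for i in idx])
        e = np.array([reads[i].end for i in idx])
        pk.height, pk.summit = max_coverage(s, e)
        pk.support = len(idx)
    return peaks


def place_reads_contiguous(tx: Transcript, rng: np.random.Generator,
                           lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Place reads uniformly over the transcript's exonic space, restricted
    to starts where the read maps back to one contiguous genomic interval
    (i.e. lies within a single exon, as an unspliced aligned read does).

    Reads longer than every exon are placed flush at the start of the
    longest exon, clipped to it, with a warning.  Returns genomic
    (starts, ends) aligned with ``lengths``.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    ex_starts = np.array([s for s, _ in tx.exons], dtype=np.int64)
    ex_lens = np.array([e - s for s, e in tx.exons], dtype=np.int64)
    gs = np.empty(lengths.shape, dtype=np.int64)
    ge = np.empty(lengths.shape, dtype=np.int64)
    for l in np.unique(lengths):
        mask = lengths == l
        n = int(mask.sum())
        slots = np.maximum(ex_lens - l + 1, 0)
        total = int(slots.sum())
        if total == 0:
            i = int(np.argmax(ex_lens))
            logger.warning(
                "%s: read length %d exceeds every exon; placed flush at exon start",
                tx.transcript_id, l,
            )
            gs[mask] = ex_starts[i]
            ge[mask] = ex_starts[i] + min(int(l), int(ex_lens[i]))
            continue
        cum = np.cumsum(slots)
        r = rng.integers(0, total, size=n)
        idx = np.searchsorted(cum, r, side="right")
        start = ex_starts[idx] + (r - (cum[idx] - slots[idx]))
        gs[mask] = start
        ge[mask] = start + l
    return gs, ge


def _row_max_heights(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Max interval-overlap per row of (n_sims, m) start/end arrays."""
    n, m = starts.shape
    pos = np.concatenate([starts, ends], axis=1)
    delta = np.concatenate(
        [np.ones((1, m), np.int64), -np.ones((1, m), np.int64)], axis=1
    )
    delta = np.broadcast_to(delta, (n, 2 * m))
    key = pos * 2 + (delta > 0)  # end events sort before start events at equal pos
    order = np.argsort(key, axis=1, kind="stable")
    d = np.take_along_axis(delta, order, axis=1)
    return d.cumsum(axis=1).max(axis=1)


# ---------------------------------------------------------------------------
# permutation null


def simulate_null(
    gene: Gene,
    read_lengths: np.ndarray | list[int],
    n_sims: int = DEFAULT_N_SIMS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    span: str = "exonic",
    keep_placements: bool = False,
) -> NullModel:
    """Build the max-height permutation null for one gene.

    Each of the ``n_sims`` permutations places, for every observed peak-read,
    one random read of identical length uniformly within the placement span,
    re-clusters the placed reads and records the maximum peak height.

    ``span="exonic"`` places reads over the representative transcript's
    exonic space and maps them back to genomic spans (RIP reads derive from
    mature mRNA); ``span="gene_span"`` places them over the gene's full
    genomic span.  A read longer than the span is placed flush at the span
    start with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.asarray(read_lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError(f"{gene.gene_id}: no peak reads to permute")
    m = lengths.size

    if span == "exonic":
        tx: Transcript = gene.representative_transcript()
        L = tx.exonic_length
    elif span == "gene_span":
        g0, g1 = gene.span
        L = g1 - g0
    else:
        raise ValueError(f"unknown null span {span!r}")

    if span == "exonic":
        lens = np.broadcast_to(lengths, (n_sims, m)).reshape(-1)
        gs, ge = place_reads_contiguous(tx, rng, lens)
        gs = gs.reshape(n_sims, m)
        ge = ge.reshape(n_sims, m)
    else:
        if np.any(lengths > L):
            logger.warning(
                "%s: %d simulated reads longer than placement span (%d bp); placed flush at span start",
                gene.gene_id, int((lengths > L).sum()), L,
            )
        high = np.maximum(L - lengths + 1, 1)  # per-read number of start positions
        starts_t = rng.integers(0, high, size=(n_sims, m))
        gs = g0 + starts_t
        ge = np.minimum(gs + lengths, g1)

    heights = _row_max_heights(gs, ge)
    placements = None
    if keep_placements:
        placements = [np.stack([gs[i], ge[i]], axis=1) for i in range(n_sims)]
    return NullModel(
        gene_id=gene.gene_id,
        n_sims=n_sims,
        sim_max_heights=heights,
        read_lengths=np.sort(lengths),
        seed_entropy=(seed,),
        placements=placements,
    )


def score_peaks(
    peaks: list[Peak],
    null: NullModel,
    alpha: float = DEFAULT_ALPHA,
    select_rule: str = DEFAULT_SELECT_RULE,
) -> list[Peak]:
    """Attach empirical p-values and select significant peaks (in place).

    ``p_empirical`` is the fraction of permutations whose maximum height is
    >= the observed peak height (ties count against the peak).  Under
    ``select_rule="empirical_p"`` a peak is selected when p < alpha; under
    ``"strict_max"`` when its height strictly exceeds every permutation
    maximum.
    """
    sims = np.sort(null.sim_max_heights)
    n = null.n_sims
    sim_max = int(sims[-1]) if n else 0
    for pk in peaks:
        ge = n - int(np.searchsorted(sims, pk.height, side="left"))
        pk.p_empirical = ge / n
        if select_rule == "empirical_p":
            pk.selected = pk.p_empirical < alpha
        elif select_rule == "strict_max":
            pk.selected = pk.height > sim_max
        else:
            raise ValueError(f"unknown select_rule {select_rule!r}")
    return peaks


def subtract_input(ip_peaks: list[Peak], input_peaks: list[Peak]) -> list[Peak]:
    """Remove IP peaks overlapping (>=1 bp, same strand) any input peak."""
    if not input_peaks:
        logger.warning("input peak set is empty; IP peaks returned unchanged")
        return list(ip_peaks)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for pk in input_peaks:
        trees.setdefault((pk.chrom, pk.strand), IntervalTree()).addi(pk.start, pk.end)
    kept = []
    for pk in ip_peaks:
        tree = trees.get((pk.chrom, pk.strand))
        if tree is not None and tree.overlap(pk.start, pk.end):
            continue
        kept.append(pk)
    logger.info("input subtraction removed %d/%d IP peaks", len(ip_peaks) - len(kept), len(ip_peaks))
    return kept


def call_targets(peaks: list[Peak]) -> set[str]:
    """Genes owning at least one retained peak."""
    return {pk.gene_id for pk in peaks}


# ---------------------------------------------------------------------------
# per-library and IP-vs-input pipelines


@dataclass
class PeakCallResult:
    """All peaks of one library, with per-gene null models."""

    peaks: list[Peak]
    nulls: dict[str, NullModel]
    params: dict

    @property
    def selected(self) -> list[Peak]:
        return [p for p in self.peaks if p.selected]


def call_peaks(
    reads: list[AlignedRead],
    genes: list[Gene],
    index: GenomeIndex | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    null_span: str = "exonic",
    select_rule: str = DEFAULT_SELECT_RULE,
    min_support: int = 1,
) -> PeakCallResult:
    """Cluster, permute and score peaks for one library over all genes.

    Reads are assigned to genes by >=1 bp exon overlap on the matching
    strand; a read overlapping two genes is analysed within each.  Clusters
    with support below ``min_support`` are dropped before the null is built
    (default keeps everything: every read lies in some peak).
    """
    if index is None:
        index = GenomeIndex(genes)
    by_id = {g.gene_id: g for g in genes}
    assignment = assign_reads(reads, index)
    all_peaks: list[Peak] = []
    nulls: dict[str, NullModel] = {}
    for gid in sorted(assignment):
        gene = by_id[gid]
        gene_reads = [reads[i] for i in assignment[gid]]
        peaks = cluster_reads(gene_reads)
        peaks = [p for p in peaks if p.support >= min_support]
        if not peaks:
            continue
        for p in peaks:
            p.gene_id = gid
        # "reads in peaks": with min_support == 1 this is every gene read
        order = sorted(range(len(gene_reads)), key=lambda i: (gene_reads[i].start, gene_reads[i].end))
        kept_spans = IntervalTree.from_tuples((p.start, p.end) for p in peaks) if min_support > 1 else None
        if kept_spans is None:
            lengths = [gene_reads[i].length for i in order]
        else:
            lengths = [gene_reads[i].length for i in order
                       if kept_spans.overlap(gene_reads[i].start, gene_reads[i].end)]
        rng = gene_rng(seed, gid)
        null = simulate_null(gene, lengths, n_sims=n_sims, rng=rng, span=null_span)
        null.seed_entropy = (seed, gid)
        score_peaks(peaks, null, alpha=alpha, select_rule=select_rule)
        nulls[gid] = null
        all_peaks.extend(peaks)
    all_peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.gene_id))
    params = {
        "n_sims": n_sims,
        "alpha": alpha,
        "seed": seed,
        "null_span": null_span,
        "select_rule": select_rule,
        "min_support": min_support,
    }
    return PeakCallResult(peaks=all_peaks, nulls=nulls, params=params)


@dataclass
class RipResult:
    """IP-vs-input run: selected peak sets, retained IP peaks, target genes."""

    ip: PeakCallResult
    input: PeakCallResult
    retained: list[Peak] = field(default_factory=list)
    targets: set[str] = field(default_factory=set)

    @property
    def params(self) -> dict:
        return self.ip.params


def run_rip_pipeline(
    ip_reads: list[AlignedRead],
    input_reads: list[AlignedRead],
    genes: list[Gene],
    index: GenomeIndex | None = None,
    **kwargs,
) -> RipResult:
    """The full IP-vs-input analysis: both libraries are peak-called
    independently with the same configuration, selected IP peaks that
    overlap selected input peaks are removed, and target genes are the
    owners of the retained peaks."""
    if index is None:
        index = GenomeIndex(genes)
    ip_res = call_peaks(ip_reads, genes, index=index, **kwargs)
    input_res = call_peaks(input_reads, genes, index=index, **kwargs)
    retained = subtract_input(ip_res.selected, input_res.selected)
    return RipResult(ip=ip_res, input=input_res, retained=retained,
                     targets=call_targets(retained))


# ---------------------------------------------------------------------------
# output


def peaks_to_bed(peaks: list[Peak]) -> str:
    """Peaks as BED6+4 text (name=gene_id, score=height; extra columns:
    support, p_empirical, selected, summit)."""
    lines = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.gene_id)):
        pval = "NA" if p.p_empirical is None else f"{p.p_empirical:.6f}"
        summit = "NA" if p.summit is None else str(p.summit)
        lines.append(
            f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}\t{p.height}\t{p.strand}"
            f"\t{p.support}\t{pval}\t{int(p.selected)}\t{summit}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def write_peaks_bed(peaks: list[Peak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(peaks_to_bed(peaks))


def write_targets(targets: set[str], path: str) -> None:
    with open(path, "w") as fh:
        for gid in sorted(targets):
            fh.write(gid + "\n")


def write_params(params: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
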