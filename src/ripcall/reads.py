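"""Aligned-read ingestion and gene assignment.

Reads come in as BED6 (the primary path for the synthetic libraries) or
BAM/SAM.  Only uniquely mapped reads survive ingestion; the uniqueness rule
is configurable because aligners encode uniqueness differently.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pandas as pd
import pysam

from .annotation import Gene, GenomeIndex

logger = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped read as a strand-aware genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _parse_rule(rule: str | None) -> tuple[str, int]:
    if rule in (None, "none"):
        return "none", 0
    name, _, arg = rule.partition(":")
    if name not in ("mapq_ge", "score_ge", "nh_eq_1"):
        raise ValueError(f"unknown uniqueness rule {rule!r}")
    return name, int(arg) if arg else 0


def load_reads(
    path: str,
    fmt: str | None = None,
    unique_rule: str | None = "mapq_ge:10",
    pair_mode: str = "read1",
) -> list[AlignedRead]:
    """Load aligned reads from BED6 or BAM/SAM, keeping uniquely mapped reads.

    Parameters
    ----------
    fmt:
        ``"bed"`` or ``"bam"``; inferred from the extension when None.
    unique_rule:
        ``"mapq_ge:<n>"`` (BAM; default threshold 10), ``"nh_eq_1"`` (BAM,
        keep reads whose NH tag is 1; reads without NH are kept),
        ``"score_ge:<n>"`` (BED score column), or ``"none"``.  BED input is
        assumed pre-filtered unless a score rule is given.
    pair_mode:
        for paired BAM: ``"read1"`` keeps each read as its own interval;
        ``"fragment"`` collapses a proper pair to its fragment span
        (emitted once, from the leftmost mate).
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "bam" if ext in (".bam", ".sam", ".cram") else "bed"
    if fmt == "bed":
        return _load_bed(path, unique_rule)
    return _load_bam(path, unique_rule, pair_mode)


def _load_bed(path: str, unique_rule: str | None) -> list[AlignedRead]:
    rule, arg = _parse_rule(unique_rule if unique_rule and unique_rule.startswith("score_ge") else None)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty read file", path)
        return []
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED input needs >=6 columns (strand required)")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS
    n_total = len(df)
    if rule == "score_ge":
        df = df[pd.to_numeric(df["score"], errors="coerce") >= arg]
    dropped = n_total - len(df)
    if dropped:
        logger.info("%s: dropped %d/%d reads failing %s", path, dropped, n_total, unique_rule)
    return [
        AlignedRead(str(r.chrom), int(r.start), int(r.end), str(r.strand), str(r.name))
        for r in df.itertuples(index=False)
    ]


def _load_bam(path: str, unique_rule: str | None, pair_mode: str) -> list[AlignedRead]:
    rule, arg = _parse_rule(unique_rule)
    reads: list[AlignedRead] = []
    n_seen = n_dropped = 0
    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_seen += 1
            if rule == "mapq_ge" and rec.mapping_quality < arg:
                n_dropped += 1
                continue
            if rule == "nh_eq_1" and rec.has_tag("NH") and rec.get_tag("NH") != 1:
                n_dropped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            if pair_mode == "fragment" and rec.is_paired and rec.is_proper_pair:
                tlen = rec.template_length
                if tlen <= 0:  # emit the fragment once, from the leftmost mate
                    continue
                reads.append(
                    AlignedRead(rec.reference_name, rec.reference_start,
                                rec.reference_start + tlen, strand, rec.query_name)
                )
            else:
                # spliced reads contribute each aligned block separately
                for bs, be in rec.get_blocks():
                    reads.append(AlignedRead(rec.reference_name, bs, be, strand, rec.query_name))
    if n_seen == 0:
        logger.warning("%s: no mapped reads", path)
    if n_dropped:
        logger.info("%s: dropped %d/%d reads failing %s", path, n_dropped, n_seen, unique_rule)
    return reads


# ---------------------------------------------------------------------------
# gene assignment


def assign_reads(reads: list[AlignedRead], index: GenomeIndex) -> dict[str, list[int]]:
    """Map gene_id -> indices of reads overlapping its exons.

    A read is assigned to every gene whose merged exons it overlaps by >=1 bp
    on the matching strand, so a read spanning two genes counts once per
    gene.
    """
    out: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        for gid in index.genes_overlapping(r.chrom, r.start, r.end, r.strand, exonic=True):
            out.setdefault(gid, []).append(i)
    return out


def assign_reads_to_genes(reads: list[AlignedRead], genes: list[Gene],
                          index: GenomeIndex | None = None) -> pd.DataFrame:
    """Per-gene read counts with biotype, as a DataFrame.

    Because a read may overlap exons of more than one gene, per-biotype
    totals may exceed the number of reads.
    """
    if index is None:
        index = GenomeIndex(genes)
    assignment = assign_reads(reads, index)
    by_id = {g.gene_id: g for g in genes}

    def n_distinct(idx: list[int]) -> int:
        ids = {reads[i].read_id or i for i in idx}
        return len(ids)

    rows = [
        {"gene_id": gid, "biotype": by_id[gid].biotype, "n_reads": n_distinct(idx)}
        for gid, idx in sorted(assignment.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "n_reads"])


def rank_biotypes(assignments: pd.DataFrame, k: int = 10) -> list[tuple[str, int]]:
    """Top-k biotypes by total assigned reads (ties broken lexicographically)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = assignments.groupby("biotype")["n_reads"].sum()
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(b, int(n)) for b, n in ranked[:k]]


def reads_to_bed_frame(reads: list[AlignedRead], score: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "name": [r.read_id for r in reads],
            "score": score,
            "strand": [r.strand for r in reads],
        }
    )
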