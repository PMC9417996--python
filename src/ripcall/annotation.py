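"""Transcript annotation model.

Parses a GTF/GFF3 annotation into an in-memory gene/transcript model with
gene biotypes, exon/CDS/UTR structure and genome<->transcript coordinate
maps.  Every downstream stage (read assignment, peak calling, metagene and
region profiling) works against this model.

Coordinate convention: everything in memory is 0-based half-open
(BED-style).  GTF/GFF3 files are 1-based closed and are converted at parse
time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Region labels, and the precedence applied when overlapping genes give a
#: position more than one candidate label (highest priority first).
REGION_LABELS = ("5UTR", "CDS", "3UTR", "intron", "intergenic", "noncoding_exon")
DEFAULT_REGION_PRECEDENCE = ("CDS", "5UTR", "3UTR", "noncoding_exon", "intron", "intergenic")

#: Attribute keys probed, in order, for the gene biotype (GTF dialects vary).
BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype")


class AnnotationParseError(ValueError):
    """Raised when the annotation file cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        """True if the intervals share >=1 bp (half-open: book-ends do not overlap)."""
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


class Transcript:
    """One transcript: ordered exons, optional CDS, derived UTRs.

    Exons are stored as genomic ``(start, end)`` pairs sorted by genomic
    coordinate; transcript coordinates run 5'->3' in transcript orientation
    (i.e. from the high-coordinate end on the minus strand).
    """

    def __init__(
        self,
        transcript_id: str,
        chrom: str,
        strand: str,
        exons: list[tuple[int, int]],
        cds: list[tuple[int, int]] | None = None,
    ) -> None:
        exons = sorted((int(s), int(e)) for s, e in exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{transcript_id}: overlapping exons [{s1},{e1}) [{s2},{e2})")
        self.transcript_id = transcript_id
        self.chrom = chrom
        self.strand = strand
        self.exons = exons
        self.cds = sorted((int(s), int(e)) for s, e in cds) if cds else []
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in exons):
                raise ValueError(f"{transcript_id}: CDS [{s},{e}) not contained in an exon")

        self._exon_starts = np.array([s for s, _ in exons], dtype=np.int64)
        self._exon_ends = np.array([e for _, e in exons], dtype=np.int64)
        lens = self._exon_ends - self._exon_starts
        self._cum = np.cumsum(lens)           # cumulative exonic length through exon i
        self._cum0 = self._cum - lens         # cumulative exonic length before exon i
        self.exonic_length = int(self._cum[-1])

        # CDS extent in transcript coordinates
        if self.cds:
            u = [self._gpos_to_u(s) for s, _ in self.cds] + [self._gpos_to_u(e - 1) for _, e in self.cds]
            u_min, u_max = min(u), max(u)
            if strand == "+":
                self.cds_t = (u_min, u_max + 1)
            else:
                T = self.exonic_length
                self.cds_t = (T - 1 - u_max, T - u_min)
        else:
            self.cds_t = None

    # -- coordinate maps ---------------------------------------------------

    def _gpos_to_u(self, pos: int) -> int:
        """Genomic position -> plus-orientation exonic offset (raises if not exonic)."""
        i = int(np.searchsorted(self._exon_starts, pos, side="right")) - 1
        if i < 0 or pos >= self._exon_ends[i]:
            raise ValueError(f"position {pos} not exonic in {self.transcript_id}")
        return int(self._cum0[i] + pos - self._exon_starts[i])

    def _u_to_gpos(self, u):
        """Plus-orientation exonic offset(s) -> genomic position(s); vectorised."""
        u = np.asarray(u, dtype=np.int64)
        idx = np.searchsorted(self._cum, u, side="right")
        return self._exon_starts[idx] + (u - self._cum0[idx])

    def locate(self, pos: int) -> tuple[str, int | None]:
        """Classify a genomic position relative to this transcript.

        Returns ``("exonic", t)`` with the transcript-space offset,
        ``("intronic", None)`` or ``("outside", None)``.
        """
        if pos < self.exons[0][0] or pos >= self.exons[-1][1]:
            return "outside", None
        try:
            u = self._gpos_to_u(pos)
        except ValueError:
            return "intronic", None
        t = u if self.strand == "+" else self.exonic_length - 1 - u
        return "exonic", t

    def genome_to_transcript(self, pos: int) -> int | None:
        """Transcript-space offset of an exonic genomic position, else None."""
        kind, t = self.locate(pos)
        return t

    def transcript_to_genome(self, t):
        """Inverse of :meth:`genome_to_transcript`; accepts scalars or arrays."""
        t = np.asarray(t, dtype=np.int64)
        if np.any((t < 0) | (t >= self.exonic_length)):
            raise ValueError("transcript position out of range")
        u = t if self.strand == "+" else self.exonic_length - 1 - t
        out = self._u_to_gpos(u)
        return int(out) if out.ndim == 0 else out

    def tspan_to_genomic_span(self, t_start, length):
        """Genomic span [start, end) covering transcript bases [t_start, t_start+length).

        Vectorised over ``t_start``/``length``.  The span is the outermost pair
        of genomic coordinates; a span crossing an intron covers it (reads are
        handled as plain genomic intervals downstream).
        """
        t_start = np.asarray(t_start, dtype=np.int64)
        length = np.broadcast_to(np.asarray(length, dtype=np.int64), t_start.shape)
        ga = self.transcript_to_genome(t_start)
        gb = self.transcript_to_genome(t_start + length - 1)
        ga = np.asarray(ga)
        gb = np.asarray(gb)
        return np.minimum(ga, gb), np.maximum(ga, gb) + 1

    # -- derived structure -------------------------------------------------

    @property
    def utr_lengths(self) -> tuple[int, int, int] | None:
        """(5'UTR, CDS, 3'UTR) lengths in transcript bases, or None if no CDS."""
        if self.cds_t is None:
            return None
        a, b = self.cds_t
        return a, b - a, self.exonic_length - b

    def region_of_tpos(self, t: int) -> str:
        """Region label of a transcript-space position."""
        if self.cds_t is None:
            return "noncoding_exon"
        a, b = self.cds_t
        if t < a:
            return "5UTR"
        if t < b:
            return "CDS"
        return "3UTR"

    def _exonic_minus_cds(self) -> list[tuple[int, int]]:
        if not self.cds:
            return list(self.exons)
        out = []
        for xs, xe in self.exons:
            cur = xs
            for cs, ce in self.cds:
                if ce <= cur or cs >= xe:
                    continue
                if cs > cur:
                    out.append((cur, cs))
                cur = max(cur, ce)
            if cur < xe:
                out.append((cur, xe))
        return out

    @property
    def utr5(self) -> list[tuple[int, int]]:
        """Genomic 5'UTR segments (high-coordinate side on the minus strand)."""
        if not self.cds:
            return []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        segs = self._exonic_minus_cds()
        if self.strand == "+":
            return [s for s in segs if s[1] <= cds_lo]
        return [s for s in segs if s[0] >= cds_hi]

    @property
    def utr3(self) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        segs = self._exonic_minus_cds()
        if self.strand == "+":
            return [s for s in segs if s[0] >= cds_hi]
        return [s for s in segs if s[1] <= cds_lo]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Transcript {self.transcript_id} {self.chrom}:{self.exons[0][0]}-{self.exons[-1][1]}({self.strand}) {len(self.exons)} exons>"


@dataclass
class Gene:
    """A gene: one or more transcripts sharing a biotype and strand."""

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span covering every exon of every transcript."""
        start = min(t.exons[0][0] for t in self.transcripts.values())
        end = max(t.exons[-1][1] for t in self.transcripts.values())
        return start, end

    @property
    def is_coding(self) -> bool:
        return any(t.cds for t in self.transcripts.values())

    def representative_transcript(self) -> Transcript:
        """The transcript used for profiling: longest CDS among CDS-bearing
        transcripts, else longest exonic length; ties broken by id."""
        txs = list(self.transcripts.values())
        coding = [t for t in txs if t.cds_t is not None]
        if coding:
            return max(coding, key=lambda t: (t.cds_t[1] - t.cds_t[0], t.exonic_length, t.transcript_id))
        return max(txs, key=lambda t: (t.exonic_length, t.transcript_id))

    def merged_exons(self) -> list[tuple[int, int]]:
        """Union of exons across transcripts, merged into disjoint intervals."""
        ivs = sorted(x for t in self.transcripts.values() for x in t.exons)
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# parsing


def _validate_lines(path: str) -> set[str]:
    """Check the 9-column layout (reporting the first bad line) and return
    the set of feature types present."""
    feature_types: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(f"{path}: malformed annotation at line {i} (expected 9 tab-separated columns)")
            feature_types.add(fields[2])
    return feature_types


def _attr(feature, *keys, default=None):
    for k in keys:
        if k in feature.attributes:
            v = feature.attributes[k]
            return v[0] if isinstance(v, list) else v
    return default


def load_annotation(path: str, biotype_key: str | None = None) -> list[Gene]:
    """Parse a GTF or GFF3 file into a list of :class:`Gene`.

    Coordinates are converted from the file's 1-based closed convention to
    0-based half-open.  The biotype is read from ``biotype_key`` if given,
    else from ``gene_biotype``/``gene_type``/``biotype``; a gene with none of
    these is assigned biotype ``"unknown"`` with a logged warning.  UTRs are
    derived from CDS where present; genes without any CDS are noncoding.
    """
    feature_types = _validate_lines(path)
    keys = (biotype_key,) + BIOTYPE_KEYS if biotype_key else BIOTYPE_KEYS
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            # infer gene/transcript records only when the file lacks them
            disable_infer_genes="gene" in feature_types,
            disable_infer_transcripts=bool({"transcript", "mRNA"} & feature_types),
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise AnnotationParseError(f"{path}: failed to parse annotation: {exc}") from exc

    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        gene_id = _attr(g, "gene_id", "ID", default=g.id)
        biotype = _attr(g, *keys)
        if biotype is None:
            logger.warning("gene %s has no biotype attribute; assigning 'unknown'", gene_id)
            biotype = "unknown"
        gene = Gene(
            gene_id=gene_id,
            gene_name=_attr(g, "gene_name", "Name", default=gene_id),
            biotype=biotype,
            chrom=g.seqid,
            strand=g.strand,
        )
        for tf in db.children(g, featuretype=("transcript", "mRNA"), order_by="start"):
            tid = _attr(tf, "transcript_id", "ID", default=tf.id)
            exons = [(e.start - 1, e.end) for e in db.children(tf, featuretype="exon")]
            cds = [(c.start - 1, c.end) for c in db.children(tf, featuretype="CDS")]
            if not exons:
                continue
            gene.transcripts[tid] = Transcript(tid, g.seqid, g.strand, exons, cds or None)
        if gene.transcripts:
            genes.append(gene)
    genes.sort(key=lambda g: g.gene_id)
    return genes


# ---------------------------------------------------------------------------
# position labelling


class GenomeIndex:
    """Strand-aware interval index over gene spans, for position labelling
    and read->gene lookup."""

    def __init__(self, genes: list[Gene], precedence: tuple[str, ...] = DEFAULT_REGION_PRECEDENCE):
        self.genes = {g.gene_id: g for g in genes}
        self.precedence = precedence
        self._span_trees: dict[tuple[str, str], IntervalTree] = {}
        self._exon_trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            s, e = g.span
            self._span_trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(s, e, g.gene_id)
            xt = self._exon_trees.setdefault((g.chrom, g.strand), IntervalTree())
            for xs, xe in g.merged_exons():
                xt.addi(xs, xe, g.gene_id)

    def genes_at(self, chrom: str, pos: int, strand: str) -> list[Gene]:
        tree = self._span_trees.get((chrom, strand))
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos))
        return [self.genes[g] for g in hits]

    def genes_overlapping(self, chrom: str, start: int, end: int, strand: str,
                          exonic: bool = True) -> list[str]:
        """gene_ids whose (merged exons | span) overlap [start,end) by >=1 bp."""
        trees = self._exon_trees if exonic else self._span_trees
        tree = trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def label_position(self, chrom: str, pos: int, strand: str) -> str:
        """Region label of a genomic position under the precedence rule.

        Each overlapping gene contributes the label of its representative
        transcript at that position; the highest-precedence label wins, and a
        position covered by no gene is intergenic.
        """
        labels = set()
        for gene in self.genes_at(chrom, pos, strand):
            tx = gene.representative_transcript()
            kind, t = tx.locate(pos)
            if kind == "exonic":
                labels.add(tx.region_of_tpos(t))
            else:
                labels.add("intron")
        if not labels:
            return "intergenic"
        for lab in self.precedence:
            if lab in labels:
                return lab
        return "intergenic"  # pragma: no cover


# ---------------------------------------------------------------------------
# export


def genes_to_frame(genes: list[Gene]):
    """Model summary as a DataFrame (one row per transcript), for inspection."""
    import pandas as pd

    rows = []
    for g in genes:
        for t in g.transcripts.values():
            ul = t.utr_lengths
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "gene_name": g.gene_name,
                    "biotype": g.biotype,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "transcript_id": t.transcript_id,
                    "n_exons": len(t.exons),
                    "exonic_length": t.exonic_length,
                    "utr5_len": ul[0] if ul else 0,
                    "cds_len": ul[1] if ul else 0,
                    "utr3_len": ul[2] if ul else 0,
                    "span_start": t.exons[0][0],
                    "span_end": t.exons[-1][1],
                }
            )
    return pd.DataFrame(rows)
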