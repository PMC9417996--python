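"""Binding-profile analytics: metagene enrichment and region distribution.

The metagene profile averages binding signal across genes on a normalised
transcript axis (5'UTR | CDS | 3'UTR, a fixed number of bins per region).
The region distribution counts peaks by the genomic region of their
midpoint (CDS, UTRs, noncoding exon, intron, intergenic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeIndex, REGION_LABELS
from .peaks import Peak
from .reads import AlignedRead

METAGENE_REGIONS = ("5UTR", "CDS", "3UTR")
DEFAULT_BINS_PER_REGION = 20


@dataclass
class MetageneProfile:
    """Binding density over normalised 5'UTR/CDS/3'UTR bins."""

    bins_per_region: int
    counts: dict[str, np.ndarray]            # region -> per-bin item counts
    skipped: Counter = field(default_factory=Counter)
    normalization: str = "none"

    @property
    def n_binned(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    @property
    def n_total(self) -> int:
        return self.n_binned + sum(self.skipped.values())

    def values(self) -> np.ndarray:
        """Concatenated per-bin values (5'UTR|CDS|3'UTR) under the profile's
        normalization: raw counts, or fractions summing to 1 for
        ``library_size``."""
        v = np.concatenate([self.counts[r].astype(float) for r in METAGENE_REGIONS])
        if self.normalization == "library_size":
            total = v.sum()
            if total > 0:
                v = v / total
        return v

    def region_fractions(self) -> dict[str, float]:
        """Fraction of binned mass per region."""
        total = self.n_binned
        if total == 0:
            return {r: 0.0 for r in METAGENE_REGIONS}
        return {r: float(self.counts[r].sum()) / total for r in METAGENE_REGIONS}

    def to_frame(self) -> pd.DataFrame:
        vals = self.values()
        rows = []
        i = 0
        for region in METAGENE_REGIONS:
            for b in range(self.bins_per_region):
                rows.append({"region": region, "bin": b,
                             "count": int(self.counts[region][b]), "value": vals[i]})
                i += 1
        return pd.DataFrame(rows)


def _item_location(item, locate: str) -> tuple[str, int, str, str]:
    """(chrom, anchor position, strand, gene_id-or-empty) of a peak or read."""
    gid = getattr(item, "gene_id", "") or ""
    pos = item.midpoint
    if locate != "midpoint":
        summit = getattr(item, "summit", None)
        if summit is not None:
            pos = summit
        elif locate == "summit":
            raise ValueError("locate='summit' requires items with a summit")
    return item.chrom, pos, item.strand, gid


def metagene(
    items: list[Peak] | list[AlignedRead],
    index: GenomeIndex,
    bins_per_region: int = DEFAULT_BINS_PER_REGION,
    normalization: str = "library_size",
    locate: str = "auto",
) -> MetageneProfile:
    """Accumulate item positions into normalised 5'UTR/CDS/3'UTR bins.

    Each item is anchored at one position on the representative transcript
    of its gene (peaks carry a gene_id; reads are looked up in the index,
    the lexicographically first matching gene winning).  ``locate`` picks
    the anchor: ``"auto"`` uses a peak's coverage summit when present (the
    best estimate of the binding position; broad clusters over dense
    background say little through their midpoint) and the midpoint
    otherwise; ``"midpoint"`` and ``"summit"`` force one choice.  Items
    whose anchor is not exonic on that transcript, or whose gene has no
    CDS, are skipped and tallied.
    """
    counts = {r: np.zeros(bins_per_region, dtype=np.int64) for r in METAGENE_REGIONS}
    skipped: Counter = Counter()
    for item in items:
        chrom, mid, strand, gid = _item_location(item, locate)
        if gid:
            gene = index.genes.get(gid)
            if gene is None:
                skipped["unknown_gene"] += 1
                continue
        else:
            hits = index.genes_at(chrom, mid, strand)
            gene = hits[0] if hits else None
            if gene is None:
                skipped["no_gene"] += 1
                continue
        tx = gene.representative_transcript()
        if tx.cds_t is None:
            skipped["no_cds"] += 1
            continue
        kind, t = tx.locate(mid)
        if kind != "exonic":
            skipped[kind] += 1
            continue
        a, b = tx.cds_t
        lens = {"5UTR": a, "CDS": b - a, "3UTR": tx.exonic_length - b}
        if t < a:
            region, off, rl = "5UTR", t, lens["5UTR"]
        elif t < b:
            region, off, rl = "CDS", t - a, lens["CDS"]
        else:
            region, off, rl = "3UTR", t - b, lens["3UTR"]
        if rl == 0:
            skipped["zero_length_region"] += 1
            continue
        bin_i = min(int(off / rl * bins_per_region), bins_per_region - 1)
        counts[region][bin_i] += 1
    return MetageneProfile(bins_per_region=bins_per_region, counts=counts,
                           skipped=skipped, normalization=normalization)


def enrichment_profile(ip: MetageneProfile, inp: MetageneProfile,
                       eps: float | None = None) -> np.ndarray:
    """Per-bin (IP density + eps) / (input density + eps) ratio curve.

    The default pseudocount is 1 / (total bins x total items), small enough
    to leave populated bins untouched while keeping empty input bins finite.
    """
    if ip.bins_per_region != inp.bins_per_region:
        raise ValueError("profiles must share bins_per_region")
    n_bins = 3 * ip.bins_per_region
    if eps is None:
        n_items = max(ip.n_binned + inp.n_binned, 1)
        eps = 1.0 / (n_bins * n_items)
    a = MetageneProfile(ip.bins_per_region, ip.counts, ip.skipped, "library_size").values()
    b = MetageneProfile(inp.bins_per_region, inp.counts, inp.skipped, "library_size").values()
    return (a + eps) / (b + eps)


@dataclass
class RegionDistribution:
    """Peak counts and fractions per region label."""

    counts: dict[str, int]
    empty: bool = False

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / total for k, v in self.counts.items()}

    def modal_label(self) -> str | None:
        if self.empty:
            return None
        return max(self.counts.items(), key=lambda kv: (kv[1], kv[0]))[0]

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame(
            [{"region": k, "count": self.counts[k], "fraction": fr[k]} for k in self.counts]
        )


def region_distribution(peaks: list[Peak], index: GenomeIndex) -> RegionDistribution:
    """Distribution of peak midpoints across gene regions.

    An empty peak set yields all-zero counts flagged ``empty`` (fractions
    are reported as zeros rather than NaN).
    """
    counts = {lab: 0 for lab in REGION_LABELS}
    for pk in peaks:
        counts[index.label_position(pk.chrom, pk.midpoint, pk.strand)] += 1
    return RegionDistribution(counts=counts, empty=not peaks)
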