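"""Multi-evidence target intersection and consensus k-mer enrichment.

Target evidence streams (replicate IP target sets, externally derived gene
lists) are combined by plain set intersection after identifier
normalisation.  Sequence preference under peaks is summarised by k-mer
enrichment of peak sequences against matched background, with a binomial
test per k-mer and Bonferroni correction over the 4^k tests.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def normalize_gene_id(gene_id: str, strip_version: bool = True, uppercase: bool = True) -> str:
    """Normalise a gene identifier (strip Ensembl version suffix, uppercase)."""
    g = gene_id.strip()
    if strip_version:
        g = _VERSION_RE.sub("", g)
    if uppercase:
        g = g.upper()
    return g


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of normalised gene identifiers."""

    label: str
    members: frozenset[str]

    @classmethod
    def from_ids(cls, label: str, ids, normalize: bool = True, **norm_kwargs) -> "GeneSet":
        if normalize:
            ids = (normalize_gene_id(g, **norm_kwargs) for g in ids)
        return cls(label=label, members=frozenset(ids))

    def __len__(self) -> int:
        return len(self.members)


def read_gene_list(path: str, label: str | None = None, normalize: bool = True) -> GeneSet:
    """Read a plain-text gene list (one identifier per line)."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return GeneSet.from_ids(label or path, ids, normalize=normalize)


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


@dataclass
class IntersectionResult:
    """Venn partition of >=2 gene sets."""

    labels: list[str]
    membership: pd.DataFrame        # bool column per label, index = gene
    partition_counts: dict[tuple[bool, ...], int]
    core: GeneSet                   # the full n-way intersection

    def count(self, *labels: str) -> int:
        """Number of genes belonging to exactly the given labels."""
        key = tuple(l in labels for l in self.labels)
        return self.partition_counts.get(key, 0)


def intersect_sets(sets: list[GeneSet]) -> IntersectionResult:
    """Per-gene membership bitmap, Venn partition counts and the full
    intersection of two or more gene sets.  Order of the input sets does not
    affect the intersection or the partition (columns follow input order)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets")
    for s in sets:
        if not s.members:
            logger.warning("gene set %r is empty; full intersection will be empty", s.label)
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("gene set labels must be unique")
    union = sorted(set().union(*(s.members for s in sets)))
    membership = pd.DataFrame(
        {s.label: [g in s.members for g in union] for s in sets}, index=pd.Index(union, name="gene_id")
    )
    counts: dict[tuple[bool, ...], int] = {}
    if union:
        for key, grp in membership.groupby(list(membership.columns)):
            counts[tuple(bool(k) for k in (key if isinstance(key, tuple) else (key,)))] = len(grp)
    core_members = frozenset.intersection(*(s.members for s in sets))
    core = GeneSet(label="&".join(labels), members=core_members)
    return IntersectionResult(labels=labels, membership=membership,
                              partition_counts=counts, core=core)


# ---------------------------------------------------------------------------
# k-mer enrichment


def count_kmers(seqs, k: int) -> Counter:
    """Count all k-mers over the A/C/G/T alphabet in a pool of sequences
    (windows containing other characters are skipped)."""
    counts: Counter = Counter()
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= set("ACGT"):
                counts[kmer] += 1
    return counts


def kmer_enrichment(
    foreground,
    background,
    k: int = 4,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Rank k-mers by foreground/background enrichment.

    For each k-mer the foreground count is tested against the background
    frequency with a one-sided binomial test; ``significant`` applies a
    Bonferroni correction over all 4^k tests.  Returns a DataFrame sorted by
    descending enrichment ratio (k-mer lexicographic order breaks ties),
    empty (with a warning) when no sequence is long enough.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    fg = count_kmers(foreground, k)
    bg = count_kmers(background, k)
    fg_total = sum(fg.values())
    bg_total = sum(bg.values())
    if fg_total == 0 or bg_total == 0:
        logger.warning("k=%d leaves no countable k-mers (fg=%d, bg=%d windows)", k, fg_total, bg_total)
        return pd.DataFrame(columns=["kmer", "fg_count", "bg_count", "ratio", "p_value", "significant"])
    if bg_total < fg_total:
        logger.warning("background pool smaller than foreground (%d < %d windows); proceeding", bg_total, fg_total)
    n_tests = 4 ** k
    rows = []
    for kmer in map("".join, itertools.product("ACGT", repeat=k)):
        f = fg.get(kmer, 0)
        b = bg.get(kmer, 0)
        if f == 0 and b == 0:
            continue
        fg_freq = (f + pseudocount) / (fg_total + pseudocount * n_tests)
        bg_freq = (b + pseudocount) / (bg_total + pseudocount * n_tests)
        p0 = min(max(bg_freq, 1e-300), 1.0)
        p_value = float(stats.binom.sf(f - 1, fg_total, p0)) if f > 0 else 1.0
        rows.append(
            {
                "kmer": kmer,
                "fg_count": f,
                "bg_count": b,
                "ratio": fg_freq / bg_freq,
                "p_value": p_value,
                "significant": p_value < alpha / n_tests,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["ratio", "kmer"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequence extraction


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_interval_sequences(fasta_path: str, intervals) -> list[str]:
    """Transcript-sense sequences of genomic intervals from a genome FASTA.

    ``intervals`` is an iterable of objects with chrom/start/end/strand
    (peaks work).  Minus-strand intervals are reverse-complemented.
    """
    from pyfaidx import Fasta

    out = []
    with Fasta(fasta_path, as_raw=True, sequence_always_upper=True) as fa:
        for iv in intervals:
            seq = str(fa[iv.chrom][iv.start : iv.end])
            out.append(reverse_complement(seq) if iv.strand == "-" else seq)
    return out
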