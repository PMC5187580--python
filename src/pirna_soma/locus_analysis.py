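"""piRNA cluster and genic accounting from unique genome alignments.

Cluster counts, fold ratios and coverage use 23-29 nt reads that align
uniquely to the genome (multi-mappers are suppressed entirely), normalized
to total uniquely aligning reads excluding sno/tRNA and miRNA reads. Genic
piRNAs are split into 5'UTR / CDS / 3'UTR by majority overlap and into
sense/antisense relative to the gene strand.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .mini_align import Alignment, align_all, align_any, select_unique
from .preprocess import ReadRecord
from .refio import (
    CDS,
    FIVE_UTR,
    THREE_UTR,
    GeneRegions,
    IntervalSet,
    SequenceDB,
)

REGIONS = (FIVE_UTR, CDS, THREE_UTR)

PIRNA_WINDOW = (23, 29)


def unique_genome_alignments(
    reads: Sequence[ReadRecord],
    genome_db: SequenceDB,
    v: int = 1,
    size_window: tuple[int, int] | None = PIRNA_WINDOW,
) -> list[Alignment]:
    """One alignment per read that maps uniquely to the genome (reads with
    >= 2 hits at <= v mismatches are suppressed), after size selection."""
    out: list[Alignment] = []
    cache: dict[str, Alignment | None] = {}
    for read in reads:
        if size_window is not None:
            lo, hi = size_window
            if not lo <= len(read.sequence) <= hi:
                continue
        aln = cache.get(read.sequence, "?")
        if aln == "?":
            aln = select_unique(align_all(read.read_id, read.sequence, genome_db, v))
            cache[read.sequence] = aln
        if aln is not None:
            # re-attach this read's id (cache may hold another read's hit)
            out.append(
                Alignment(read.read_id, aln.ref_id, aln.start, aln.end,
                          aln.strand, aln.mismatches)
            )
    return out


def unique_total_excluding(
    reads: Sequence[ReadRecord],
    genome_db: SequenceDB,
    exclude_dbs: Sequence[SequenceDB],
    v: int = 1,
    size_window: tuple[int, int] | None = None,
) -> int:
    """Total uniquely genome-aligning reads, excluding reads that align to
    any of the given databases (conventionally sno/tRNA and miRNA) — the
    per-library normalizer for cluster statistics."""
    cache: dict[str, bool] = {}
    n = 0
    for read in reads:
        if size_window is not None:
            lo, hi = size_window
            if not lo <= len(read.sequence) <= hi:
                continue
        counted = cache.get(read.sequence)
        if counted is None:
            counted = not any(align_any(read.sequence, db, v) for db in exclude_dbs)
            if counted:
                counted = (
                    select_unique(align_all(read.read_id, read.sequence, genome_db, v))
                    is not None
                )
            cache[read.sequence] = counted
        n += counted
    return n


def _cluster_trees(clusters: IntervalSet) -> dict[str, IntervalTree]:
    clusters.validate_nonoverlapping()
    trees: dict[str, IntervalTree] = {}
    for iv in clusters:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def assign_cluster(alignment: Alignment, trees: Mapping[str, IntervalTree]) -> str | None:
    """Cluster holding the alignment (>= 1 bp overlap). If the alignment
    spans the gap between two clusters, the larger overlap wins, then the
    leftmost cluster."""
    tree = trees.get(alignment.ref_id)
    if tree is None:
        return None
    hits = tree.overlap(alignment.start, alignment.end)
    if not hits:
        return None
    best = max(
        (iv.data for iv in hits),
        key=lambda c: (c.overlap(alignment.start, alignment.end), -c.start),
    )
    return best.name


def cluster_counts(
    alignments: Sequence[Alignment],
    clusters: IntervalSet,
) -> pd.Series:
    """Unique-read count per cluster from unique genome alignments."""
    trees = _cluster_trees(clusters)
    names = [iv.name for iv in clusters]
    counts = pd.Series(0, index=names, name="count")
    counts.index.name = "cluster"
    for aln in alignments:
        name = assign_cluster(aln, trees)
        if name is not None:
            counts[name] += 1
    return counts


def cluster_fold_ratio(
    mutant_counts: pd.Series,
    control_counts: pd.Series,
    mutant_normalizer: int,
    control_normalizer: int,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster (mutant_norm + pc) / (control_norm + pc) on per-million
    normalized counts, ranked ascending (most depleted first)."""
    if mutant_normalizer <= 0 or control_normalizer <= 0:
        raise ValueError("normalizers must be > 0")
    idx = control_counts.index.union(mutant_counts.index)
    ctrl = control_counts.reindex(idx, fill_value=0) * 1e6 / control_normalizer
    mut = mutant_counts.reindex(idx, fill_value=0) * 1e6 / mutant_normalizer
    ratio = (mut + pseudocount) / (ctrl + pseudocount)
    df = pd.DataFrame({"control_norm": ctrl, "mutant_norm": mut, "ratio": ratio})
    df.index.name = "cluster"
    return df.sort_values("ratio")


def cluster_coverage(
    alignments: Sequence[Alignment],
    cluster,
    normalizer: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-split per-base depth inside one cluster interval, scaled per
    million normalizer reads. Returns (plus_depth, minus_depth) over cluster
    coordinates."""
    scale = 1e6 / normalizer if normalizer else 1.0
    plus = np.zeros(len(cluster), dtype=float)
    minus = np.zeros(len(cluster), dtype=float)
    for aln in alignments:
        if aln.ref_id != cluster.chrom:
            continue
        lo = max(aln.start, cluster.start) - cluster.start
        hi = min(aln.end, cluster.end) - cluster.start
        if lo < hi:
            (plus if aln.strand == "+" else minus)[lo:hi] += 1
    return plus * scale, minus * scale


def write_bedgraph(depth: np.ndarray, chrom: str, offset: int, path: str) -> None:
    """Write a depth vector as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        i = 0
        n = len(depth)
        while i < n:
            j = i
            while j < n and depth[j] == depth[i]:
                j += 1
            if depth[i] != 0:
                fh.write(f"{chrom}\t{offset + i}\t{offset + j}\t{depth[i]:g}\n")
            i = j


def genic_region_counts(
    alignments: Sequence[Alignment],
    gene_regions: Mapping[str, GeneRegions],
) -> pd.DataFrame:
    """Sense/antisense counts per (gene, region) from unique alignments.

    Each alignment goes to the gene it overlaps most, then to the region
    (5'UTR/CDS/3'UTR) holding the majority of its aligned bases; region ties
    go to the more 3' region in transcription direction. Sense means the
    alignment strand equals the gene strand.
    """
    trees: dict[str, IntervalTree] = {}
    for gr in gene_regions.values():
        lo, hi = gr.span()
        trees.setdefault(gr.chrom, IntervalTree()).addi(lo, hi, gr)

    rows = {
        (gr.gene_id, region): {"sense": 0, "antisense": 0}
        for gr in gene_regions.values()
        for region in REGIONS
    }
    # 3'-ward preference for ties, in transcription direction: the
    # 5'UTR < CDS < 3'UTR order is intrinsic, independent of genomic strand
    rank = {FIVE_UTR: 0, CDS: 1, THREE_UTR: 2}

    for aln in alignments:
        tree = trees.get(aln.ref_id)
        if tree is None:
            continue
        hits = tree.overlap(aln.start, aln.end)
        if not hits:
            continue
        gr = max(
            (iv.data for iv in hits),
            key=lambda g: min(g.span()[1], aln.end) - max(g.span()[0], aln.start),
        )
        overlaps = {
            region: sum(
                iv.overlap(aln.start, aln.end)
                for iv in gr.regions
                if iv.feature_class == region
            )
            for region in REGIONS
        }
        best = max(REGIONS, key=lambda r: (overlaps[r], rank[r]))
        if overlaps[best] == 0:
            continue
        rel = "sense" if aln.strand == gr.strand else "antisense"
        rows[(gr.gene_id, best)][rel] += 1

    df = pd.DataFrame(
        [
            {"gene": g, "region": r, **cnt}
            for (g, r), cnt in sorted(rows.items())
        ]
    )
    return df


def sense_fraction(table: pd.DataFrame, region: str = THREE_UTR) -> tuple[pd.Series, float | None]:
    """Per-gene sense/(sense+antisense) for a region plus the aggregate over
    all genes; genes (or an aggregate) with zero reads report NaN/None."""
    sub = table[table["region"] == region].set_index("gene")
    denom = sub["sense"] + sub["antisense"]
    per_gene = sub["sense"] / denom.where(denom > 0)
    total = denom.sum()
    agg = float(sub["sense"].sum() / total) if total > 0 else None
    return per_gene, agg


def rpkm(counts: pd.Series, lengths: pd.Series, mapped_total: int) -> pd.Series:
    """Reads per kilobase of feature per million mapped reads."""
    if mapped_total <= 0:
        raise ValueError("mapped total must be > 0")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all feature lengths must be > 0")
    return counts / (lengths / 1e3) / (mapped_total / 1e6)
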