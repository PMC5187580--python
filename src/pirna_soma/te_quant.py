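"""Multi-mapping-aware transposon family quantification.

Follows the combine-all-instances counting model: a read increments a TE
family once if it aligns to *any* instance or consensus of that family at
least once, so multi-mapping reads are retained instead of discarded. A read
hitting several distinct families increments each of them (within-family
collapsing only). Small-RNA counts are normalized to unique alignments at
genotype-stable loci (cisNATs / structured loci); per-million scaling with a
pseudocount stands in for count-table-package normalization on the RNA-seq
side.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mini_align import align_all, select_unique
from .preprocess import ReadRecord
from .refio import SequenceDB

#: log2 of the 1.2-fold increase used to select heat-map families
HEATMAP_THRESHOLD = 0.263


def fold_change_threshold(fold: float = 1.2) -> float:
    """log2 of a fold cut-off (1.2-fold -> 0.263...)."""
    return math.log2(fold)


def count_te_families(
    reads: Sequence[ReadRecord],
    te_db: SequenceDB,
    family_map: Mapping[str, str] | None = None,
    v: int = 1,
) -> pd.Series:
    """Per-family read counts under the at-least-once rule.

    ``family_map`` sends each record id (instance or consensus) to its family
    name; by default each record is its own family. A read aligning to k > 1
    records of one family still contributes exactly +1 to that family.
    """
    if len(te_db) == 0:
        raise ValueError("empty TE catalog")
    if family_map is None:
        family_map = {rid: rid for rid in te_db.records}
    families = sorted(set(family_map.values()))
    counts = pd.Series(0, index=families, name="count")
    counts.index.name = "family"
    cache: dict[str, frozenset] = {}
    for read in reads:
        fams = cache.get(read.sequence)
        if fams is None:
            hits = align_all(read.read_id, read.sequence, te_db, v)
            fams = frozenset(family_map[a.ref_id] for a in hits)
            cache[read.sequence] = fams
        for fam in fams:
            counts[fam] += 1
    return counts


def norm_loci_unique_count(
    reads: Sequence[ReadRecord],
    norm_db: SequenceDB,
    v: int = 1,
) -> int:
    """Number of reads aligning uniquely to the normalization loci."""
    cache: dict[str, bool] = {}
    n = 0
    for read in reads:
        u = cache.get(read.sequence)
        if u is None:
            u = select_unique(align_all(read.read_id, read.sequence, norm_db, v)) is not None
            cache[read.sequence] = u
        n += u
    return n


def normalize_smrna(counts: pd.Series, norm_loci_unique: int) -> pd.Series:
    """Scale family counts to reads per million norm-loci-unique reads."""
    if norm_loci_unique <= 0:
        raise ValueError("norm-loci unique count must be > 0 (no silent fallback)")
    return counts * 1e6 / norm_loci_unique


def log2_fold_change(
    normalized_mutant: pd.Series,
    normalized_control: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-family log2((mutant + pc) / (control + pc)) on normalized counts."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    idx = normalized_control.index.union(normalized_mutant.index)
    ctrl = normalized_control.reindex(idx, fill_value=0.0)
    mut = normalized_mutant.reindex(idx, fill_value=0.0)
    fc = np.log2((mut + pseudocount) / (ctrl + pseudocount))
    return pd.DataFrame(
        {"control": ctrl, "mutant": mut, "log2fc": fc}
    ).rename_axis("family")


def select_heatmap_tes(
    rnaseq_fc: pd.DataFrame,
    smrna_fc: pd.DataFrame | None = None,
    threshold: float = HEATMAP_THRESHOLD,
) -> pd.DataFrame:
    """Families with RNA-seq log2FC strictly above the threshold (default
    0.263 = log2 of a 1.2-fold increase), paired with their small-RNA log2FC
    for the heat map."""
    sel = rnaseq_fc[rnaseq_fc["log2fc"] > threshold]
    out = pd.DataFrame({"rnaseq_log2fc": sel["log2fc"]})
    if smrna_fc is not None:
        out["smrna_log2fc"] = smrna_fc["log2fc"].reindex(out.index)
    return out.sort_values("rnaseq_log2fc", ascending=False)


def te_coverage_profile(
    reads: Sequence[ReadRecord],
    te_db: SequenceDB,
    ref_id: str,
    library_unique_total: int,
    v: int = 1,
) -> np.ndarray:
    """Per-position depth over one consensus from uniquely mapping reads,
    scaled per million library-unique reads. Reads with two or more hits on
    the consensus contribute nothing."""
    if library_unique_total <= 0:
        raise ValueError("library unique total must be > 0")
    if ref_id not in te_db.records:
        raise KeyError(f"no consensus record {ref_id!r}")
    single = SequenceDB(ref_id, {ref_id: te_db.records[ref_id]}, te_db.category)
    depth = np.zeros(len(te_db.records[ref_id]), dtype=float)
    for read in reads:
        aln = select_unique(align_all(read.read_id, read.sequence, single, v))
        if aln is not None:
            depth[aln.start : aln.end] += 1
    return depth * 1e6 / library_unique_total


def percent_change(normalized_control: float, normalized_mutant: float) -> float:
    """Percent decrease from control to mutant; negative means an increase."""
    if normalized_control <= 0:
        raise ValueError("control total must be > 0")
    return 100.0 * (normalized_control - normalized_mutant) / normalized_control
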