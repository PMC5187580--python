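"""piRNA signature statistics: size profiles, sense/antisense splits with
respect to transposon consensus sequences, and the first-position nucleotide
bias matrix behind the sequence-logo panels.

Reads are kept in the DNA alphabet throughout (the 1U bias of piRNAs appears
as a position-1 T in cDNA reads); information content is reported in bits,
R_i = 2 - H_i, without the small-sample correction a logo renderer would
apply (an ``ssc`` switch exists for parity with such renderers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mini_align import align_all, align_any, select_best
from .preprocess import ReadRecord
from .refio import SequenceDB

SIZE_MIN = 18
SIZE_MAX = 50

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def length_histogram(reads: Sequence[ReadRecord]) -> pd.Series:
    counts = pd.Series(0, index=range(SIZE_MIN, SIZE_MAX + 1), name="count")
    for r in reads:
        L = len(r.sequence)
        if SIZE_MIN <= L <= SIZE_MAX:
            counts[L] += 1
    counts.index.name = "length"
    return counts


def size_profile(
    reads: Sequence[ReadRecord],
    mirna_db: SequenceDB | Sequence[SequenceDB] | None,
    v: int = 1,
) -> pd.Series:
    """Read-length histogram over 18-50 nt after excluding reads aligning to
    the given database(s) (conventionally the miRNA set; pass a list to also
    exclude e.g. sno/tRNA, or None to exclude nothing)."""
    if mirna_db is None:
        dbs: list[SequenceDB] = []
    elif isinstance(mirna_db, SequenceDB):
        dbs = [mirna_db]
    else:
        dbs = list(mirna_db)
    cache: dict[str, bool] = {}
    kept = []
    for r in reads:
        ex = cache.get(r.sequence)
        if ex is None:
            ex = any(align_any(r.sequence, db, v) for db in dbs)
            cache[r.sequence] = ex
        if not ex:
            kept.append(r)
    return length_histogram(kept)


def split_te_reads(
    reads: Sequence[ReadRecord],
    te_db: SequenceDB,
    v: int = 1,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition TE-aligning reads into (sense, antisense) by the strand of
    each read's single best consensus hit; non-TE reads appear in neither."""
    sense: list[ReadRecord] = []
    antisense: list[ReadRecord] = []
    cache: dict[str, str | None] = {}
    for r in reads:
        strand = cache.get(r.sequence, "?")
        if strand == "?":
            best = select_best(align_all(r.read_id, r.sequence, te_db, v))
            strand = best.strand if best else None
            cache[r.sequence] = strand
        if strand == "+":
            sense.append(r)
        elif strand == "-":
            antisense.append(r)
    return sense, antisense


def te_size_profiles(
    reads: Sequence[ReadRecord],
    te_db: SequenceDB,
    v: int = 1,
) -> tuple[pd.Series, pd.Series]:
    """Size profiles of TE-mapping reads, split sense/antisense with respect
    to the consensus (+ hit = sense)."""
    sense, antisense = split_te_reads(reads, te_db, v)
    return length_histogram(sense), length_histogram(antisense)


@dataclass
class PositionFrequencyMatrix:
    """Base frequencies over positions 1..width of 5'-anchored reads.

    ``freqs`` is a 4 x width matrix (rows A, C, G, T); ``information`` holds
    per-position information content in bits, in [0, 2].
    """

    freqs: np.ndarray
    information: np.ndarray
    n_reads: int

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, index=list(BASES),
                          columns=range(1, self.width + 1))
        df.index.name = "base"
        return df


def first_position_bias(
    reads: Sequence[ReadRecord],
    size_window: tuple[int, int] = (23, 29),
    trim_to: int = 23,
    ssc: bool = False,
) -> PositionFrequencyMatrix:
    """Position frequency matrix of reads trimmed to a uniform 5'-anchored
    length (default 23 nt), restricted to a size window first.

    The 5' end is kept because the signature of interest (the position-1
    uracil of primary piRNAs) is 5'-anchored. ``ssc`` subtracts the
    small-sample correction e_n = 3/(2 ln2 n) from the information content.
    """
    lo, hi = size_window
    seqs = [r.sequence[:trim_to] for r in reads if lo <= len(r.sequence) <= hi]
    if not seqs:
        raise ValueError("no reads in the size window; cannot build a matrix")
    counts = np.zeros((4, trim_to), dtype=float)
    for seq in seqs:
        for pos, base in enumerate(seq):
            i = _BASE_IDX.get(base)
            if i is not None:  # N contributes to no base
                counts[i, pos] += 1
    col_totals = counts.sum(axis=0)
    col_totals[col_totals == 0] = 1.0
    freqs = counts / col_totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    if ssc:
        info = info - 3.0 / (2.0 * np.log(2) * len(seqs))
    info = np.clip(info, 0.0, 2.0)
    return PositionFrequencyMatrix(freqs=freqs, information=info, n_reads=len(seqs))
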