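"""Raw FASTQ to clean size-ranged reads: 3' adapter trimming, rRNA removal,
size selection. Every stage returns per-stage accounting so that read
conservation (input = kept + discarded) can be audited end to end."""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio import SeqIO

from .mini_align import align_any
from .refio import SequenceDB


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    trimmed: bool = False
    rrna_hit: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def _open_maybe_gz(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    with _open_maybe_gz(str(path)) as fh:
        return [
            ReadRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with _open_maybe_gz(str(path), "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> ReadRecord | None:
    """Remove the leftmost 3' adapter occurrence and everything 3' of it.

    An occurrence is the full adapter anywhere in the read, or a 3'-terminal
    prefix of the adapter of length >= ``min_overlap``, matched with mismatch
    fraction <= ``max_error_rate`` (floor(rate * overlap) mismatches
    allowed). Returns ``None`` when the insert would be empty (adapter at
    position 0). Reads already flagged ``trimmed`` are returned unchanged —
    trimming is applied once, which also makes it idempotent.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    if read.trimmed:
        return read
    seq = read.sequence
    for p in range(len(seq)):
        ov = min(len(adapter), len(seq) - p)
        if ov < min_overlap:
            break
        allowed = int(max_error_rate * ov)
        mm = 0
        for a, b in zip(seq[p : p + ov], adapter):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        if mm <= allowed:
            if p == 0:
                return None
            return replace(read, sequence=seq[:p], trimmed=True)
    return read


def trim_adapters(
    reads: Sequence[ReadRecord],
    adapter: str,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
    discard_untrimmed: bool = False,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Trim a whole library; untrimmed reads are retained but flagged unless
    ``discard_untrimmed`` is set."""
    kept: list[ReadRecord] = []
    stats = {"input": len(reads), "trimmed": 0, "untrimmed": 0,
             "discarded_empty": 0, "discarded_untrimmed": 0}
    for read in reads:
        out = trim_adapter(read, adapter, min_overlap, max_error_rate)
        if out is None:
            stats["discarded_empty"] += 1
            continue
        if out.trimmed:
            stats["trimmed"] += 1
            kept.append(out)
        elif discard_untrimmed:
            stats["discarded_untrimmed"] += 1
        else:
            stats["untrimmed"] += 1
            kept.append(out)
    stats["kept"] = len(kept)
    return kept, stats


def remove_rrna(
    reads: Sequence[ReadRecord],
    rrna_db: SequenceDB,
    max_mismatches: int = 1,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Drop every read aligning to any rRNA record (either strand,
    <= max_mismatches substitutions). An empty rRNA database is a hard
    error: silently filtering nothing would corrupt every downstream
    fraction."""
    if len(rrna_db) == 0:
        raise ValueError("rRNA database is empty; refusing to no-op filter")
    kept: list[ReadRecord] = []
    removed = 0
    cache: dict[str, bool] = {}
    for read in reads:
        hit = cache.get(read.sequence)
        if hit is None:
            hit = align_any(read.sequence, rrna_db, max_mismatches)
            cache[read.sequence] = hit
        if hit:
            removed += 1
        else:
            kept.append(read)
    stats = {"input": len(reads), "rrna_removed": removed, "kept": len(kept)}
    return kept, stats


def size_select(
    reads: Sequence[ReadRecord],
    min_len: int = 18,
    max_len: int = 50,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Keep reads with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [r for r in reads if min_len <= len(r.sequence) <= max_len]
    stats = {
        "input": len(reads),
        "too_short": sum(1 for r in reads if len(r.sequence) < min_len),
        "too_long": sum(1 for r in reads if len(r.sequence) > max_len),
        "kept": len(kept),
    }
    return kept, stats


def preprocess_library(
    reads: Sequence[ReadRecord],
    adapter: str,
    rrna_db: SequenceDB,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
    discard_untrimmed: bool = False,
    rrna_max_mismatches: int = 1,
    min_len: int = 18,
    max_len: int = 50,
) -> tuple[list[ReadRecord], list[dict]]:
    """Adapter trim -> rRNA removal -> size selection, with a per-stage
    accounting table (list of stage stats dicts)."""
    trimmed, s1 = trim_adapters(reads, adapter, min_overlap, max_error_rate,
                                discard_untrimmed)
    no_rrna, s2 = remove_rrna(trimmed, rrna_db, rrna_max_mismatches)
    sized, s3 = size_select(no_rrna, min_len, max_len)
    stages = [
        {"stage": "trim_adapter", **s1},
        {"stage": "remove_rrna", **s2},
        {"stage": "size_select", **s3},
    ]
    return sized, stages
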