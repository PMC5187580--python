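"""Substitution-only short-read alignment with all/best/unique reporting.

Re-implements the v-mismatch alignment model used throughout the analysis
(bowtie ``-v`` semantics): a read aligns to every reference window whose
Hamming distance to the read (plus strand) or to its reverse complement
(minus strand) is at most ``v``. Indels are never considered, and ``N`` in
either read or reference always counts as a mismatch (including N vs N).

Three reporting modes mirror the flag combinations the pipeline depends on:

* :func:`align_all` — every hit with <= v mismatches (``-v v -a``);
* :func:`select_best` — a single minimal-mismatch hit (``-v v -k 1 --best``),
  with the documented deterministic tie-break (ref id, then start, then +
  before -) replacing bowtie's pseudo-random one;
* :func:`select_unique` — the hit iff exactly one exists (``-v v -m 1``).

Implementation: pigeonhole seed-and-verify over a k-mer occurrence index of
the reference set (contract is the exhaustive window scan; the index is only
a speed-up, with a brute-force fallback for reads too short to seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .refio import SequenceDB

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_N = "N"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One placement of a read on the plus strand of a named reference.

    ``start``/``end`` are 0-based half-open reference coordinates; for
    ``strand == '-'`` the reverse complement of the read matches the window.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int

    def sort_key(self) -> tuple:
        return (self.ref_id, self.start, self.strand != "+")


def _hamming_leq(a: str, b: str, limit: int) -> int:
    """Mismatch count of equal-length strings, N always mismatching;
    returns limit + 1 early once the limit is exceeded."""
    if a == b and _N not in a:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == _N:
            mm += 1
            if mm > limit:
                return mm
    return mm


class _SeedIndex:
    """k-mer occurrence index of every reference window start."""

    def __init__(self, db: SequenceDB, k: int):
        self.k = k
        self.ref_ids = sorted(db.records)
        self.seqs = {rid: db.records[rid] for rid in self.ref_ids}
        index: dict[str, list[tuple[str, int]]] = {}
        for rid in self.ref_ids:
            seq = self.seqs[rid]
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((rid, pos))
        self.index = index


_SEED_K = 9  # supports v <= 1 for reads >= 18 nt via the pigeonhole split


def _get_index(db: SequenceDB, k: int = _SEED_K) -> _SeedIndex:
    idx = db._index_cache.get(k)
    if idx is None:
        idx = _SeedIndex(db, k)
        db._index_cache[k] = idx
    return idx


def _candidates_seeded(query: str, idx: _SeedIndex, v: int) -> set[tuple[str, int]]:
    """Candidate (ref, start) windows via the pigeonhole principle: split the
    query into v+1 disjoint k-mers; any true hit matches one exactly."""
    k = idx.k
    cands: set[tuple[str, int]] = set()
    n = len(query)
    for i in range(v + 1):
        off = i * k
        hits = idx.index.get(query[off : off + k])
        if not hits:
            continue
        for rid, pos in hits:
            start = pos - off
            if start >= 0 and start + n <= len(idx.seqs[rid]):
                cands.add((rid, start))
    return cands


def _candidates_brute(query: str, idx: _SeedIndex) -> Iterable[tuple[str, int]]:
    n = len(query)
    for rid in idx.ref_ids:
        for start in range(len(idx.seqs[rid]) - n + 1):
            yield (rid, start)


def align_all(read_id: str, seq: str, db: SequenceDB, v: int = 1) -> list[Alignment]:
    """Every alignment of ``seq`` against ``db`` with at most ``v``
    substitutions, on both strands, in deterministic order (ref id
    ascending, start ascending, + before -)."""
    if not 0 <= v <= 2:
        raise ValueError("v must be in 0..2")
    if not seq:
        raise ValueError("empty read sequence")
    idx = _get_index(db)
    n = len(seq)
    out: list[Alignment] = []
    seeded = n >= (v + 1) * idx.k
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        if seeded:
            cands = _candidates_seeded(query, idx, v)
        else:
            cands = _candidates_brute(query, idx)
        for rid, start in cands:
            mm = _hamming_leq(query, idx.seqs[rid][start : start + n], v)
            if mm <= v:
                out.append(Alignment(read_id, rid, start, start + n, strand, mm))
    out.sort(key=Alignment.sort_key)
    return out


def align_any(seq: str, db: SequenceDB, v: int = 1) -> bool:
    """True iff the read has at least one alignment with <= v mismatches.

    Same contract as ``align_all(...) != []`` but exits on the first hit.
    """
    if not seq:
        return False
    idx = _get_index(db)
    n = len(seq)
    seeded = n >= (v + 1) * idx.k
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        cands = (
            _candidates_seeded(query, idx, v) if seeded else _candidates_brute(query, idx)
        )
        for rid, start in cands:
            if _hamming_leq(query, idx.seqs[rid][start : start + n], v) <= v:
                return True
    return False


def select_best(alignments: Sequence[Alignment]) -> Alignment | None:
    """Single best hit: minimal mismatches, ties broken by ref id, then
    start, then + before - (deterministic stand-in for ``-k 1 --best``)."""
    if not alignments:
        return None
    return min(alignments, key=lambda a: (a.mismatches, *a.sort_key()))


def select_unique(alignments: Sequence[Alignment]) -> Alignment | None:
    """The hit iff exactly one reportable alignment exists (``-m 1``):
    reads with two or more hits are suppressed entirely."""
    if len(alignments) == 1:
        return alignments[0]
    return None


def count_hits(seq: str, db: SequenceDB, v: int = 1, cap: int = 2) -> int:
    """Number of alignments, early-exiting once ``cap`` hits are found.

    ``count_hits(seq, db, v, cap=2)`` is what unique-mode filtering needs:
    0, 1, or "2 = many".
    """
    idx = _get_index(db)
    n = len(seq)
    if not seq:
        return 0
    seeded = n >= (v + 1) * idx.k
    found = 0
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        cands = (
            _candidates_seeded(query, idx, v) if seeded else _candidates_brute(query, idx)
        )
        for rid, start in cands:
            if _hamming_leq(query, idx.seqs[rid][start : start + n], v) <= v:
                found += 1
                if found >= cap:
                    return found
    return found


def write_tsv(alignments: Iterable[Alignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tstart\tend\tstrand\tmismatches\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.ref_id}\t{a.start}\t{a.end}\t{a.strand}\t{a.mismatches}\n"
            )


def write_sam(
    alignments: Iterable[Alignment],
    db: SequenceDB,
    reads: dict[str, str],
    path: str,
) -> None:
    """Minimal SAM output (QNAME/FLAG/RNAME/POS/CIGAR=<L>M + NM tag)."""
    import pysam

    ref_ids = sorted(db.records)
    header = pysam.AlignmentHeader.from_references(
        ref_ids, [len(db.records[r]) for r in ref_ids]
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seq = reads[a.read_id]
            seg.query_sequence = revcomp(seq) if a.strand == "-" else seq
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = ref_ids.index(a.ref_id)
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.end - a.start}M"
            seg.set_tag("NM", a.mismatches)
            out.write(seg)
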