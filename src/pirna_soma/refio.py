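"""Reference sequence and annotation I/O.

Owns the coordinate conventions the rest of the package relies on: all
intervals are stored 0-based half-open on the forward strand; BED is read
natively, GFF3 is converted from 1-based closed at the boundary and
converted back on write.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {
        "genome",
        "sno_tRNA",
        "miRNA",
        "TE_consensus",
        "exon",
        "intergenic",
        "rRNA",
        "norm_loci",
    }
)

_VALID_BASES = frozenset("ACGTN")

FIVE_UTR = "five_prime_UTR"
CDS = "CDS"
THREE_UTR = "three_prime_UTR"


@dataclass
class SequenceDB:
    """A named set of reference sequences belonging to one compartment.

    Sequences are uppercase A/C/G/T/N. ``category`` declares the role the
    set plays in the pipeline (genome, miRNA, TE_consensus, ...).
    """

    name: str
    records: dict[str, str]
    category: str
    # lazy per-(k, ref) seed index managed by mini_align; not part of identity
    _index_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown SequenceDB category {self.category!r}")
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"record {rid!r} has non-ACGTN character {seq[pos]!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "."
    name: str = "."
    feature_class: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class IntervalSet:
    """Intervals in 0-based half-open genome coordinates."""

    name: str
    intervals: list[Interval]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def validate_against(self, genome: SequenceDB) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome.records:
                raise ValueError(
                    f"interval {iv.name!r} references unknown chrom {iv.chrom!r}"
                )
            if iv.end > len(genome.records[iv.chrom]):
                raise ValueError(
                    f"interval {iv.name!r} extends past end of {iv.chrom!r}"
                )

    def validate_nonoverlapping(self) -> None:
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping intervals on {chrom}: "
                        f"{a.name} [{a.start},{a.end}) and {b.name} [{b.start},{b.end})"
                    )


@dataclass
class GeneRegions:
    """5'UTR / CDS / 3'UTR intervals of one gene, in genome coordinates.

    Region labels are assigned in transcription direction: for a minus-strand
    gene the 3'UTR is the leftmost genomic block.
    """

    gene_id: str
    chrom: str
    strand: str
    regions: list[Interval]  # feature_class in {five_prime_UTR, CDS, three_prime_UTR}

    def region_length(self, label: str) -> int:
        return sum(len(iv) for iv in self.regions if iv.feature_class == label)

    def span(self) -> tuple[int, int]:
        return min(iv.start for iv in self.regions), max(iv.end for iv in self.regions)


def load_fasta(path: str | os.PathLike, category: str, name: str | None = None) -> SequenceDB:
    """Load a FASTA file into a :class:`SequenceDB`.

    Record ids are the first whitespace-delimited token of each header;
    sequences are case-folded to uppercase. Duplicate ids, empty files and
    non-ACGTN characters are hard errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceDB(name=name or os.path.basename(str(path)), records=records,
                      category=category)


def write_fasta(db: SequenceDB | Mapping[str, str], path: str | os.PathLike) -> None:
    records = db.records if isinstance(db, SequenceDB) else db
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_intervals(
    path: str | os.PathLike,
    fmt: str,
    genome: SequenceDB | None = None,
    name: str | None = None,
) -> IntervalSet:
    """Load BED6 (kept 0-based half-open) or GFF3 (converted from 1-based
    closed) into an :class:`IntervalSet`."""
    fmt = fmt.upper()
    if fmt == "BED":
        ivs = _load_bed(path)
    elif fmt == "GFF":
        ivs = _load_gff(path)
    else:
        raise ValueError(f"unsupported interval format {fmt!r}")
    iset = IntervalSet(name=name or os.path.basename(str(path)), intervals=ivs)
    if genome is not None:
        iset.validate_against(genome)
    return iset


def _load_bed(path: str | os.PathLike) -> list[Interval]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype=str,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    ivs = []
    for row in df.itertuples(index=False):
        ivs.append(
            Interval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand if row.strand in {"+", "-"} else ".",
                name=row.name if isinstance(row.name, str) else ".",
            )
        )
    return ivs


def _load_gff(path: str | os.PathLike) -> list[Interval]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    ivs = []
    for feat in db.all_features(order_by=("seqid", "start")):
        start0 = feat.start - 1  # GFF is 1-based closed
        if feat.end <= start0:
            raise ValueError(
                f"feature {feat.id} has end <= start after conversion"
            )
        parent = feat.attributes.get("Parent", [None])[0]
        fid = feat.attributes.get("ID", [None])[0]
        ivs.append(
            Interval(
                chrom=feat.seqid,
                start=start0,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
                name=parent or fid or ".",
                feature_class=feat.featuretype,
            )
        )
    return ivs


def write_bed(iset: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t.\t{iv.strand}\n"
            )


def write_gff(iset: IntervalSet, path: str | os.PathLike, source: str = "pirna_soma") -> None:
    """Write features back out as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in iset:
            ftype = iv.feature_class if iv.feature_class != "." else "region"
            if ftype in {"exon", "CDS"}:
                attrs = f"Parent={iv.name}"
            else:
                attrs = f"ID={iv.name}"
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def build_gene_regions(gene_models: IntervalSet) -> dict[str, GeneRegions]:
    """Derive 5'UTR / CDS / 3'UTR blocks from exon and CDS features.

    UTRs are the exonic sequence outside the CDS genomic span, labelled in
    transcription direction. One principal transcript per gene: the first
    encountered set of exon/CDS features under a gene name. Genes without a
    CDS are skipped with a warning.
    """
    exons: dict[str, list[Interval]] = {}
    cdss: dict[str, list[Interval]] = {}
    order: list[str] = []
    for iv in gene_models:
        if iv.feature_class == "exon":
            exons.setdefault(iv.name, []).append(iv)
            if iv.name not in order:
                order.append(iv.name)
        elif iv.feature_class == "CDS":
            cdss.setdefault(iv.name, []).append(iv)
            if iv.name not in order:
                order.append(iv.name)

    out: dict[str, GeneRegions] = {}
    for gene in order:
        if gene not in exons:
            continue
        if gene not in cdss:
            logger.warning("gene %s has no CDS; skipped (non-coding)", gene)
            continue
        exon_ivs = sorted(exons[gene], key=lambda i: i.start)
        chrom = exon_ivs[0].chrom
        strand = exon_ivs[0].strand
        cds_lo = min(iv.start for iv in cdss[gene])
        cds_hi = max(iv.end for iv in cdss[gene])
        left_label = FIVE_UTR if strand == "+" else THREE_UTR
        right_label = THREE_UTR if strand == "+" else FIVE_UTR
        regions: list[Interval] = []
        for ex in exon_ivs:
            for lo, hi, label in (
                (ex.start, min(ex.end, cds_lo), left_label),
                (max(ex.start, cds_lo), min(ex.end, cds_hi), CDS),
                (max(ex.start, cds_hi), ex.end, right_label),
            ):
                if lo < hi:
                    regions.append(
                        Interval(chrom, lo, hi, strand, gene, label)
                    )
        out[gene] = GeneRegions(gene_id=gene, chrom=chrom, strand=strand,
                                regions=regions)
    return out


def extract_sequence(genome: SequenceDB, iv: Interval) -> str:
    """Forward-strand genome sequence under an interval."""
    return genome.records[iv.chrom][iv.start : iv.end]
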