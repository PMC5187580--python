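"""Sequential (priority-ordered) genomic-compartment classification.

Genome-aligning reads are assigned to the first compartment database they
align to, in the fixed order sno+tRNA -> miRNA -> TE -> exon -> intergenic;
reads aligning to the genome but to no compartment database fall into an
explicit ``unassigned`` bucket so that counts always partition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .mini_align import align_any
from .preprocess import ReadRecord
from .refio import SequenceDB

COMPARTMENT_ORDER = ("sno_tRNA", "miRNA", "TE", "exon", "intergenic")

UNASSIGNED = "unassigned"

# compartment label carried by each SequenceDB category
_LABEL_FOR_CATEGORY = {
    "sno_tRNA": "sno_tRNA",
    "miRNA": "miRNA",
    "TE_consensus": "TE",
    "exon": "exon",
    "intergenic": "intergenic",
}


@dataclass(frozen=True)
class CompartmentAssignment:
    read_id: str
    compartment: str
    length: int


def assign_compartments(
    reads: Sequence[ReadRecord],
    genome_db: SequenceDB,
    compartment_dbs: Sequence[SequenceDB],
    v: int = 1,
) -> tuple[list[CompartmentAssignment], dict[str, int]]:
    """Classify genome-aligning reads into the first compartment they hit.

    ``compartment_dbs`` must supply all five compartments in priority order.
    Reads with no genome alignment (<= v mismatches, either strand) are
    excluded from classification and reported in the stats.
    """
    labels = [_LABEL_FOR_CATEGORY.get(db.category) for db in compartment_dbs]
    if sorted(filter(None, labels)) != sorted(COMPARTMENT_ORDER):
        raise ValueError(
            "need exactly one compartment database for each of "
            f"{COMPARTMENT_ORDER} (classification follows the given order)"
        )
    assignments: list[CompartmentAssignment] = []
    cache: dict[str, str | None] = {}
    n_unaligned = 0
    for read in reads:
        seq = read.sequence
        comp = cache.get(seq, "?")
        if comp == "?":
            if not align_any(seq, genome_db, v):
                comp = None
            else:
                comp = UNASSIGNED
                for label, db in zip(labels, compartment_dbs):
                    if align_any(seq, db, v):
                        comp = label
                        break
            cache[seq] = comp
        if comp is None:
            n_unaligned += 1
        else:
            assignments.append(CompartmentAssignment(read.read_id, comp, len(seq)))
    stats = {
        "input": len(reads),
        "genome_unaligned": n_unaligned,
        "classified": len(assignments),
    }
    return assignments, stats


def composition_summary(
    assignments: Sequence[CompartmentAssignment],
    size_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-compartment counts and fractions, optionally restricted to a read
    length window (e.g. the 23-29 nt piRNA window). Fractions are over all
    classified reads in the window and sum to 1."""
    if size_window is not None:
        lo, hi = size_window
        assignments = [a for a in assignments if lo <= a.length <= hi]
    if not assignments:
        raise ValueError("no classified reads in the requested window")
    counts = {label: 0 for label in (*COMPARTMENT_ORDER, UNASSIGNED)}
    for a in assignments:
        counts[a.compartment] += 1
    total = len(assignments)
    df = pd.DataFrame(
        {
            "compartment": list(counts),
            "count": list(counts.values()),
        }
    )
    df["fraction"] = df["count"] / total
    return df
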