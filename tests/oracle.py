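"""Independent brute-force alignment oracle used to check the aligner.

Deliberately shares no code with the package's seed-and-verify
implementation: every reference window on both strands is scanned with a
vectorized Hamming comparison (N always counts as a mismatch, including
N vs N).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = str.maketrans("ACGTN", "TGCAN")
_N = ord("N")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def align_all_bruteforce(
    read: str, refs: dict[str, str], v: int
) -> set[tuple[str, int, str, int]]:
    """All (ref_id, start, strand, mismatches) with mismatches <= v."""
    hits: set[tuple[str, int, str, int]] = set()
    n = len(read)
    for rid, ref in refs.items():
        if len(ref) < n:
            continue
        ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        windows = sliding_window_view(ref_arr, n)
        for strand, query in (("+", read), ("-", rc(read))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            mm = ((windows != q) | (windows == _N) | (q == _N)).sum(axis=1)
            for start in np.nonzero(mm <= v)[0]:
                hits.add((rid, int(start), strand, int(mm[start])))
    return hits
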