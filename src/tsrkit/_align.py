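"""Low-level sequence scanning helpers shared across modules.

Everything here works on the internal DNA alphabet (uppercase, U already
mapped to T). References in this toolkit are tiny (tRNAs, trailers, toy
genomes), so placements are found with vectorised sliding-window mismatch
scans; indel-tolerant placement uses edlib's infix (HW) mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = str.maketrans("ACGTUN", "TGCAAN")

VALID_BASES = frozenset("ACGTUN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def scan_mismatch(query: str, ref: str, max_mm: int):
    """All ungapped placements of ``query`` inside ``ref`` with <= max_mm mismatches.

    Returns a list of ``(start0, mismatch_offsets)`` where ``start0`` is the
    0-based offset of the placement in ``ref`` and ``mismatch_offsets`` are
    0-based offsets within the query.
    """
    m, L = len(query), len(ref)
    if m == 0 or m > L:
        return []
    q = _encode(query)
    windows = sliding_window_view(_encode(ref), m)
    neq = windows != q
    counts = neq.sum(axis=1)
    hits = np.nonzero(counts <= max_mm)[0]
    return [(int(s), np.nonzero(neq[s])[0].tolist()) for s in hits]


def has_match(query: str, refs, max_mm: int, both_strands: bool = False) -> bool:
    """True iff ``query`` occurs as an ungapped substring of any reference
    with at most ``max_mm`` mismatches."""
    queries = [query]
    if both_strands:
        queries.append(revcomp(query))
    for ref in refs:
        for q in queries:
            if scan_mismatch(q, ref, max_mm):
                return True
    return False


def prefix_match_lengths(query: str, ref: str, max_mm: int) -> int:
    """Length of the longest prefix of ``query`` matching somewhere in ``ref``
    with <= max_mm mismatches, not ending in a mismatch.

    Trailing mismatches are trimmed so that a chance edit cannot extend a
    matching arm past its true boundary.
    """
    m, L = len(query), len(ref)
    if m == 0 or L == 0:
        return 0
    q = _encode(query)
    r = _encode(ref)
    best = 0
    for s in range(L):
        span = min(m, L - s)
        if span <= best:
            continue
        neq = q[:span] != r[s : s + span]
        cum = np.cumsum(neq)
        ok = np.nonzero(cum <= max_mm)[0]
        if ok.size == 0:
            continue
        k = int(ok[-1]) + 1  # longest prefix within budget
        # trim trailing mismatches
        while k > 0 and neq[k - 1]:
            k -= 1
        best = max(best, k)
    return best


def suffix_match_length(query: str, ref: str, max_mm: int) -> int:
    """Length of the longest suffix of ``query`` matching inside ``ref``."""
    return prefix_match_lengths(query[::-1], ref[::-1], max_mm)
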