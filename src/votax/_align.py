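"""Semi-global edit distance with IUPAC-aware substitution costs.

The query is aligned end-to-end; the target contributes a free-standing
window (both target ends are unpenalized).  Bases are encoded as 4-bit
sets over {A, C, G, T} so degenerate symbols cost nothing to compare:
a substitution is free iff the two base sets intersect.
"""

from __future__ import annotations

import numpy as np

# Bitmask encoding: A=1, C=2, G=4, T=8.
IUPAC_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as an array of IUPAC base-set masks."""
    try:
        return np.array([IUPAC_MASKS[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide symbol {exc.args[0]!r}") from None


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def semiglobal_distance(query: str, target: str) -> int:
    """Minimum edit distance of ``query`` against any window of ``target``.

    Substitutions between IUPAC-compatible symbols are free; incompatible
    substitutions, insertions and deletions each cost 1.  The empty window
    is admissible, so the result never exceeds ``len(query)``.
    """
    q = encode(query)
    t = encode(target)
    if q.size == 0:
        raise ValueError("query must be non-empty")
    n = t.size
    j = np.arange(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)  # row 0: free left target end
    temp = np.empty(n + 1, dtype=np.int64)
    for i in range(1, q.size + 1):
        sub = (q[i - 1] & t) == 0  # 1 where incompatible
        temp[0] = i
        np.minimum(prev[:-1] + sub, prev[1:] + 1, out=temp[1:])
        # D[i][j] = min(temp[j], D[i][j-1] + 1) == j + min_{k<=j}(temp[k] - k)
        prev = np.minimum.accumulate(temp - j) + j
        temp = np.empty(n + 1, dtype=np.int64)
    return int(prev.min())


def hamming_window_distance(query: str, target: str) -> int:
    """Best IUPAC-aware mismatch count of ``query`` over all gapless windows.

    Requires ``len(target) >= len(query)``.
    """
    q = encode(query)
    t = encode(target)
    m, n = q.size, t.size
    if m == 0:
        raise ValueError("query must be non-empty")
    if n < m:
        raise ValueError("target shorter than query in gapless mode")
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mismatches = ((windows & q) == 0).sum(axis=1)
    return int(mismatches.min())
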