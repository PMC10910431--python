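"""Textbook quadratic dynamic-programming Levenshtein oracle.

Independent of the alignment backend used by the package: implements the
classic unit-cost edit-distance recurrence row by row.  The horizontal
(insertion) dependency is resolved in closed form — with unit costs,
cur[j] = min_k<=j (cur0[k] + (j - k)) — so rows can be computed with numpy
while remaining the plain DP recurrence.
"""

from __future__ import annotations

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Unit-cost edit distance between two strings (quadratic DP)."""
    if len(a) < len(b):  # iterate over the longer string, keep rows short
        a, b = b, a
    bj = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    m = bj.size
    prev = np.arange(m + 1)
    idx = np.arange(m + 1)
    for i, ch in enumerate(a.encode("ascii"), start=1):
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = i
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (bj != ch))
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])
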