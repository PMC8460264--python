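"""Numba kernel for semi-global read-vs-reference alignment.

Scoring: match +1, mismatch -1, gap -2 (linear). The read is aligned
globally from its 5' end (products are anchored at the primer), but gaps in
the read past the 3' end of its alignment are free: a short product is a
truncation, not a run of deletions.

Tie-breaking: among equal-scoring alignments, the one with the fewest gap
columns wins (mismatches are preferred over indel pairs), implemented as a
lexicographic objective — the DP maximizes score * K - gap_columns with K
larger than any possible gap count, so the secondary term can never
override the primary score. Remaining ties resolve during traceback
(diagonal, then deletion, then insertion, pushing gaps toward the 5' end)
and the alignment ends at the smallest reference position achieving the
optimum, so trailing ambiguity resolves to truncation. The result is fully
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2

# op codes emitted by the kernel
OP_MATCH = 0
OP_MISMATCH = 1
OP_DELETION = 2
OP_INSERTION = 3


@njit(cache=True)
def _align_kernel(read: np.ndarray, ref: np.ndarray):
    """Return (score, end_ref_pos, op_codes, ref_pos, read_idx).

    read/ref are uint8 code arrays. Ops are in alignment order; for
    insertions ref_pos is the reference position the inserted base follows
    and read_idx the 0-based read index of the inserted base.
    """
    m = read.shape[0]
    n = ref.shape[0]
    # composite objective: primary score scaled by K, minus 1 per gap column
    K = np.int64(2 * (m + n) + 2)
    s_match = MATCH * K
    s_mismatch = MISMATCH * K
    s_gap = GAP * K - 1
    D = np.empty((m + 1, n + 1), dtype=np.int64)
    for j in range(n + 1):
        D[0, j] = s_gap * j
    for i in range(1, m + 1):
        D[i, 0] = s_gap * i
        ri = read[i - 1]
        for j in range(1, n + 1):
            sub = s_match if ri == ref[j - 1] else s_mismatch
            best = D[i - 1, j - 1] + sub
            up = D[i - 1, j] + s_gap
            if up > best:
                best = up
            left = D[i, j - 1] + s_gap
            if left > best:
                best = left
            D[i, j] = best

    # free 3'-terminal reference gap: stop at the smallest j with max score
    jend = 0
    best_final = D[m, 0]
    for j in range(1, n + 1):
        if D[m, j] > best_final:
            best_final = D[m, j]
            jend = j
    # recover the primary score: composite = K*score - gaps, 0 <= gaps < K
    score = -((-best_final) // K)

    ops_code = np.empty(m + n, dtype=np.int8)
    ops_ref = np.empty(m + n, dtype=np.int32)
    ops_read = np.empty(m + n, dtype=np.int32)
    k = m + n  # fill backwards
    i = m
    j = jend
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = s_match if read[i - 1] == ref[j - 1] else s_mismatch
            if D[i, j] == D[i - 1, j - 1] + sub:
                k -= 1
                ops_code[k] = OP_MATCH if sub == s_match else OP_MISMATCH
                ops_ref[k] = j
                ops_read[k] = i - 1
                i -= 1
                j -= 1
                continue
        if j > 0 and D[i, j] == D[i, j - 1] + s_gap:
            k -= 1
            ops_code[k] = OP_DELETION
            ops_ref[k] = j
            ops_read[k] = -1
            j -= 1
            continue
        k -= 1
        ops_code[k] = OP_INSERTION
        ops_ref[k] = j
        ops_read[k] = i - 1
        i -= 1
    return score, jend, ops_code[k:], ops_ref[k:], ops_read[k:]


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGU"):
    _CODE[_b] = _i


def encode(residues: str) -> np.ndarray:
    """Encode an RNA string as a uint8 array (A=0, C=1, G=2, U=3)."""
    arr = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-RNA character in {residues!r}")
    return arr
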