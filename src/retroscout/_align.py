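"""Dynamic-programming alignment kernels shared by the scanning modules.

Two primitives are implemented here, by hand, because they are the package's
BLAST/Clustal substitutes:

* ``global_identity`` - Needleman-Wunsch with linear gap cost, used for the
  >95%-identity family definition (match +1, mismatch -1, gap -2); identity is
  matches / aligned columns excluding terminal gaps.
* ``banded_sw`` - banded local Smith-Waterman with affine gaps (match +1,
  mismatch -1, gap open -5, extend -1), used to extend k-mer seed chains in the
  direct-repeat (LTR) and genome-copy scanners.

Tie-breaks are fixed (diagonal > gap-in-target > gap-in-query) so outputs are
deterministic and testable against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}

NEG_INF = -1_000_000_000


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class LocalAlignment:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap):
    m, n = len(a), len(b)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    P = np.empty((m + 1, n + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    H[0, 0] = 0
    for i in range(1, m + 1):
        H[i, 0] = i * gap
        P[i, 0] = 1
    for j in range(1, n + 1):
        H[0, j] = j * gap
        P[0, j] = 2
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            sub = match if ai == b[j - 1] else mismatch
            d = H[i - 1, j - 1] + sub
            u = H[i - 1, j] + gap
            l = H[i, j - 1] + gap
            best = d
            ptr = 0
            if u > best:
                best = u
                ptr = 1
            if l > best:
                best = l
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return H, P


def nw_align(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Global alignment; returns (score, matches, columns_excluding_terminal_gaps).

    N never counts as a match. Ties prefer diagonal, then a-gap, then b-gap.
    """
    ea, eb = encode(a), encode(b)
    H, P = _nw_fill(ea, eb, match, mismatch, gap)
    i, j = len(ea), len(eb)
    cols = []  # 0 = aligned pair, 1/2 = gap column
    pairs = []
    while i > 0 or j > 0:
        p = P[i, j]
        if i > 0 and j > 0 and p == 0:
            is_match = ea[i - 1] == eb[j - 1] and a[i - 1] != "N"
            cols.append(0)
            pairs.append(is_match)
            i -= 1
            j -= 1
        elif i > 0 and (j == 0 or p == 1):
            cols.append(1)
            pairs.append(False)
            i -= 1
        else:
            cols.append(2)
            pairs.append(False)
            j -= 1
    cols.reverse()
    pairs.reverse()
    # trim terminal gap columns
    first = 0
    last = len(cols)
    while first < last and cols[first] != 0:
        first += 1
    while last > first and cols[last - 1] != 0:
        last -= 1
    matches = sum(pairs[first:last])
    n_cols = last - first
    return int(H[len(ea), len(eb)]), matches, n_cols


def global_identity(a: str, b: str, match: int = 1, mismatch: int = -1,
                    gap: int = -2) -> float:
    _, matches, n_cols = nw_align(a, b, match, mismatch, gap)
    return matches / n_cols if n_cols else 0.0


@njit(cache=True)
def _banded_sw_fill(a, b, dlo, dhi, match, mismatch, gap_open, gap_extend):
    m, n = len(a), len(b)
    W = dhi - dlo + 1
    neg = NEG_INF
    M = np.full((m + 1, W), neg, dtype=np.int32)
    X = np.full((m + 1, W), neg, dtype=np.int32)  # gap in b (consumes a)
    Y = np.full((m + 1, W), neg, dtype=np.int32)  # gap in a (consumes b)
    PM = np.zeros((m + 1, W), dtype=np.uint8)  # 0 start, 1 M, 2 X, 3 Y
    PX = np.zeros((m + 1, W), dtype=np.uint8)
    PY = np.zeros((m + 1, W), dtype=np.uint8)
    best = 0
    bi = -1
    bk = -1
    for i in range(0, m + 1):
        for k in range(W):
            j = i + dlo + k
            if j < 0 or j > n:
                continue
            if i == 0 or j == 0:
                if i == 0 and j == 0:
                    M[i, k] = 0
                continue
            an = a[i - 1]
            bn = b[j - 1]
            sub = match if (an == bn and an != 78) else mismatch  # 78 = 'N'
            # M state
            prev_best = 0
            ptr = 0
            pm = M[i - 1, k]
            if pm > prev_best:
                prev_best = pm
                ptr = 1
            px = X[i - 1, k]
            if px > prev_best:
                prev_best = px
                ptr = 2
            py = Y[i - 1, k]
            if py > prev_best:
                prev_best = py
                ptr = 3
            M[i, k] = prev_best + sub
            PM[i, k] = ptr
            # X state: gap in b, predecessor at (i-1, j) -> band col k+1
            if k + 1 < W:
                from_m = M[i - 1, k + 1] + gap_open
                from_x = X[i - 1, k + 1] + gap_extend
                if from_m >= from_x:
                    X[i, k] = from_m
                    PX[i, k] = 1
                else:
                    X[i, k] = from_x
                    PX[i, k] = 2
            # Y state: gap in a, predecessor at (i, j-1) -> band col k-1
            if k - 1 >= 0:
                from_m = M[i, k - 1] + gap_open
                from_y = Y[i, k - 1] + gap_extend
                if from_m >= from_y:
                    Y[i, k] = from_m
                    PY[i, k] = 1
                else:
                    Y[i, k] = from_y
                    PY[i, k] = 3
            if M[i, k] > best:
                best = M[i, k]
                bi = i
                bk = k
    return M, X, Y, PM, PX, PY, best, bi, bk


def banded_sw(
    a: str | np.ndarray,
    b: str | np.ndarray,
    dlo: int,
    dhi: int,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> LocalAlignment | None:
    """Best local alignment with diagonal offset j-i restricted to [dlo, dhi].

    The first residue of a gap costs ``gap_open``; each further residue costs
    ``gap_extend``. Returns None when no positive-scoring alignment exists.
    """
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    dlo = max(dlo, -len(ea))
    dhi = min(dhi, len(eb))
    if dlo > dhi:
        return None
    M, X, Y, PM, PX, PY, best, bi, bk = _banded_sw_fill(
        ea, eb, dlo, dhi, match, mismatch, gap_open, gap_extend
    )
    if best <= 0 or bi < 0:
        return None
    # traceback from (bi, bk) in state M
    i, k = bi, bk
    state = 1  # 1 M, 2 X, 3 Y
    matches = 0
    columns = 0
    end_i, end_j = bi, bi + dlo + bk
    while True:
        j = i + dlo + k
        if state == 1:
            ptr = PM[i, k]
            if ea[i - 1] == eb[j - 1] and ea[i - 1] != ord("N"):
                matches += 1
            columns += 1
            i -= 1
            # k unchanged for diagonal move
            if ptr == 0:
                break
            state = ptr
        elif state == 2:
            ptr = PX[i, k]
            columns += 1
            i -= 1
            k += 1
            state = ptr
        else:
            ptr = PY[i, k]
            columns += 1
            k -= 1
            state = ptr
    start_i, start_j = i, i + dlo + k
    return LocalAlignment(
        score=int(best),
        a_start=start_i,
        a_end=end_i,
        b_start=start_j,
        b_end=end_j,
        matches=matches,
        columns=columns,
    )
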