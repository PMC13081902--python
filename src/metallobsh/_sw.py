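"""Numba-accelerated affine-gap Smith-Waterman kernel for the read-search hot path.

The general-purpose alignment API lives in :mod:`metallobsh.alignment`; this
kernel exists because the translated search aligns every read frame against
every prefilter-passing database entry, a volume at which per-call overhead
dominates. It implements the same scoring contract (gap of length L costs
open + L*extend; deterministic diagonal > up > left traceback) and is
cross-checked against the alignment module in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .alignment import SubstitutionMatrix, default_matrix

_NEG = -1e18


@njit(cache=True)
def _sw_kernel(q, t, sub, go, ge, amb):  # pragma: no cover - exercised via wrapper
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] - ge
            alt = H[i, j - 1] - go - ge
            if alt > e:
                e = alt
            E[i, j] = e
            f = F[i - 1, j] - ge
            alt = H[i - 1, j] - go - ge
            if alt > f:
                f = alt
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback (diagonal > up > left on ties)
    i = bi
    j = bj
    n_ident = 0
    n_mismatch = 0
    aln_len = 0
    gap_opens = 0
    state = 0  # 0 = H, 1 = F (vertical, query residue vs gap), 2 = E (horizontal)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] <= 0.0:
                break
            diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if H[i, j] == diag:
                aln_len += 1
                if q[i - 1] == t[j - 1] and amb[q[i - 1]] == 0:
                    n_ident += 1
                elif q[i - 1] != t[j - 1]:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            elif H[i, j] == E[i, j]:
                state = 2
            else:  # numerically impossible; bail out defensively
                break
        elif state == 1:
            aln_len += 1
            from_open = H[i - 1, j] - go - ge
            if F[i, j] == from_open:
                gap_opens += 1
                state = 0
            i -= 1
        else:
            aln_len += 1
            from_open = H[i, j - 1] - go - ge
            if E[i, j] == from_open:
                gap_opens += 1
                state = 0
            j -= 1
    return best, n_ident, aln_len, n_mismatch, gap_opens, i + 1, bi, j + 1, bj


class SWEngine:
    """Encodes sequences once and runs the jitted kernel.

    Exposes scores, identity counts and 1-based alignment coordinates
    identical in contract to :func:`metallobsh.alignment.local_align`.
    """

    def __init__(
        self,
        matrix: SubstitutionMatrix | None = None,
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
    ):
        matrix = matrix or default_matrix()
        alphabet = matrix.alphabet
        self.alphabet = alphabet
        self._code = np.full(256, alphabet.index("X") if "X" in alphabet else 0, dtype=np.uint8)
        for idx, ch in enumerate(alphabet):
            self._code[ord(ch)] = idx
        size = len(alphabet)
        self._sub = np.empty((size, size), dtype=np.float64)
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                self._sub[i, j] = matrix.score(a, b)
        self._amb = np.zeros(size, dtype=np.uint8)
        for ch in "X*":
            if ch in alphabet:
                self._amb[alphabet.index(ch)] = 1
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)

    def encode(self, seq: str) -> np.ndarray:
        return self._code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

    def align(self, q: np.ndarray, t: np.ndarray):
        """(score, n_ident, aln_len, n_mismatch, gap_opens, qs, qe, ts, te)."""
        return _sw_kernel(q, t, self._sub, self.gap_open, self.gap_extend, self._amb)
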