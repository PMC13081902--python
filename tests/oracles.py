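"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and library code
paths: alignments are scored by exhaustive enumeration of alignment paths,
rank statistics by explicit rank-then-Pearson arithmetic, and the BH
adjustment by the hand-written step-up recursion.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def enumerate_global_best(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by enumerating every alignment path.

    ``sub(x, y)`` is a residue-pair score function; a gap of length L costs
    gap_open + L * gap_extend (charged per gap run, tracked via the previous
    move).
    """
    best = -math.inf

    def rec(i: int, j: int, score: float, prev: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < len(a):
            step = gap_extend if prev == "D" else gap_open + gap_extend
            rec(i + 1, j, score - step, "D")
        if j < len(b):
            step = gap_extend if prev == "I" else gap_open + gap_extend
            rec(i, j + 1, score - step, "I")

    rec(0, 0, 0.0, "")
    return best


def enumerate_local_best(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Best local score: max over all substring pairs of the global enumeration.

    End gaps never improve a score, so the optimum over substrings equals
    the Smith-Waterman optimum; the empty alignment contributes 0.
    """
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = enumerate_global_best(a[i1:i2], b[j1:j2], sub, gap_open, gap_extend)
                    best = max(best, s)
    return best


def rank_then_pearson(x, y) -> float:
    """Spearman rho as Pearson on average ranks, written out explicitly."""

    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def step_up_bh(p_values) -> list[float]:
    """Hand-written Benjamini-Hochberg step-up."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(1.0, m * p_values[idx] / rank_from_top)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def chi2_cells(detected, totals) -> float:
    """Pearson chi-square by summing (obs-exp)^2/exp cell by cell."""
    detected = np.asarray(detected, dtype=float)
    totals = np.asarray(totals, dtype=float)
    not_detected = totals - detected
    grand = totals.sum()
    col_sums = np.array([detected.sum(), not_detected.sum()])
    chi2 = 0.0
    for row_total, obs_pair in zip(totals, zip(detected, not_detected)):
        for col_total, obs in zip(col_sums, obs_pair):
            exp = row_total * col_total / grand
            chi2 += (obs - exp) ** 2 / exp
    return chi2


def chi2_2x2_closed_form(a: float, b: float, c: float, d: float) -> float:
    """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table (a,b;c,d)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
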