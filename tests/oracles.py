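"""Independent brute-force oracles used by the test suite.

These re-derive expected results by exhaustive enumeration with no code
shared with the package implementation, so they can act as references
for the pattern matcher, the tandem-repeat scanner, the motif finder
and the pairwise aligner.
"""

from __future__ import annotations

import numpy as np

PURINES = {"A", "G"}

# --- 11-mer patterns, written out position by position ------------------


def oracle_loose(s: str) -> bool:
    return len(s) == 11 and s[4] == "T" and s[8] == "C"


def oracle_strict(s: str) -> bool:
    return oracle_loose(s) and s[7] in PURINES and s[9] in PURINES


def oracle_dr(s: str) -> bool:
    return len(s) == 11 and s[4] == "T" and s[7] == "A" and s[8] == "C" and s[9] == "A"


def oracle_scan(seq: str, min_repeats: int = 3, min_strict: int = 1):
    """Exhaustive tandem-repeat run finder over all offsets and registers.

    Returns the kept (offset, n_repeats) runs after applying the same
    documented overlap rule: more strict matches first, then more DR
    labels, then leftmost.
    """
    seq = seq.upper()
    n = len(seq)
    candidates = []
    for i in range(n - 11 + 1):
        # maximal run must not extend upstream
        if i >= 11 and oracle_loose(seq[i - 11 : i]):
            continue
        k = 0
        while i + (k + 1) * 11 <= n and oracle_loose(seq[i + k * 11 : i + (k + 1) * 11]):
            k += 1
        if k < min_repeats:
            continue
        units = [seq[i + j * 11 : i + (j + 1) * 11] for j in range(k)]
        n_strict = sum(oracle_strict(u) for u in units)
        n_dr = sum(oracle_dr(u) for u in units)
        if n_strict < min_strict:
            continue
        candidates.append((i, k, n_strict, n_dr))
    candidates.sort(key=lambda c: (-c[2], -c[3], c[0]))
    kept = []
    for i, k, ns, nd in candidates:
        if all(i + k * 11 <= j or j + m * 11 <= i for j, m, *_ in kept):
            kept.append((i, k, ns, nd))
    return sorted((i, k) for i, k, *_ in kept)


# --- protein motifs ------------------------------------------------------


def oracle_wx9eh(seq: str):
    """All (1-based start, end) spans matching W x9 E H by direct checking."""
    hits = []
    for i in range(len(seq) - 11):
        if seq[i] == "W" and seq[i + 10] == "E" and seq[i + 11] == "H":
            hits.append((i + 1, i + 12))
    return hits


def oracle_rxwerry(seq: str):
    hits = []
    for i in range(len(seq) - 6):
        if (seq[i] == "R" and seq[i + 2] == "W" and seq[i + 3] == "E"
                and seq[i + 4] == "R" and seq[i + 5] == "R" and seq[i + 6] == "Y"):
            hits.append((i + 1, i + 7))
    return hits


def oracle_b12(seq: str):
    """[D/E] x H x2 [G/P] x41 S x [T/V] x(22..27) G G, every spacer length."""
    hits = []
    n = len(seq)
    for i in range(n):
        if seq[i] not in "DE":
            continue
        if i + 2 >= n or seq[i + 2] != "H":
            continue
        if i + 5 >= n or seq[i + 5] not in "GP":
            continue
        s_pos = i + 5 + 42  # S after the x41 spacer
        if s_pos >= n or seq[s_pos] != "S":
            continue
        if s_pos + 2 >= n or seq[s_pos + 2] not in "TV":
            continue
        for spacer in range(22, 28):
            g_pos = s_pos + 3 + spacer
            if g_pos + 1 >= n:
                break
            if seq[g_pos] == "G" and seq[g_pos + 1] == "G":
                hits.append((i + 1, g_pos + 2))
    return hits


# --- affine-gap global alignment (Gotoh, free end gaps) ------------------


def gotoh_score(a: str, b: str, matrix, gap_open: float = -11.0,
                gap_extend: float = -1.0) -> float:
    """Optimal global alignment score with affine gaps and free end gaps.

    A gap of length L costs gap_open + (L-1)*gap_extend, except
    leading/trailing gaps which are free.  ``matrix`` is a Biopython
    substitution matrix (used only as a score lookup table).
    """
    m, n = len(a), len(b)
    neg = float("-inf")
    M = np.full((m + 1, n + 1), neg)
    Ix = np.full((m + 1, n + 1), neg)  # gap in b (a consumed)
    Iy = np.full((m + 1, n + 1), neg)  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        Ix[i][0] = 0.0  # leading gap in b is free
    for j in range(1, n + 1):
        Iy[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + sub
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend,
                           Iy[i - 1][j] + gap_open)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend,
                           Ix[i][j - 1] + gap_open)
    # trailing gaps free: best over last row/column states
    best = max(M[m][n], Ix[m][n], Iy[m][n])
    for i in range(m + 1):
        best = max(best, M[i][n], Ix[i][n], Iy[i][n])
    for j in range(n + 1):
        best = max(best, M[m][j], Ix[m][j], Iy[m][j])
    return float(best)
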