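"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or textbook
formulas, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_matches(S, min_len=7, max_matches=200):
    """Exhaustive greedy gapless-match extraction.

    Enumerates every diagonal segment (i0, j0, L >= min_len) of unmasked
    cells, picks the one with the largest total score (> 0; ties by smallest
    (i0, j0), then shortest), masks its rows and columns, and repeats.
    Returns a list of (score, i0, j0, L) in extraction order.
    """
    S = np.asarray(S, dtype=float)
    na, nb = S.shape
    rm = [False] * na
    cm = [False] * nb
    out = []
    while len(out) < max_matches:
        best = None
        for i0 in range(na):
            for j0 in range(nb):
                for L in range(min_len, min(na - i0, nb - j0) + 1):
                    if any(rm[i0 + t] or cm[j0 + t] for t in range(L)):
                        continue
                    sc = 0.0
                    for t in range(L):
                        sc += S[i0 + t, j0 + t]
                    if sc <= 0.0:
                        continue
                    if (best is None or sc > best[0]
                            or (sc == best[0]
                                and (i0, j0, L) < (best[1], best[2], best[3]))):
                        best = (sc, i0, j0, L)
        if best is None:
            break
        out.append(best)
        _, i0, j0, L = best
        for t in range(L):
            rm[i0 + t] = True
            cm[j0 + t] = True
    return out


def enumerate_alignment_score(seq_a, seq_b, match=1.0, mismatch=0.0, gap=-0.5):
    """Optimal global-alignment score by plain recursive enumeration."""

    def rec(i, j):
        if i == len(seq_a):
            return gap * (len(seq_b) - j)
        if j == len(seq_b):
            return gap * (len(seq_a) - i)
        diag = rec(i + 1, j + 1) + (match if seq_a[i] == seq_b[j] else mismatch)
        up = rec(i + 1, j) + gap
        left = rec(i, j + 1) + gap
        return max(diag, up, left)

    return rec(0, 0)


def pearson(x, y):
    """Textbook Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
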