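"""Dense diagonal pre-filter for the dispersed-repeat scanner.

For genome-scale inputs the 7-mer seeding step stops pruning (an AT-rich
124 kb circle has a chance seed on essentially every diagonal), so the
scanner instead asks, per diagonal, whether any ``min_len`` window carries
at most ``k`` mismatches — a rolling-count sweep that is exact, not a
heuristic.  Only flagged diagonals get the detailed maximal-window
enumeration.  The sweep is jitted with numba when available; a vectorised
numpy fallback gives identical output.

For the reversal-based transforms (P, R) a pair and its mirror listing sit
on the same diagonal symmetrically about its midpoint, so sweeping the
first half of each diagonal (plus one window length) is sufficient to flag
it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install
    HAVE_NUMBA = False


def _hit_diagonals_numpy(a: np.ndarray, b: np.ndarray, d_lo: int, d_hi: int,
                         k: int, min_len: int, half: bool) -> np.ndarray:
    """Vectorised fallback: per-diagonal windowed mismatch minimum."""
    n = a.shape[0]
    hits = []
    for d in range(d_lo, d_hi + 1):
        if d >= 0:
            av, bv = a[: n - d], b[d:]
        else:
            av, bv = a[-d:], b[: n + d]
        m = len(av)
        if m < min_len:
            continue
        if half:
            limit = min(m, m // 2 + min_len)
            av, bv = av[:limit], bv[:limit]
            m = limit
        x = (av != bv)
        c = np.cumsum(x, dtype=np.int32)
        w = c[min_len - 1:].copy()
        w[1:] -= c[: m - min_len]
        if w.min() <= k:
            hits.append(d)
    return np.array(hits, dtype=np.int64)


if HAVE_NUMBA:

    @njit(cache=False)
    def _hit_diagonals_jit(a, b, d_lo, d_hi, k, min_len, half):  # pragma: no cover
        n = a.shape[0]
        out = np.empty(d_hi - d_lo + 1, np.int64)
        m_out = 0
        for d in range(d_lo, d_hi + 1):
            if d >= 0:
                ia, ib, m = 0, d, n - d
            else:
                ia, ib, m = -d, 0, n + d
            if m < min_len:
                continue
            limit = m
            if half:
                h = m // 2 + min_len
                if h < limit:
                    limit = h
            c = 0
            hit = False
            for i in range(limit):
                if a[ia + i] != b[ib + i]:
                    c += 1
                j = i - min_len
                if j >= 0 and a[ia + j] != b[ib + j]:
                    c -= 1
                if i >= min_len - 1 and c <= k:
                    hit = True
                    break
            if hit:
                out[m_out] = d
                m_out += 1
        return out[:m_out]


def hit_diagonals(a: np.ndarray, b: np.ndarray, d_lo: int, d_hi: int,
                  k: int, min_len: int, half: bool) -> np.ndarray:
    """Diagonals (offsets of ``b`` relative to ``a``) containing at least one
    ``min_len`` window with <= ``k`` mismatches."""
    if HAVE_NUMBA:
        return _hit_diagonals_jit(a, b, d_lo, d_hi, k, min_len, half)
    return _hit_diagonals_numpy(a, b, d_lo, d_hi, k, min_len, half)
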