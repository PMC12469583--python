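"""Independent oracles used to check the scanners.

These deliberately avoid the implementation's algorithmic formulations:

* ``oracle_dispersed`` sweeps every diagonal and derives maximal windows
  from a rank/searchsorted two-pointer (the implementation enumerates
  mismatch-gap sentinels on seed-filtered diagonals).
* ``brute_dispersed_tiny`` is the definition made literal — every (i, j, L)
  triple is validated and checked for maximality by direct extension — and
  is only affordable on tiny inputs.
* ``brute_ssrs`` re-scans every (start, period) pair directly.
* ``brute_pi`` is an explicit all-pairs Hamming loop.
"""

from __future__ import annotations

import numpy as np

from plastchar._seq import complement, revcomp

_PAIRWISE = {
    # per-type mismatch predicate on genome coordinates (i, j, window pos t)
    "F": lambda s, i, j, L, t: s[i + t] != s[j + t],
    "C": lambda s, i, j, L, t: s[i + t] != complement(s[j + t]),
    "R": lambda s, i, j, L, t: s[i + t] != s[j + L - 1 - t],
    "P": lambda s, i, j, L, t: s[i + t] != complement(s[j + L - 1 - t]),
}


def _mismatches(seq: str, rtype: str, i: int, j: int, L: int) -> int | None:
    n = len(seq)
    if i < 0 or j < 0 or i + L > n or j + L > n:
        return None
    pred = _PAIRWISE[rtype]
    return sum(1 for t in range(L) if pred(seq, i, j, L, t))


def brute_dispersed_tiny(seq: str, min_len: int, k: int
                         ) -> set[tuple[str, int, int, int, int]]:
    """Literal enumeration of maximal pairs; O(n^3)-ish, tiny inputs only."""
    n = len(seq)
    out: set[tuple[str, int, int, int, int]] = set()
    for rtype in "FPRC":
        for L in range(min_len, n + 1):
            for i in range(n - L + 1):
                for j in range(n - L + 1):
                    if rtype == "F" and i == j:
                        continue
                    mm = _mismatches(seq, rtype, i, j, L)
                    if mm is None or mm > k:
                        continue
                    # maximality: both one-base extensions must fail
                    if rtype in ("F", "C"):
                        left = _mismatches(seq, rtype, i - 1, j - 1, L + 1)
                        right = _mismatches(seq, rtype, i, j, L + 1)
                    else:
                        left = _mismatches(seq, rtype, i - 1, j, L + 1)
                        right = _mismatches(seq, rtype, i, j - 1, L + 1)
                    if (left is not None and left <= k) or \
                       (right is not None and right <= k):
                        continue
                    p1, p2 = (i, j) if i <= j else (j, i)
                    out.add((rtype, p1, p2, L, mm))
    return out


def oracle_dispersed(seq: str, min_len: int = 30, k: int = 3
                     ) -> set[tuple[str, int, int, int, int]]:
    """Exhaustive diagonal sweep with searchsorted two-pointer windows."""
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    images = {"F": seq, "P": revcomp(seq), "R": seq[::-1], "C": complement(seq)}
    out: set[tuple[str, int, int, int, int]] = set()
    for rtype, img in images.items():
        b = np.frombuffer(img.encode(), dtype=np.uint8)
        if rtype in ("F", "C"):
            drange = range(1, n - min_len + 1)
        else:
            drange = range(-(n - min_len), n - min_len + 1)
        for d in drange:
            if d >= 0:
                av, bv, off = a[: n - d], b[d:], 0
            else:
                av, bv, off = a[-d:], b[: n + d], -d
            m = len(av)
            if m < min_len:
                continue
            mism = np.flatnonzero(av != bv)
            pos = np.arange(m)
            idx = np.searchsorted(mism, pos, side="left")
            if len(mism) == 0:
                e = np.full(m, m)
            else:
                has_far = idx + k < len(mism)
                e = np.where(has_far,
                             mism[np.minimum(idx + k, len(mism) - 1)], m)
            maximal = np.ones(m, dtype=bool)
            maximal[1:] = e[:-1] < e[1:]
            ok = np.flatnonzero(maximal & (e - pos >= min_len))
            for s0 in ok:
                s0 = int(s0)
                end = int(e[s0])
                L = end - s0
                mm = int(np.searchsorted(mism, end) - idx[s0])
                i = off + s0
                bpos = i + d
                j = bpos if rtype in ("F", "C") else n - bpos - L
                if rtype == "F" and i == j:
                    continue
                p1, p2 = (i, j) if i <= j else (j, i)
                out.add((rtype, p1, p2, L, mm))
    return out


def brute_ssrs(seq: str, thresholds: dict[int, int]
               ) -> set[tuple[str, int, int, int]]:
    """Direct (start, period) scan for perfect primitive tandem runs."""
    n = len(seq)
    raw: list[tuple[str, int, int, int]] = []
    for p, need in thresholds.items():
        for i in range(n - p):
            # run must not extend left at match-array level
            if i > 0 and seq[i - 1] == seq[i + p - 1]:
                continue
            matched = 0
            while i + p + matched < n and seq[i + matched] == seq[i + p + matched]:
                matched += 1
            units = (matched + p) // p
            if units < need:
                continue
            motif = seq[i: i + p]
            if "N" in motif:
                continue
            if any(p % d == 0 and motif == motif[:d] * (p // d)
                   for d in range(1, p)):
                continue  # not primitive
            raw.append((motif, units, i, i + units * p))
    kept = set()
    for motif, units, s, e in raw:
        if any(len(m2) < len(motif) and s2 <= s and e <= e2
               for m2, u2, s2, e2 in raw):
            continue
        kept.add((motif, units, s, e))
    return kept


def brute_pi(rows: list[str]) -> float | None:
    """Explicit all-pairs Hamming pi with complete deletion."""
    keep = [c for c in range(len(rows[0]))
            if all(r[c] in "ACGT" for r in rows)]
    if not keep:
        return None
    total = 0
    npairs = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            npairs += 1
            total += sum(1 for c in keep if rows[i][c] != rows[j][c])
    return total / npairs / len(keep)
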