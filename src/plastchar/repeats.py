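"""Repeat mining: microsatellites (SSRs) and maximal dispersed repeats.

SSRs are perfect tandem runs of a primitive 1-6 nt motif, reported under the
MISA-style class thresholds (mono >=10 units, di >=6, tri >=4, tetra/penta/
hexa >=3 by default).

Dispersed repeats are maximal pairs of >=30 bp segments matching under one of
four transforms — F (direct), P (reverse complement), R (reverse), C
(complement) — with Hamming distance <= 3, REPuter-style.  The finder is
seed-and-extend: any qualifying 30 bp window with <=3 mismatches contains an
exact run of >= ceil((30-3)/4) = 7 nt (pigeonhole), so exact 7-mer seed
matches locate every candidate diagonal; each candidate diagonal is then
swept exhaustively for maximal windows.  When seeding would enumerate more
pairs than a dense sweep (AT-rich plastomes at full length), the finder
falls back to sweeping all diagonals — output is identical either way.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._scan import hit_diagonals
from ._seq import as_bytes, complement, revcomp
from .genome_io import GenomeRecord
from .structure import QuadripartiteLayout

# unit-count thresholds per motif length (MISA defaults used in plastome work)
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}

REPEAT_TYPES = ("F", "P", "R", "C")


@dataclass(frozen=True)
class SsrLocus:
    motif: str          # as read on the forward strand, starting at `start`
    unit_count: int
    start: int          # 0-based half-open
    end: int
    region: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.unit_count:
            raise ValueError("SSR span inconsistent with motif * unit_count")


@dataclass(frozen=True)
class DispersedRepeat:
    type: str           # F / P / R / C
    pos1: int           # start of first copy (0-based), pos1 <= pos2
    pos2: int
    length: int
    mismatches: int
    is_ir_pair: bool = False

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.pos1, self.pos1 + self.length),
                (self.pos2, self.pos2 + self.length))


# ---------------------------------------------------------------------------
# SSR mining
# ---------------------------------------------------------------------------

def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_ssrs(genome: GenomeRecord | str,
              thresholds: Mapping[int, int] = DEFAULT_SSR_THRESHOLDS,
              layout: QuadripartiteLayout | None = None) -> list[SsrLocus]:
    """Left-to-right scan for perfect SSRs meeting the class thresholds.

    Each maximal tandem run is assigned its smallest primitive period; runs
    whose interval lies inside an already-reported run of smaller period are
    not double-reported.  Unit counts are whole units (trailing partial
    units do not count toward the threshold and are not included in the
    reported span).
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    a = as_bytes(seq)
    n = len(a)
    loci: list[SsrLocus] = []
    for period in sorted(thresholds):
        need = thresholds[period]
        if n < period * need:
            continue
        eq = a[period:] == a[:-period]
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        flips = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(flips[::2], flips[1::2]):
            run_len = int(run_end - run_start)           # matched positions
            total = run_len + period                     # tandem span in bp
            units = total // period
            if units < need:
                continue
            start = int(run_start)
            motif = seq[start:start + period]
            if "N" in motif or not _is_primitive(motif):
                continue
            end = start + units * period
            loci.append(SsrLocus(motif=motif, unit_count=units,
                                 start=start, end=end))
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    # containment filter: drop loci inside a reported locus of smaller period
    kept: list[SsrLocus] = []
    for loc in loci:
        contained = any(
            len(other.motif) < len(loc.motif)
            and other.start <= loc.start and loc.end <= other.end
            for other in loci if other is not loc
        )
        if not contained:
            kept.append(loc)
    if layout is not None:
        kept = [replace(l, region=layout.region_of(l.start)) for l in kept]
    return kept


def summarize_ssrs(loci: Sequence[SsrLocus]) -> dict:
    """Counts by motif as read (A and T tallied separately) and by class."""
    by_motif: dict[str, int] = defaultdict(int)
    by_class: dict[int, int] = defaultdict(int)
    for l in loci:
        by_motif[l.motif] += 1
        by_class[len(l.motif)] += 1
    return {
        "total": len(loci),
        "by_motif": dict(sorted(by_motif.items())),
        "by_class": {k: by_class.get(k, 0) for k in range(1, 7)},
    }


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------

def _diagonal_windows(av: np.ndarray, bv: np.ndarray, k: int,
                      min_len: int) -> list[tuple[int, int, int]]:
    """All maximal (start, end, n_mismatch) windows of one diagonal.

    A maximal window with <=k mismatches is delimited on each side by either
    the diagonal boundary or the (k+1)-th mismatch; enumerating gaps between
    mismatches k+1 apart (with boundary sentinels) yields exactly the
    maximal windows.
    """
    m = len(av)
    if m < min_len:
        return []
    mism = np.flatnonzero(av != bv)
    if len(mism) <= k:
        return [(0, m, int(len(mism)))]
    sent = np.empty(len(mism) + 2, dtype=np.int64)
    sent[0] = -1
    sent[1:-1] = mism
    sent[-1] = m
    starts = sent[: -(k + 1)] + 1
    ends = sent[k + 1:]
    good = np.flatnonzero(ends - starts >= min_len)
    return [(int(starts[t]), int(ends[t]), k) for t in good]


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _kmer_codes(a: np.ndarray, k: int) -> np.ndarray:
    enc = _ENC[a].astype(np.int64)
    c = np.zeros(len(a) - k + 1, dtype=np.int64)
    for j in range(k):
        c = c * 4 + enc[j:j + len(c)]
    return c


def _candidate_diagonals(a: np.ndarray, b: np.ndarray, seed_len: int,
                         budget: int) -> np.ndarray | None:
    """Diagonals (b_pos - a_pos) carrying an exact seed match, or ``None``
    when enumerating seed pairs would exceed ``budget`` (dense fallback)."""
    ca = _kmer_codes(a, seed_len)
    cb = _kmer_codes(b, seed_len)
    cnt_a = np.bincount(ca, minlength=4 ** seed_len)
    cnt_b = np.bincount(cb, minlength=4 ** seed_len)
    n_pairs = int(np.dot(cnt_a.astype(np.float64), cnt_b.astype(np.float64)))
    if n_pairs > budget:
        return None
    pos_b: dict[int, list[int]] = defaultdict(list)
    for p, code in enumerate(cb.tolist()):
        pos_b[code].append(p)
    diags: set[int] = set()
    for p, code in enumerate(ca.tolist()):
        for q in pos_b.get(code, ()):
            diags.add(q - p)
    return np.array(sorted(diags), dtype=np.int64)


def _scan_transform(seq: str, bseq: str, rtype: str, min_len: int,
                    k: int, seed_len: int) -> set[tuple[int, int, int, int]]:
    """Maximal pairs between ``seq`` and transform image ``bseq``.

    Returns canonical tuples (pos1, pos2, length, mismatches) in genome
    coordinates.
    """
    a = as_bytes(seq)
    b = as_bytes(bseq)
    n = len(a)
    if rtype in ("F", "C"):
        d_lo, d_hi = 1, n - min_len
    else:  # P, R: mirror pairs share a diagonal, so all diagonals are needed
        d_lo, d_hi = -(n - min_len), n - min_len
    budget = max(200_000, 4 * n)
    cand = _candidate_diagonals(a, b, seed_len, budget)
    if cand is None:
        # seeding stopped pruning (large, low-complexity input): exact dense
        # pre-filter keeps only diagonals that contain a qualifying window
        diagonals: Iterable[int] = hit_diagonals(
            a, b, d_lo, d_hi, k, min_len, rtype in ("P", "R"))
    else:
        diagonals = cand[(cand >= d_lo) & (cand <= d_hi)]
    found: set[tuple[int, int, int, int]] = set()
    for d in diagonals:
        d = int(d)
        if d >= 0:
            av, bv = a[: n - d], b[d:]
            a_off = 0
        else:
            av, bv = a[-d:], b[: n + d]
            a_off = -d
        for ws, we, mm in _diagonal_windows(av, bv, k, min_len):
            i = a_off + ws
            length = we - ws
            b_start = i + d
            if rtype in ("F", "C"):
                j = b_start
            else:
                j = n - b_start - length
            if rtype == "F" and i == j:
                continue
            p1, p2 = (i, j) if i <= j else (j, i)
            found.add((p1, p2, length, mm))
    return found


def find_dispersed(genome: GenomeRecord | str, min_len: int = 30,
                   max_mismatch: int = 3, seed_len: int | None = None,
                   layout: QuadripartiteLayout | None = None
                   ) -> list[DispersedRepeat]:
    """Mine maximal dispersed repeats of all four types.

    Each unordered pair is reported once; palindromes whose two listings
    coincide (pos1 == pos2) appear once.  When a layout is supplied, the
    palindromic pair formed by the inverted repeats themselves is tagged
    ``is_ir_pair`` so summaries can exclude it.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    if seed_len is None:
        # pigeonhole: a min_len window with <=max_mismatch mismatches keeps
        # an exact run of ceil((min_len - k) / (k + 1)) nt
        seed_len = max(1, -(-(min_len - max_mismatch) // (max_mismatch + 1)))
    if len(seq) < min_len:
        return []
    transforms = {
        "F": seq,
        "P": revcomp(seq),
        "R": seq[::-1],
        "C": complement(seq),
    }
    repeats: list[DispersedRepeat] = []
    for rtype, bseq in transforms.items():
        for p1, p2, length, mm in sorted(
                _scan_transform(seq, bseq, rtype, min_len, max_mismatch,
                                seed_len)):
            repeats.append(DispersedRepeat(rtype, p1, p2, length, mm))
    repeats.sort(key=lambda r: (r.pos1, r.pos2, r.type))
    if layout is not None:
        repeats = tag_ir_pairs(repeats, layout)
    return repeats


def tag_ir_pairs(repeats: Sequence[DispersedRepeat],
                 layout: QuadripartiteLayout) -> list[DispersedRepeat]:
    """Flag palindromic repeats that are the IRa/IRb pair itself."""
    out = []
    ir_len = layout.ir_length
    ir_starts = sorted((layout.ira[0], layout.irb[0]))
    for r in repeats:
        flag = (
            r.type == "P"
            and r.length >= 0.5 * ir_len
            and abs(r.pos1 - ir_starts[0]) <= ir_len // 2
            and abs(r.pos2 - ir_starts[1]) <= ir_len // 2
        )
        out.append(replace(r, is_ir_pair=flag) if flag != r.is_ir_pair else r)
    return out


def summarize_dispersed(repeats: Sequence[DispersedRepeat],
                        include_ir_pair: bool = False) -> dict:
    """Counts by type; the IR self-pair is excluded unless requested."""
    used = [r for r in repeats if include_ir_pair or not r.is_ir_pair]
    by_type = {t: 0 for t in REPEAT_TYPES}
    for r in used:
        by_type[r.type] += 1
    return {"total": len(used), "by_type": by_type,
            "n_ir_pairs_tagged": sum(1 for r in repeats if r.is_ir_pair)}


def validate_repeat(seq: str, r: DispersedRepeat) -> bool:
    """Re-check a reported repeat against its definition on the raw sequence."""
    s1 = seq[r.pos1: r.pos1 + r.length]
    s2 = seq[r.pos2: r.pos2 + r.length]
    if len(s1) != r.length or len(s2) != r.length:
        return False
    image = {"F": lambda x: x, "P": revcomp,
             "R": lambda x: x[::-1], "C": complement}[r.type](s2)
    mism = sum(1 for x, y in zip(s1, image) if x != y)
    return mism == r.mismatches


def validate_ssr(seq: str, l: SsrLocus) -> bool:
    """Re-check a reported SSR: perfect tandem, primitive motif, maximal."""
    if seq[l.start: l.end] != l.motif * l.unit_count:
        return False
    if not _is_primitive(l.motif):
        return False
    p = len(l.motif)
    # no full extra unit on either side
    if l.start >= p and seq[l.start - p: l.start] == l.motif:
        return False
    if seq[l.end: l.end + p] == l.motif:
        return False
    return True
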