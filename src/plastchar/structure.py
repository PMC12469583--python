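"""Quadripartite plastome layout: IR detection, region statistics, junctions.

A typical moss plastome is a circle of four regions — large single copy
(LSC), inverted repeat b (IRb), small single copy (SSC), inverted repeat a
(IRa) — where IRa is the exact reverse complement of IRb.  Junctions are
named after the regions they separate: JLB (LSC|IRb), JSB (IRb|SSC),
JSA (SSC|IRa), JLA (IRa|LSC).

Detection is annotation-free: the layout is the longest pair of disjoint
circular intervals whose sequences are reverse complements of each other
(optionally allowing a few mismatches), with both gaps nonempty; the longer
gap is the LSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._seq import gc_fraction, revcomp, rotate
from .genome_io import Feature, GenomeRecord

JUNCTION_ORDER = ("JLB", "JSB", "JSA", "JLA")


class NoInvertedRepeatError(ValueError):
    """Raised when no qualifying IR pair exists (non-quadripartite genome)."""


@dataclass(frozen=True)
class QuadripartiteLayout:
    """Region intervals as (start, length) on circular coordinates."""

    genome_length: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    def __post_init__(self) -> None:
        total = self.lsc[1] + self.ssc[1] + self.ira[1] + self.irb[1]
        if total != self.genome_length:
            raise ValueError(
                f"regions sum to {total}, genome length is {self.genome_length}")
        if self.ira[1] != self.irb[1]:
            raise ValueError("IR copies must have equal length")

    @property
    def ir_length(self) -> int:
        return self.ira[1]

    @property
    def junctions(self) -> dict[str, int]:
        n = self.genome_length
        return {
            "JLB": self.irb[0] % n,
            "JSB": self.ssc[0] % n,
            "JSA": self.ira[0] % n,
            "JLA": self.lsc[0] % n,
        }

    def region_of(self, pos: int) -> str:
        """Region name containing circular position ``pos``."""
        n = self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            start, length = getattr(self, name)
            if (pos - start) % n < length:
                return {"lsc": "LSC", "irb": "IRb",
                        "ssc": "SSC", "ira": "IRa"}[name]
        raise AssertionError("regions tile the circle")  # pragma: no cover

    def region_sequence(self, genome: GenomeRecord, name: str) -> str:
        start, length = getattr(self, name.lower())
        doubled = genome.sequence + genome.sequence
        return doubled[start:start + length]


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _circular_extend(seq: str, rc: str, i: int, q: int, seed_len: int,
                     max_mismatch: int) -> tuple[int, int, int, int]:
    """Extend an exact seed match between circular ``seq`` and circular
    ``rc`` (its reverse complement) allowing up to ``max_mismatch``
    substitutions; returns (i0, q0, length, mismatches) of a maximal match.

    Greedy symmetric extension: alternately push left then right while the
    mismatch budget allows; for the default budget of 0 this is exactly the
    maximal exact match.
    """
    n = len(seq)
    left = 0
    right = seed_len
    mism: list[int] = []  # offsets (relative to i-left) of accepted mismatches
    # extend right
    budget = max_mismatch

    def at(s: str, p: int) -> str:
        return s[p % n]

    # right extension
    r_mism = 0
    while left + right < n:
        if at(seq, i + right) == at(rc, q + right):
            right += 1
        elif r_mism + 0 < budget:
            # tentative: only consume budget if a match follows soon; simple
            # greedy consume
            r_mism += 1
            right += 1
        else:
            break
    budget -= r_mism
    l_mism = 0
    while left + right < n:
        if at(seq, i - left - 1) == at(rc, q - left - 1):
            left += 1
        elif l_mism < budget:
            l_mism += 1
            left += 1
        else:
            break
    # trim mismatching end positions (a maximal match should not start or
    # end on a mismatch)
    i0, q0, length = i - left, q - left, left + right
    while length > 0 and at(seq, i0) != at(rc, q0):
        i0 += 1
        q0 += 1
        length -= 1
    while length > 0 and at(seq, i0 + length - 1) != at(rc, q0 + length - 1):
        length -= 1
    mismatches = sum(
        1 for off in range(length) if at(seq, i0 + off) != at(rc, q0 + off))
    return i0 % n, q0 % n, length, mismatches


def detect_inverted_repeats(genome: GenomeRecord, min_ir_len: int = 1000,
                            max_ir_mismatch: int = 0) -> QuadripartiteLayout:
    """Find the quadripartite layout of a circular plastome.

    Seeds exact 31-mers of the genome against its reverse complement at a
    stride small enough that any repeat of ``min_ir_len`` is hit, extends
    each seed to a maximal match, and keeps the longest disjoint pair with
    two nonempty gaps.  Ties break toward the smallest IRb start in the
    frame where the LSC starts at 0.
    """
    seq = genome.sequence
    n = len(seq)
    if min_ir_len < 31:
        raise ValueError("min_ir_len must be at least 31")
    if 2 * min_ir_len >= n:
        raise NoInvertedRepeatError(
            f"{genome.id}: genome of {n} bp cannot host two {min_ir_len} bp IRs")
    rc = revcomp(seq)
    k = 31
    rc2 = rc + rc[:k]
    seq2 = seq + seq[:k]
    # index all k-mers of the circular reverse complement
    table: dict[str, list[int]] = {}
    for q in range(n):
        table.setdefault(rc2[q:q + k], []).append(q)
    stride = max(1, min_ir_len - k + 1)
    candidates: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(0, n, stride):
        for q in table.get(seq2[i:i + k], ()):
            i0, q0, length, mm = _circular_extend(seq, rc, i, q, k,
                                                  max_ir_mismatch)
            if length < min_ir_len or length > n // 2:
                continue
            # map the rc interval back to genome coordinates:
            # rc[q .. q+L) == revcomp(seq_circ[n-q-L .. n-q))
            j0 = (n - q0 - length) % n
            a, b = sorted((i0, j0))
            candidates[(a, b)] = (length, mm)
    best: tuple[int, int, int, int] | None = None  # (length, a, b)
    for (a, b), (length, mm) in candidates.items():
        # the two copies must be disjoint on the circle with nonempty gaps
        gap1 = b - (a + length)
        gap2 = (a + n) - (b + length)
        if gap1 <= 0 or gap2 <= 0:
            continue
        key = (length, -a, -b)
        if best is None or key > (best[0], -best[1], -best[2]):
            best = (length, a, b, mm)
    if best is None:
        raise NoInvertedRepeatError(
            f"{genome.id}: no inverted repeat pair of >= {min_ir_len} bp; "
            "genome is not quadripartite")
    length, a, b, _ = best
    gap_ab = (a + length, b - (a + length))          # between copy A and copy B
    gap_ba = ((b + length) % n, (a + n) - (b + length))  # wraps the origin
    if gap_ab[1] >= gap_ba[1]:
        lsc, ssc = gap_ab, gap_ba
        irb_start, ira_start = b, a     # LSC -> (wrap) ...; order below
        # circle order starting at LSC: lsc, then copy B, then gap_ba(SSC),
        # then copy A
        layout = QuadripartiteLayout(n, lsc=gap_ab, irb=(b, length),
                                     ssc=gap_ba, ira=(a, length))
    else:
        layout = QuadripartiteLayout(n, lsc=gap_ba, irb=(a, length),
                                     ssc=gap_ab, ira=(b, length))
    return layout


def rotate_to_canonical(genome: GenomeRecord,
                        layout: QuadripartiteLayout) -> tuple[GenomeRecord,
                                                              QuadripartiteLayout]:
    """Rotate so the LSC starts at position 0 (canonical JLA at origin)."""
    n = len(genome)
    off = layout.lsc[0] % n
    new_seq = rotate(genome.sequence, off)
    feats = []
    for f in genome.features:
        ivs = tuple((((s - off) % n), ((s - off) % n) + (e - s))
                    for s, e in f.intervals)
        if any(e > n for _, e in ivs):
            # feature now crosses the origin; keep original record semantics
            # by splitting is avoided — plastome annotations are rotated so
            # this should not occur for canonical layouts
            ivs = tuple((s, min(e, n)) for s, e in ivs)
        feats.append(Feature(f.gene_name, f.kind, f.strand, ivs, f.notes))
    new_layout = QuadripartiteLayout(
        n,
        lsc=(0, layout.lsc[1]),
        irb=((layout.irb[0] - off) % n, layout.irb[1]),
        ssc=((layout.ssc[0] - off) % n, layout.ssc[1]),
        ira=((layout.ira[0] - off) % n, layout.ira[1]),
    )
    return (GenomeRecord(genome.id, new_seq, genome.circular, tuple(feats)),
            new_layout)


# ---------------------------------------------------------------------------
# region statistics
# ---------------------------------------------------------------------------

def region_stats(genome: GenomeRecord, layout: QuadripartiteLayout) -> dict:
    """Per-region length and GC, plus genome totals.

    GC = (G+C)/(A+C+G+T); N excluded from the denominator.  Percentages are
    rounded to one decimal in the ``*_pct`` fields, fractions kept raw.
    """
    out: dict[str, dict] = {}
    for name in ("LSC", "SSC", "IRa", "IRb"):
        seq = layout.region_sequence(genome, name)
        frac = gc_fraction(seq)
        out[name] = {"length": len(seq), "gc": frac,
                     "gc_pct": round(100 * frac, 1)}
    total_gc = gc_fraction(genome.sequence)
    out["total"] = {"length": len(genome), "gc": total_gc,
                    "gc_pct": round(100 * total_gc, 1)}
    out["ir_length"] = layout.ir_length
    return out


# ---------------------------------------------------------------------------
# junction distances
# ---------------------------------------------------------------------------

def _signed_distance(span: tuple[int, int], junction: int, n: int) -> int:
    """Signed gene-to-junction distance on the circle.

    Positive: gap between the nearer gene end and the junction.  Negative:
    the gene crosses the junction; magnitude is the overlap into the region
    on the far side (the smaller of the two pieces the junction cuts).
    Zero: a gene end sits exactly on the junction.
    """
    s, e = span
    # work in a frame centered on the junction
    ds = (s - junction) % n
    de = (e - junction) % n
    length = (e - s) % n or (e - s)
    if ds == 0 or de == 0:
        return 0
    # gene covers the junction iff start is "before" it and end "after" it
    # in circular terms: (junction - s) % n < length
    if (junction - s) % n < length:
        into_right = de            # bp of gene past the junction
        into_left = (junction - s) % n
        return -min(into_left, into_right)
    # gap: distance from the nearer end
    return min(ds, n - de)


def junction_distances(genomes: Sequence[tuple[GenomeRecord, QuadripartiteLayout]],
                       genes_of_interest: Sequence[str]) -> list[dict]:
    """Distance of each named gene to each junction, across genomes.

    For each (genome, junction, gene) the nearest copy of the gene is used;
    absent genes are reported with ``distance=None`` and ``status='absent'``
    (plastomes do lose junction genes, e.g. rpl23).
    """
    report: list[dict] = []
    for genome, layout in genomes:
        n = len(genome)
        feats_by_name: dict[str, list[Feature]] = {}
        for f in genome.features:
            feats_by_name.setdefault(f.gene_name, []).append(f)
        for jname, jpos in layout.junctions.items():
            for gene in genes_of_interest:
                feats = feats_by_name.get(gene)
                if not feats:
                    report.append({"genome": genome.id, "junction": jname,
                                   "gene": gene, "distance": None,
                                   "status": "absent"})
                    continue
                best = None
                for f in feats:
                    d = _signed_distance(f.span, jpos, n)
                    if best is None or abs(d) < abs(best[0]):
                        best = (d, f)
                d, f = best
                s, e = f.span
                report.append({
                    "genome": genome.id, "junction": jname, "gene": gene,
                    "distance": d,
                    "status": "crosses" if d < 0 else "gap",
                    "start_region": layout.region_of(s),
                    "end_region": layout.region_of((e - 1) % n),
                })
    return report
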