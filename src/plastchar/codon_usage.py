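"""Codon-usage-bias statistics: composition, RSCU, ENC, plot datasets,
correlations, and optimal-codon identification.

All computations use the standard genetic code.  Codons are handled as DNA
triplets internally; reporting functions emit RNA spelling (U for T), which
is the convention for published codon tables.

Key quantities
--------------
RSCU
    Observed count of a codon divided by the mean count of its synonymous
    family; 1 means no bias within the family.
ENC (Nc)
    Wright's effective number of codons, from 20 (one codon per amino acid)
    to 61 (uniform synonymous usage), estimated from family homozygosity
    F = (n * sum(p_i^2) - 1) / (n - 1) averaged within degeneracy classes:
    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
Optimal codons
    Genes are sorted by ENC; the lowest-ENC decile forms the putative
    high-expression pool and the highest-ENC decile the low-expression pool.
    A codon is optimal when its genome-wide pooled RSCU exceeds 1 (high
    frequency) and its pool difference dRSCU = RSCU_high - RSCU_low is at
    least 0.08 (high expression).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import STOP_CODONS, CdsRecord

# ---------------------------------------------------------------------------
# genetic code (standard), DNA spelling
# ---------------------------------------------------------------------------

GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in GENETIC_CODE if GENETIC_CODE[c] != "*")

# synonymous families (size > 1); Met and Trp are non-degenerate
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(GENETIC_CODE[_codon], tuple())
FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if GENETIC_CODE[c] == aa)
    for aa in FAMILIES
}
DEGENERATE_FAMILIES = {aa: cs for aa, cs in FAMILIES.items() if len(cs) > 1}
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for cs in DEGENERATE_FAMILIES.values() for c in cs)

_GC = frozenset("GC")


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.replace("U", "T")


# ---------------------------------------------------------------------------
# per-gene composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonStats:
    gene_name: str
    length_nt: int
    a3: float
    t3: float
    g3: float
    c3: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float | None
    gc_all: float
    enc: float | None

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


def coding_codons(cds: CdsRecord) -> list[str]:
    """Codons entering the analysis: stop removed, start retained."""
    codons = list(cds.codons)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return [c for c in codons if c in GENETIC_CODE and GENETIC_CODE[c] != "*"]


def count_codons(records: CdsRecord | Iterable[CdsRecord]) -> Counter:
    """Pooled sense-codon counts (DNA spelling) for one or many genes."""
    if isinstance(records, CdsRecord):
        records = [records]
    counts: Counter = Counter()
    for rec in records:
        counts.update(coding_codons(rec))
    return counts


def codon_composition(cds: CdsRecord) -> CodonStats:
    """Positional base composition and ENC for one unflagged CDS.

    The stop codon is excluded from every tally and the start codon is
    included.  A3/T3/G3/C3 and GC3s are taken over the synonymously-variable
    codons only (AUG and UGG excluded); GC1/GC2/GC3/GCall run over all
    remaining codons.
    """
    codons = coding_codons(cds)
    if not codons:
        raise ValueError(f"{cds.gene_name}: no analyzable codons")
    n = len(codons)
    gc1 = sum(c[0] in _GC for c in codons) / n
    gc2 = sum(c[1] in _GC for c in codons) / n
    gc3 = sum(c[2] in _GC for c in codons) / n
    gc_all = (gc1 + gc2 + gc3) / 3
    syn = [c for c in codons if c in SYNONYMOUS_CODONS]
    if syn:
        third = [c[2] for c in syn]
        m = len(syn)
        a3 = third.count("A") / m
        t3 = third.count("T") / m
        g3 = third.count("G") / m
        c3 = third.count("C") / m
        gc3s = (third.count("G") + third.count("C")) / m
    else:
        a3 = t3 = g3 = c3 = float("nan")
        gc3s = None
    return CodonStats(
        gene_name=cds.gene_name, length_nt=cds.length_nt,
        a3=a3, t3=t3, g3=g3, c3=c3,
        gc1=gc1, gc2=gc2, gc3=gc3, gc3s=gc3s, gc_all=gc_all,
        enc=enc(Counter(codons)),
    )


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

def rscu(codon_counts: Mapping[str, int]) -> dict[str, float | None]:
    """RSCU per sense codon (RNA keys).

    Families with zero observations yield ``None`` (undefined, not 0).
    Met (AUG) and Trp (UGG) carry RSCU 1 by definition when observed.
    """
    counts = {to_dna(c): v for c, v in codon_counts.items()}
    out: dict[str, float | None] = {}
    for aa, codons in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            if total == 0:
                out[to_rna(c)] = None
            elif k == 1:
                out[to_rna(c)] = 1.0
            else:
                out[to_rna(c)] = counts.get(c, 0) * k / total
    return out


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------

def _family_homozygosity(ns: Sequence[int]) -> float | None:
    n = sum(ns)
    if n < 2:
        return None
    p2 = sum((x / n) ** 2 for x in ns)
    return (n * p2 - 1) / (n - 1)


def enc(codon_counts: Mapping[str, int]) -> float | None:
    """Wright's effective number of codons for one gene.

    Six-fold families (Leu, Ser, Arg) are kept six-fold.  A missing
    three-fold class (Ile unobserved) is imputed as the mean of the two- and
    four-fold class averages; a missing two-, four- or six-fold class makes
    the estimate undefined (``None``).  Values are capped at 61.
    """
    counts = {to_dna(c): v for c, v in codon_counts.items()}
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in DEGENERATE_FAMILIES.items():
        f = _family_homozygosity([counts.get(c, 0) for c in codons])
        if f is not None:
            per_class[len(codons)].append(f)
    fbar: dict[int, float | None] = {
        k: (sum(v) / len(v) if v else None) for k, v in per_class.items()}
    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if any(fbar[k] is None or fbar[k] <= 0 for k in (2, 3, 4, 6)):
        return None
    nc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(nc, 61.0)


def enc_expected(gc3: float) -> float:
    """Mutation-pressure-only ENC at a given third-position GC content.

    The standard null curve: ENC = 2 + GC3 + 29 / (GC3^2 + (1 - GC3)^2).
    """
    if not 0 <= gc3 <= 1:
        raise ValueError("gc3 must lie in [0, 1]")
    return 2 + gc3 + 29 / (gc3 ** 2 + (1 - gc3) ** 2)


# ---------------------------------------------------------------------------
# plot datasets
# ---------------------------------------------------------------------------

def neutrality_regression(stats_list: Sequence[CodonStats]) -> dict:
    """GC12-on-GC3 ordinary least squares (the neutrality plot).

    A slope near 1 implicates directional mutation pressure acting on all
    codon positions alike; a flat slope implicates selective constraint on
    positions 1-2.  Reports the OLS slope/intercept, r-squared, the
    two-tailed p of the slope test and of the Pearson correlation (identical
    for simple OLS, both emitted for completeness), and the counts of genes
    above/below the y = x diagonal.
    """
    if len(stats_list) < 3:
        raise ValueError("need at least 3 genes for a regression")
    x = np.array([s.gc3 for s in stats_list])
    y = np.array([s.gc12 for s in stats_list])
    if np.allclose(x, x[0]):
        raise ValueError("GC3 has zero variance; slope undefined")
    fit = sps.linregress(x, y)
    if np.allclose(y, y[0]):
        r, p_corr = float("nan"), float("nan")  # correlation undefined
    else:
        r, p_corr = sps.pearsonr(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
        "p_slope_two_tailed": float(fit.pvalue),
        "p_correlation_two_tailed": float(p_corr),
        "n_above_diagonal": int(np.sum(y > x)),
        "n_below_diagonal": int(np.sum(y < x)),
        "points": [(float(a), float(b)) for a, b in zip(x, y)],
    }


def pr2_coordinates(stats_list: Sequence[CodonStats]) -> dict:
    """Parity-rule-2 plot data: x = G3/(G3+C3), y = A3/(A3+T3) per gene.

    (0.5, 0.5) is the no-bias point.  Genes with a zero denominator get a
    missing coordinate and are excluded from the quadrant tallies.
    """
    points = []
    quadrants = {"x>0.5,y>0.5": 0, "x<0.5,y>0.5": 0,
                 "x<0.5,y<0.5": 0, "x>0.5,y<0.5": 0, "boundary": 0}
    for s in stats_list:
        x = s.g3 / (s.g3 + s.c3) if (s.g3 + s.c3) > 0 else None
        y = s.a3 / (s.a3 + s.t3) if (s.a3 + s.t3) > 0 else None
        points.append({"gene": s.gene_name, "x": x, "y": y})
        if x is None or y is None:
            continue
        if x == 0.5 or y == 0.5:
            quadrants["boundary"] += 1
        else:
            key = f"x{'>' if x > 0.5 else '<'}0.5,y{'>' if y > 0.5 else '<'}0.5"
            quadrants[key] += 1
    return {"points": points, "quadrants": quadrants}


CORRELATION_VARIABLES = ("GC1", "GC2", "GC3", "GC3s", "GCall", "ENC", "Length")


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlation_matrix(stats_list: Sequence[CodonStats]) -> dict:
    """Pairwise Pearson correlations over the seven codon parameters.

    Returns symmetric DataFrames of coefficients, two-tailed p-values and
    significance stars (0.05 / 0.01 / 0.001); pairs involving a constant
    column are NaN.  Genes lacking a defined value (e.g. ENC) are dropped
    pairwise.
    """
    if len(stats_list) < 3:
        raise ValueError("need at least 3 genes")
    cols = {
        "GC1": [s.gc1 for s in stats_list],
        "GC2": [s.gc2 for s in stats_list],
        "GC3": [s.gc3 for s in stats_list],
        "GC3s": [np.nan if s.gc3s is None else s.gc3s for s in stats_list],
        "GCall": [s.gc_all for s in stats_list],
        "ENC": [np.nan if s.enc is None else s.enc for s in stats_list],
        "Length": [s.length_nt for s in stats_list],
    }
    df = pd.DataFrame(cols)
    k = len(CORRELATION_VARIABLES)
    r = pd.DataFrame(np.eye(k), index=CORRELATION_VARIABLES,
                     columns=CORRELATION_VARIABLES)
    p = pd.DataFrame(np.zeros((k, k)), index=CORRELATION_VARIABLES,
                     columns=CORRELATION_VARIABLES)
    for i, vi in enumerate(CORRELATION_VARIABLES):
        for j, vj in enumerate(CORRELATION_VARIABLES):
            if i >= j:
                continue
            sub = df[[vi, vj]].dropna()
            xi, xj = sub[vi].to_numpy(), sub[vj].to_numpy()
            if len(sub) < 3 or np.allclose(xi, xi[0]) or np.allclose(xj, xj[0]):
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(xi, xj)
            r.loc[vi, vj] = r.loc[vj, vi] = rij
            p.loc[vi, vj] = p.loc[vj, vi] = pij
    stars = p.map(lambda v: "" if np.isnan(v) else _stars(v))
    np.fill_diagonal(stars.values, "")
    return {"r": r, "p": p, "stars": stars, "n_genes": len(stats_list)}


# ---------------------------------------------------------------------------
# optimal codons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimalCodonReport:
    high_pool: tuple[str, ...]   # lowest-ENC decile (putative high expression)
    low_pool: tuple[str, ...]    # highest-ENC decile
    table: pd.DataFrame          # per-codon RSCU_all/high/low, dRSCU, flags

    @property
    def optimal(self) -> list[str]:
        return sorted(self.table.index[self.table["optimal"]])

    @property
    def high_frequency(self) -> list[str]:
        return sorted(self.table.index[self.table["high_frequency"]])


def optimal_codons(entries: Sequence[tuple[str, Mapping[str, int], float]],
                   delta_threshold: float = 0.08) -> OptimalCodonReport:
    """Identify optimal codons from (gene, codon counts, ENC) triples.

    Genes sort ascending by ENC (ties broken by name); the first
    ceil(0.1 * n) genes form the high-expression pool, the last ceil(0.1 * n)
    the low-expression pool.  dRSCU = RSCU_high - RSCU_low.  Optimal means
    pooled-all RSCU > 1 and dRSCU >= delta_threshold.
    """
    n = len(entries)
    m = math.ceil(0.1 * n)
    if 2 * m > n:
        raise ValueError(
            f"{n} genes cannot form two disjoint {m}-gene decile pools")
    order = sorted(entries, key=lambda e: (float("inf") if e[2] is None
                                           else e[2], e[0]))
    high = order[:m]
    low = order[-m:]

    def pool_counts(pool) -> Counter:
        c: Counter = Counter()
        for _, counts, _ in pool:
            c.update({to_dna(k): v for k, v in counts.items()})
        return c

    rscu_all = rscu(pool_counts(order))
    rscu_high = rscu(pool_counts(high))
    rscu_low = rscu(pool_counts(low))
    rows = []
    for codon in sorted(to_rna(c) for c in SENSE_CODONS):
        rh, rl, ra = rscu_high[codon], rscu_low[codon], rscu_all[codon]
        delta = None if rh is None or rl is None else rh - rl
        hf = ra is not None and ra > 1
        he = delta is not None and delta >= delta_threshold
        rows.append({"codon": codon, "amino_acid": GENETIC_CODE[to_dna(codon)],
                     "rscu_all": ra, "rscu_high": rh, "rscu_low": rl,
                     "delta_rscu": delta, "high_frequency": hf,
                     "high_expression": he, "optimal": hf and he})
    table = pd.DataFrame(rows).set_index("codon")
    return OptimalCodonReport(
        high_pool=tuple(name for name, _, _ in high),
        low_pool=tuple(name for name, _, _ in low),
        table=table,
    )


def optimal_codons_from_cds(records: Sequence[CdsRecord],
                            delta_threshold: float = 0.08
                            ) -> OptimalCodonReport:
    """Convenience wrapper running the full per-gene pipeline first."""
    entries = []
    for rec in records:
        counts = count_codons(rec)
        entries.append((rec.gene_name, counts, enc(counts)))
    return optimal_codons(entries, delta_threshold=delta_threshold)
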