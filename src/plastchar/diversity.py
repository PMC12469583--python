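"""Nucleotide diversity (pi) from per-gene alignments, DnaSP-style.

Pi is the mean number of pairwise differences per site: the sum of Hamming
distances over all unordered sequence pairs, divided by C(n, 2) and by the
number of retained sites.  Sites containing any gap or ambiguous base are
excluded entirely (complete deletion), and no multiple-hit correction is
applied — matching the headline Pi of standard population-genetics software.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GeneAlignment, GenomeRecord, extract_cds, splice

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class PiResult:
    gene_name: str
    pi: float | None          # None when no site survives complete deletion
    n_taxa: int
    sites_used: int
    windows: tuple[tuple[int, int, float | None], ...] = ()


def _matrix(aln: GeneAlignment) -> np.ndarray:
    return np.array([np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                     for _, seq in aln.rows])


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of columns where every row holds an unambiguous base."""
    ok = np.zeros(mat.shape, dtype=bool)
    for b in _ACGT:
        ok |= mat == b
    return ok.all(axis=0)


def _pi_on(mat: np.ndarray) -> tuple[float | None, int]:
    n = mat.shape[0]
    keep = _complete_columns(mat)
    sites = int(keep.sum())
    if sites == 0:
        return None, 0
    sub = mat[:, keep]
    total = 0
    for i, j in combinations(range(n), 2):
        total += int(np.count_nonzero(sub[i] != sub[j]))
    npairs = n * (n - 1) // 2
    return total / npairs / sites, sites


def gene_pi(aln: GeneAlignment) -> PiResult:
    """Whole-gene pi: one window spanning the alignment."""
    if aln.ntaxa < 2:
        raise ValueError("pi needs at least two sequences")
    mat = _matrix(aln)
    pi, sites = _pi_on(mat)
    return PiResult(gene_name=aln.gene_name, pi=pi, n_taxa=aln.ntaxa,
                    sites_used=sites,
                    windows=((0, aln.ncol, pi),))


def sliding_pi(aln: GeneAlignment, window: int,
               step: int = 25) -> list[tuple[int, int, float | None]]:
    """Per-window pi over alignment columns.

    Windows advance by ``step``; a final partial window is included when at
    least ``step`` columns remain past the last full window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if window > aln.ncol:
        raise ValueError(f"window {window} exceeds alignment length {aln.ncol}")
    mat = _matrix(aln)
    out: list[tuple[int, int, float | None]] = []
    start = 0
    while start < aln.ncol:
        end = min(start + window, aln.ncol)
        if end - start < window:
            # trailing partial window: kept when at least `step` columns remain
            if end - start >= step:
                pi, _ = _pi_on(mat[:, start:end])
                out.append((start, end, pi))
            break
        pi, _ = _pi_on(mat[:, start:end])
        out.append((start, end, pi))
        if end == aln.ncol:
            break
        start += step
    return out


def rank_hypervariable(results: Sequence[PiResult],
                       threshold: float = 0.08) -> list[PiResult]:
    """Genes with pi strictly above the threshold, highest first.

    Ties break alphabetically on the gene name.
    """
    hits = [r for r in results if r.pi is not None and r.pi > threshold]
    return sorted(hits, key=lambda r: (-r.pi, r.gene_name))


def extract_shared_genes(genomes: Sequence[GenomeRecord],
                         out_dir: str | Path | None = None
                         ) -> dict[str, list[tuple[str, str]]]:
    """Unaligned per-gene sequence sets for genes shared by all genomes.

    Intersects CDS gene names across the parsed records and returns, per
    gene, one spliced sequence per genome (the retained, non-IR-duplicate
    copy).  Writes one FASTA per gene when ``out_dir`` is given; alignment
    itself is left to external tools.
    """
    per_genome: list[dict[str, str]] = []
    for g in genomes:
        seqs: dict[str, str] = {}
        for rec in extract_cds(g):
            if "ir_duplicate" in rec.filter_flags:
                continue
            seqs.setdefault(rec.gene_name, rec.sequence)
        per_genome.append(seqs)
    shared = set(per_genome[0])
    for seqs in per_genome[1:]:
        shared &= set(seqs)
    out: dict[str, list[tuple[str, str]]] = {}
    for gene in sorted(shared):
        out[gene] = [(g.id, seqs[gene])
                     for g, seqs in zip(genomes, per_genome)]
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for gene, rows in out.items():
            with open(out_path / f"{gene}.fasta", "w") as fh:
                for tid, seq in rows:
                    fh.write(f">{tid}\n{seq}\n")
    return out
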