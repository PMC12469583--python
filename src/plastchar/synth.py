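"""Seeded synthetic plastomes, CDS sets and alignments with planted truth.

The generator emulates a moss-like chloroplast genome: a ~124 kb circle of
LSC + IRb + SSC + IRa where IRa is the exact reverse complement of IRb,
AT-rich single-copy regions and GC-rich IRs, annotated CDS/tRNA/rRNA
features (including IR-duplicated and intron-split genes), planted SSRs of
all six motif classes, and planted F/P/R/C dispersed repeats.  Every planted
element is returned in a ground-truth manifest so detectors can be checked
for exact-coordinate recovery.

Planted elements are "sealed": the bases immediately flanking a planted SSR
or repeat are forced to break the repeat pattern, so the maximal element the
scanners report has exactly the planted coordinates.  Dispersed repeats are
planted carrying the scanner's full mismatch budget for the same reason — a
pair with spare budget would lawfully extend past its flanks.

All randomness flows from one integer seed through a single numpy
Generator; sequence construction uses integer draws only, so output is
byte-identical across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import complement, revcomp
from .genome_io import CdsRecord, Feature, GenomeRecord
from .codon_usage import DEGENERATE_FAMILIES, GENETIC_CODE

BASES = "ACGT"


# ---------------------------------------------------------------------------
# codon-usage profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CubProfile:
    """Per-family codon probabilities used to sample synthetic CDS.

    ``family_probs`` maps amino acid -> {DNA codon -> probability}; each
    family's probabilities sum to 1.  Only the 18 synonymously-variable
    families are sampled (Met and Trp would pin composition).
    """

    family_probs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for aa, probs in self.family_probs.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"family {aa} probabilities sum to {total}")

    @staticmethod
    def uniform() -> "CubProfile":
        return CubProfile({
            aa: {c: 1 / len(cs) for c in cs}
            for aa, cs in DEGENERATE_FAMILIES.items()
        })

    @staticmethod
    def from_at_bias(at_bias_3: float) -> "CubProfile":
        """Tilt third-position usage toward A/T.

        ``at_bias_3`` = 0 is uniform; 1 confines usage to A/T-ending codons
        (every degenerate family has at least one).
        """
        if not 0 <= at_bias_3 <= 1:
            raise ValueError("at_bias_3 must lie in [0, 1]")
        fams = {}
        for aa, cs in DEGENERATE_FAMILIES.items():
            at = [c for c in cs if c[2] in "AT"]
            probs = {}
            for c in cs:
                p = (1 - at_bias_3) / len(cs)
                if c in at:
                    p += at_bias_3 / len(at)
                probs[c] = p
            fams[aa] = probs
        return CubProfile(fams)

    @staticmethod
    def deterministic(choices: Mapping[str, str]) -> "CubProfile":
        """Probability 1 on one chosen codon per family (ENC -> 20 genes)."""
        fams = {}
        for aa, cs in DEGENERATE_FAMILIES.items():
            pick = choices.get(aa, cs[0])
            if pick not in cs:
                raise ValueError(f"{pick} does not encode {aa}")
            fams[aa] = {c: (1.0 if c == pick else 0.0) for c in cs}
        return CubProfile(fams)

    @staticmethod
    def concentrated(choices: Mapping[str, str], weight: float) -> "CubProfile":
        """Put ``weight`` on the chosen codon, the rest spread uniformly."""
        fams = {}
        for aa, cs in DEGENERATE_FAMILIES.items():
            pick = choices.get(aa, cs[0])
            k = len(cs)
            fams[aa] = {c: (weight + (1 - weight) / k if c == pick
                            else (1 - weight) / k) for c in cs}
        return CubProfile(fams)


def _sample_codons(rng: np.random.Generator, n_codons: int,
                   profile: CubProfile) -> list[str]:
    aas = sorted(profile.family_probs)
    aa_idx = rng.integers(0, len(aas), size=n_codons)
    out = []
    for i in aa_idx:
        probs = profile.family_probs[aas[i]]
        codons = sorted(probs)
        p = np.array([probs[c] for c in codons])
        out.append(codons[rng.choice(len(codons), p=p / p.sum())])
    return out


def generate_cds_set(n_genes: int, mean_codons: int, profile: CubProfile,
                     seed: int, name_prefix: str = "g") -> list[CdsRecord]:
    """Sample CDS records that pass every analysis filter by construction.

    Codons are drawn family-by-family from the profile; an ATG start and a
    TAA stop are appended.  Gene lengths are Poisson around ``mean_codons``
    with a floor of 101 interior codons (so length > 300 nt holds).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genes):
        n = max(101, int(rng.poisson(mean_codons)))
        codons = ["ATG"] + _sample_codons(rng, n, profile) + ["TAA"]
        records.append(CdsRecord(
            gene_name=f"{name_prefix}{i + 1:03d}",
            codons=tuple(codons),
            filter_flags=frozenset(),
        ))
    return records


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def mutation_rate_for_pi(pairwise_diversity: float) -> float:
    """Per-site, per-row mutation probability giving the target expected pi.

    Each row mutates independently from a common ancestor; a mutated base is
    uniform over the three alternatives, so a pair differs at a site with
    probability 2*mu*(1-mu) + (2/3)*mu**2; solving for mu inverts that.
    """
    if not 0 <= pairwise_diversity <= 0.75:
        raise ValueError("pairwise_diversity must lie in [0, 0.75]")
    pi = pairwise_diversity
    # (4/3) mu^2 - 2 mu + pi = 0, smaller root
    return float((2 - np.sqrt(4 - 16 * pi / 3)) / (8 / 3))


def generate_alignment(n_taxa: int, length: int, pairwise_diversity: float,
                       seed: int, gene_name: str = "synthetic"):
    """Gap-free alignment whose expected pi equals ``pairwise_diversity``."""
    from .genome_io import GeneAlignment
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    mu = mutation_rate_for_pi(pairwise_diversity)
    ancestor = rng.integers(0, 4, size=length)
    rows = []
    for t in range(n_taxa):
        mask = rng.random(length) < mu
        shift = rng.integers(1, 4, size=length)
        seq = np.where(mask, (ancestor + shift) % 4, ancestor)
        rows.append((f"taxon{t + 1}",
                     "".join(BASES[b] for b in seq)))
    return GeneAlignment(gene_name=gene_name, rows=tuple(rows))


# ---------------------------------------------------------------------------
# plastome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One gene to plant: a CDS (n_codons) or a tRNA/rRNA (length_nt)."""

    name: str
    kind: str = "CDS"
    strand: str = "+"
    region: str = "lsc"          # lsc / irb / ssc (ira is derived)
    n_codons: int = 150
    length_nt: int | None = None  # for tRNA/rRNA
    offset: int | None = None     # explicit start relative to region start
    intron_len: int = 0           # 0 = no intron; else one intron mid-gene


@dataclass(frozen=True)
class PlastomeSpec:
    """Blueprint of a synthetic plastome; defaults mirror a moss plastome
    (124,264 bp total; LSC 85,572 / SSC 18,608 / IR 10,042; AT-rich single
    copies, GC-rich IRs giving ~28.7% overall GC)."""

    region_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"lsc": 85_572, "ssc": 18_608, "ir": 10_042})
    region_gc: Mapping[str, float] = field(
        default_factory=lambda: {"lsc": 0.260, "ssc": 0.251, "ir": 0.433})
    planted_ssrs: tuple[tuple[str, int, str], ...] = ()      # motif, units, region
    planted_repeats: tuple[tuple[str, int, int, tuple[str, str]], ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    cub_profile: CubProfile = field(
        default_factory=lambda: CubProfile.from_at_bias(0.6))
    seed: int = 0

    @property
    def total_length(self) -> int:
        return (self.region_lengths["lsc"] + self.region_lengths["ssc"]
                + 2 * self.region_lengths["ir"])


@dataclass(frozen=True)
class SyntheticPlastome:
    genome: GenomeRecord
    manifest: dict

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=1)


class _RegionAllocator:
    """Sequential slot allocator with randomized gaps inside one region.

    ``reserved`` intervals (explicitly placed genes, including junction-gene
    overhangs) are skipped.
    """

    def __init__(self, rng: np.random.Generator, length: int, name: str,
                 reserved: Sequence[tuple[int, int]] = (), margin: int = 300):
        self.rng = rng
        self.length = length
        self.name = name
        self.margin = margin
        self.cursor = margin
        self.reserved = sorted(reserved)

    def take(self, size: int) -> int:
        gap = int(self.rng.integers(60, 200))
        start = self.cursor + gap
        moved = True
        while moved:
            moved = False
            for rs, re in self.reserved:
                if start < re + 10 and rs - 10 < start + size:
                    start = re + 10 + gap
                    moved = True
        if start + size > self.length - self.margin:
            raise ValueError(
                f"region {self.name} overflows: planted elements need "
                f"{start + size} bp of {self.length}")
        self.cursor = start + size
        return start


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(4, size=length, p=probs)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return bytearray(lut[draw].tobytes())


def _force_differ(seq: bytearray, pos: int, forbidden: str) -> None:
    """Ensure seq[pos] is none of the forbidden bases (seal a flank)."""
    if chr(seq[pos]) in forbidden:
        for b in BASES:
            if b not in forbidden:
                seq[pos] = ord(b)
                return


def _cds_fragment(rng: np.random.Generator, gs: GeneSpec,
                  profile: CubProfile) -> str:
    codons = ["ATG"] + _sample_codons(rng, gs.n_codons, profile) + ["TAA"]
    return "".join(codons)


def generate_plastome(spec: PlastomeSpec) -> SyntheticPlastome:
    """Build the genome, plant every element, and record the ground truth.

    Region order on the circle is LSC, IRb, SSC, IRa with the LSC starting
    at position 0 (canonical orientation); IRa is written as the exact
    reverse complement of IRb after all IRb planting, so anything planted in
    IRb exists mirrored in IRa (and IR genes are annotated in both copies).
    """
    rng = np.random.default_rng(spec.seed)
    ll = spec.region_lengths["lsc"]
    ls = spec.region_lengths["ssc"]
    li = spec.region_lengths["ir"]
    starts = {"lsc": 0, "irb": ll, "ssc": ll + li, "ira": ll + li + ls}
    n = spec.total_length

    buf = {
        "lsc": _random_bases(rng, ll, spec.region_gc["lsc"]),
        "irb": _random_bases(rng, li, spec.region_gc["ir"]),
        "ssc": _random_bases(rng, ls, spec.region_gc["ssc"]),
    }
    # reserve footprints of explicitly placed genes (incl. junction
    # overhangs into the neighbouring region) before sequential allocation
    reserved: dict[str, list[tuple[int, int]]] = {r: [] for r in buf}
    order = ["lsc", "irb", "ssc"]
    for gs in spec.genes:
        if gs.offset is None:
            continue
        size = (3 * (gs.n_codons + 2) if gs.kind == "CDS"
                else (gs.length_nt or 80)) + gs.intron_len
        rlen = len(buf[gs.region])
        rel = gs.offset if gs.offset >= 0 else rlen + gs.offset
        reserved[gs.region].append((rel, min(rel + size, rlen)))
        over = rel + size - rlen
        if over > 0:
            if gs.region == "ssc":
                raise ValueError(f"gene {gs.name} overhangs into the derived IRa")
            nxt = order[order.index(gs.region) + 1]
            reserved[nxt].append((0, over))
    alloc = {r: _RegionAllocator(rng, len(buf[r]), r, reserved[r])
             for r in buf}

    features: list[Feature] = []
    manifest: dict = {
        "seed": spec.seed,
        "length": n,
        "regions": {"lsc": (0, ll), "irb": (ll, li),
                    "ssc": (ll + li, ls), "ira": (ll + li + ls, li)},
        "junctions": {"JLB": ll, "JSB": ll + li,
                      "JSA": ll + li + ls, "JLA": 0},
        "genes": [], "ssrs": [], "repeats": [],
    }

    # ---- genes -----------------------------------------------------------
    irb_features: list[Feature] = []
    for gs in spec.genes:
        if gs.region not in buf:
            raise ValueError(f"gene {gs.name}: region must be lsc/irb/ssc")
        if gs.kind == "CDS":
            body = _cds_fragment(rng, gs, spec.cub_profile)
        else:
            body = bytes(_random_bases(
                rng, gs.length_nt or 80, spec.region_gc["lsc"])).decode()
        if gs.intron_len > 0:
            e1 = len(body) // 2
            intron = bytes(_random_bases(
                rng, gs.intron_len, spec.region_gc[
                    "ir" if gs.region == "irb" else gs.region])).decode()
            genomic = body[:e1] + intron + body[e1:]
            exon_rel = [(0, e1), (e1 + gs.intron_len, len(genomic))]
        else:
            genomic = body
            exon_rel = [(0, len(genomic))]
        if gs.strand == "-":
            # mirror transcript coordinates; the mapped list stays in
            # transcription order (5' exon first)
            genomic = revcomp(genomic)
            L = len(genomic)
            exon_rel = [(L - e, L - s) for s, e in exon_rel]
        if gs.offset is not None:
            # offsets are python-slice style: >=0 from the region start,
            # negative from the region end (junction genes)
            rel = gs.offset if gs.offset >= 0 else len(buf[gs.region]) + gs.offset
        else:
            rel = alloc[gs.region].take(len(genomic))
        abs_start = starts[gs.region] + rel
        intervals = tuple((abs_start + s, abs_start + e) for s, e in exon_rel)
        feat = Feature(gene_name=gs.name, kind=gs.kind, strand=gs.strand,
                       intervals=intervals)
        features.append(feat)
        if gs.region == "irb" and all(
                ll <= s and e <= ll + li for s, e in intervals):
            irb_features.append(feat)
        manifest["genes"].append({
            "name": gs.name, "kind": gs.kind, "strand": gs.strand,
            "region": gs.region, "intervals": [list(iv) for iv in intervals],
        })
        # write into the region buffer (clipped parts handled post-assembly)
        _write_fragment(buf, starts, gs.region, rel, genomic)

    # ---- SSRs ------------------------------------------------------------
    for motif, units, region in spec.planted_ssrs:
        if not (1 <= len(motif) <= 6):
            raise ValueError(f"SSR motif {motif} must be 1-6 nt")
        from .repeats import _is_primitive
        if not _is_primitive(motif):
            raise ValueError(f"SSR motif {motif} is not primitive")
        run = motif * units
        rel = alloc[region].take(len(run))
        b = buf[region]
        b[rel:rel + len(run)] = run.encode()
        # seal flanks so the maximal run is exactly the planted one
        _force_differ(b, rel - 1, motif[-1])
        _force_differ(b, rel + len(run), motif[0])
        start = starts[region] + rel
        manifest["ssrs"].append({
            "motif": motif, "unit_count": units,
            "start": start, "end": start + len(run), "region": region,
        })

    # ---- dispersed repeats ----------------------------------------------
    for rtype, length, mismatches, (ra, rb) in spec.planted_repeats:
        if rtype not in "FPRC":
            raise ValueError(f"unknown repeat type {rtype}")
        w = bytes(_random_bases(rng, length, 0.5)).decode()
        image = {"F": lambda x: x, "P": revcomp,
                 "R": lambda x: x[::-1], "C": complement}[rtype](w)
        image_b = bytearray(image, "ascii")
        pos_choices = rng.choice(np.arange(2, length - 2), size=mismatches,
                                 replace=False) if mismatches else []
        for q in pos_choices:
            cur = chr(image_b[q])
            alts = [x for x in BASES if x != cur]
            image_b[q] = ord(alts[int(rng.integers(0, 3))])
        rel1 = alloc[ra].take(length)
        rel2 = alloc[rb].take(length)
        buf[ra][rel1:rel1 + length] = w.encode()
        buf[rb][rel2:rel2 + length] = bytes(image_b)
        p1 = starts[ra] + rel1
        p2 = starts[rb] + rel2
        _seal_repeat_flanks(buf, ra, rel1, rb, rel2, length, rtype)
        a, b2 = sorted((p1, p2))
        manifest["repeats"].append({
            "type": rtype, "pos1": a, "pos2": b2,
            "length": length, "mismatches": mismatches,
        })

    # ---- assemble --------------------------------------------------------
    # seal the IR boundaries so the exact reverse-complement match ends
    # precisely at the planted junctions (circular pairing: left of IRb
    # pairs with position 0; SSC start pairs with SSC end)
    lsc_b, irb_b, ssc_b = buf["lsc"], buf["irb"], buf["ssc"]
    _force_differ(lsc_b, ll - 1, complement(chr(lsc_b[0])))
    _force_differ(ssc_b, 0, complement(chr(ssc_b[ls - 1])))
    ira = revcomp(bytes(irb_b).decode())
    sequence = (bytes(lsc_b) + bytes(irb_b) + bytes(ssc_b)).decode() + ira

    # mirror IRb gene annotations into IRa
    for f in irb_features:
        mirrored = []
        for s, e in f.intervals:
            rs, re = s - ll, e - ll
            mirrored.append((starts["ira"] + li - re, starts["ira"] + li - rs))
        feat = Feature(gene_name=f.gene_name, kind=f.kind,
                       strand="-" if f.strand == "+" else "+",
                       intervals=tuple(mirrored))
        features.append(feat)
        manifest["genes"].append({
            "name": feat.gene_name, "kind": feat.kind, "strand": feat.strand,
            "region": "ira",
            "intervals": [list(iv) for iv in feat.intervals],
        })

    genome = GenomeRecord(id=f"synthetic_{spec.seed}", sequence=sequence,
                          circular=True, features=tuple(features))
    return SyntheticPlastome(genome=genome, manifest=manifest)


def _write_fragment(buf, starts, region, rel, fragment: str) -> None:
    b = buf[region]
    if 0 <= rel and rel + len(fragment) <= len(b):
        b[rel:rel + len(fragment)] = fragment.encode()
        return
    # overhang into the neighbouring region (junction genes): write the
    # in-region part here, the rest into the adjacent buffer
    order = ["lsc", "irb", "ssc"]
    if rel < 0:
        raise ValueError("fragment start precedes its region")
    over = rel + len(fragment) - len(b)
    idx = order.index(region)
    if idx + 1 >= len(order):
        raise ValueError("fragment overhangs past the SSC into the derived IRa")
    nxt = order[idx + 1]
    if over > len(buf[nxt]):
        raise ValueError("fragment overhangs beyond the adjacent region")
    b[rel:] = fragment[: len(fragment) - over].encode()
    buf[nxt][:over] = fragment[len(fragment) - over:].encode()


def _seal_repeat_flanks(buf, ra: str, rel1: int, rb: str, rel2: int,
                        length: int, rtype: str) -> None:
    """Force the bases just outside a planted pair to mismatch under the
    pair's transform, making the planted window maximal."""
    b1, b2 = buf[ra], buf[rb]
    if rtype in ("F",):
        _force_differ(b2, rel2 - 1, chr(b1[rel1 - 1]))
        _force_differ(b2, rel2 + length, chr(b1[rel1 + length]))
    elif rtype == "C":
        _force_differ(b2, rel2 - 1, complement(chr(b1[rel1 - 1])))
        _force_differ(b2, rel2 + length, complement(chr(b1[rel1 + length])))
    elif rtype in ("P", "R"):
        # left of copy1 pairs with right of copy2 and vice versa
        c1l = chr(b1[rel1 - 1])
        c1r = chr(b1[rel1 + length])
        if rtype == "P":
            _force_differ(b2, rel2 + length, complement(c1l))
            _force_differ(b2, rel2 - 1, complement(c1r))
        else:
            _force_differ(b2, rel2 + length, c1l)
            _force_differ(b2, rel2 - 1, c1r)


# ---------------------------------------------------------------------------
# ready-made study-scale spec
# ---------------------------------------------------------------------------

def default_plastome_spec(seed: int = 0) -> PlastomeSpec:
    """A full-scale synthetic plastome exercising every detector.

    Region sizes and GC mirror the moss plastome the package targets;
    planted SSRs cover all six motif classes at (or above) their thresholds,
    planted dispersed repeats cover all four types at the scanner's mismatch
    budget, and the gene set includes junction genes (trnM near JLB, ndhF
    crossing JSB by 76 bp, chlL near JSA), an intron-split gene, and an
    IR-duplicated gene.
    """
    genes = [
        GeneSpec("psbA", "CDS", "+", "lsc", n_codons=350),
        GeneSpec("matK", "CDS", "-", "lsc", n_codons=500),
        GeneSpec("atpF", "CDS", "+", "lsc", n_codons=180, intron_len=700),
        GeneSpec("rpoC2", "CDS", "+", "lsc", n_codons=1400),
        GeneSpec("rbcL", "CDS", "+", "lsc", n_codons=475),
        GeneSpec("trnG-UCC", "tRNA", "+", "lsc", length_nt=72),
        GeneSpec("rpl23", "CDS", "+", "lsc", n_codons=101,
                 offset=-(3 * 103 + 500)),
        GeneSpec("trnM", "tRNA", "+", "lsc", length_nt=73, offset=-(73 + 62)),
        GeneSpec("ndhB", "CDS", "+", "irb", n_codons=510, intron_len=680),
        GeneSpec("trnN", "tRNA", "-", "irb", length_nt=72),
        # ndhF starts 76 bp before the IRb end, crossing JSB into the SSC
        GeneSpec("ndhF", "CDS", "+", "irb", n_codons=700, offset=-76),
        GeneSpec("ndhG", "CDS", "-", "ssc", n_codons=200, offset=9000),
        GeneSpec("ycf1", "CDS", "+", "ssc", n_codons=1500, offset=10_500),
        # chlL ends exactly 60 bp before JSA
        GeneSpec("chlL", "CDS", "+", "ssc", n_codons=290,
                 offset=-(3 * 292 + 60)),
    ]
    ssrs = [
        ("T", 12, "lsc"), ("A", 10, "lsc"), ("AT", 7, "lsc"),
        ("TA", 6, "ssc"), ("AAT", 4, "lsc"), ("ATAG", 3, "ssc"),
        ("AATAT", 3, "lsc"), ("ATATGC", 3, "irb"),
    ]
    repeats = [
        ("F", 42, 3, ("lsc", "lsc")),
        ("P", 38, 3, ("lsc", "ssc")),
        ("R", 35, 3, ("lsc", "lsc")),
        ("C", 40, 3, ("ssc", "ssc")),
        ("F", 61, 3, ("lsc", "ssc")),
    ]
    return PlastomeSpec(planted_ssrs=tuple(ssrs),
                        planted_repeats=tuple(repeats),
                        genes=tuple(genes), seed=seed)


def generate_specimen_pair(seed: int = 0) -> tuple[SyntheticPlastome,
                                                   SyntheticPlastome]:
    """Two near-identical plastomes (a specimen I/II surface).

    The second genome differs by slightly longer regions, one extra planted
    SSR, and a slightly stronger third-position A/T bias, emulating two
    conspecific assemblies whose codon-usage reports share most — but not
    all — optimal codons.
    """
    spec1 = default_plastome_spec(seed)
    spec2 = PlastomeSpec(
        region_lengths={"lsc": 85_731, "ssc": 18_609, "ir": 10_050},
        region_gc=spec1.region_gc,
        planted_ssrs=spec1.planted_ssrs + (("AT", 6, "lsc"),),
        planted_repeats=spec1.planted_repeats,
        genes=spec1.genes,
        cub_profile=CubProfile.from_at_bias(0.65),
        seed=seed + 1,
    )
    return generate_plastome(spec1), generate_plastome(spec2)
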