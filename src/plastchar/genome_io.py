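"""Genome records, GenBank/FASTA I/O, CDS extraction and gene classification.

Internal coordinates are 0-based half-open throughout; GenBank's 1-based
inclusive convention is applied only at the file boundary (Biopython does the
translation).  Feature intervals are stored in *transcription order*: the
first interval is the 5'-most exon, and each interval's contribution to the
spliced product is the reverse complement of its forward-strand slice when
the feature lies on the minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp, validate_dna

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
MIN_CDS_NT = 300  # analysis set keeps strictly longer CDS

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")


@dataclass(frozen=True)
class Feature:
    """One annotated, possibly multi-interval (intron-split) gene feature."""

    gene_name: str
    kind: str  # CDS / tRNA / rRNA / other
    strand: str  # '+' or '-'
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open, transcription order
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        for s, e in self.intervals:
            if not 0 <= s < e:
                raise ValueError(f"bad interval ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) across all intervals."""
        return (min(s for s, _ in self.intervals), max(e for _, e in self.intervals))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class GenomeRecord:
    """A (typically circular) plastome: sequence plus typed feature annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        validate_dna(self.sequence)
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if e > n:
                    raise ValueError(
                        f"feature {f.gene_name} interval ({s}, {e}) exceeds "
                        f"genome length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """A spliced, strand-resolved coding sequence with its filter verdict."""

    gene_name: str
    codons: tuple[str, ...]
    source_region: str | None = None  # LSC / SSC / IRa / IRb / spanning
    filter_flags: frozenset[str] = frozenset()

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def passes(self) -> bool:
        return not self.filter_flags

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass(frozen=True)
class GeneAlignment:
    """A gapped multi-sequence alignment for one gene."""

    gene_name: str
    rows: tuple[tuple[str, str], ...]  # (taxon id, aligned sequence)

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment rows")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ntaxa(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------

def splice(feature: Feature, sequence: str) -> str:
    """Spliced, strand-resolved sequence of a feature.

    Intervals are concatenated in the order stored (transcription order); each
    minus-strand interval contributes the reverse complement of its forward
    slice.  Matches Biopython's ``SeqFeature.extract`` for the location
    grammars emitted by plastome annotations (``join``, ``complement(join)``).
    """
    parts = []
    for s, e in feature.intervals:
        frag = sequence[s:e]
        parts.append(revcomp(frag) if feature.strand == "-" else frag)
    return "".join(parts)


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_from_biopython(bf: SeqFeature, seq: str) -> Feature:
    name = bf.qualifiers.get("gene", bf.qualifiers.get("locus_tag", ["?"]))[0]
    kind = _KIND_MAP.get(bf.type, "other")
    strand = "-" if bf.location.strand == -1 else "+"
    # Biopython stores compound-location parts in transcription order (it
    # reverses complement(join(...)) grammars on parse), which is exactly
    # our interval convention.
    parts = [(int(p.start), int(p.end)) for p in bf.location.parts]
    feat = Feature(gene_name=name, kind=kind, strand=strand,
                   intervals=tuple(parts),
                   notes=bf.qualifiers.get("product", [""])[0])
    # Validate against Biopython's own extraction; fall back to reversed
    # order for any location grammar stored the other way around.
    expected = str(bf.extract(Seq(seq)))
    if splice(feat, seq) != expected:
        alt = replace(feat, intervals=tuple(reversed(parts)))
        if splice(alt, seq) == expected:
            feat = alt
        else:  # pragma: no cover - no known grammar reaches here
            logger.warning("could not reproduce extraction for %s; keeping "
                           "transcription-order interpretation", name)
    return feat


def read_genbank(path: str | Path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Join/complement locations become interval lists, coordinates become
    0-based half-open, and the circular flag is read from the LOCUS line.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"GenBank file {path} has no usable ORIGIN sequence")
    validate_dna(seq)
    circular = record.annotations.get("topology", "linear") == "circular"
    feats = tuple(
        _feature_from_biopython(bf, seq)
        for bf in record.features
        if bf.type in ("CDS", "tRNA", "rRNA")
    )
    return GenomeRecord(id=record.id, sequence=seq, circular=circular, features=feats)


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Emit a GenBank flat file that :func:`read_genbank` round-trips."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.features.append(
        SeqFeature(SimpleLocation(0, len(genome.sequence)), type="source")
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        # parts listed in transcription order; Biopython renders the
        # complement(join(...)) grammar from them
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.gene_name]}
        if f.notes:
            qualifiers["product"] = [f.notes]
        record.features.append(SeqFeature(loc, type=f.kind, qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path: str | Path) -> GenomeRecord:
    record = SeqIO.read(str(path), "fasta")
    return GenomeRecord(id=record.id, sequence=str(record.seq).upper())


def write_fasta(genome: GenomeRecord, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


def read_alignment(path: str | Path, gene_name: str | None = None) -> GeneAlignment:
    """Read an aligned multi-FASTA; rows must share one length."""
    path = Path(path)
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    ref = len(rows[0][1])
    ragged = [tid for tid, seq in rows if len(seq) != ref]
    if ragged:
        raise ValueError(
            f"alignment {path} has ragged rows (length != {ref}) for taxa: "
            + ", ".join(ragged)
        )
    return GeneAlignment(gene_name=gene_name or path.stem, rows=tuple(rows))


def write_alignment(aln: GeneAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, seq in aln.rows:
            fh.write(f">{tid}\n{seq}\n")


# ---------------------------------------------------------------------------
# CDS extraction + filtering
# ---------------------------------------------------------------------------

def _locate_region(feature: Feature, layout) -> str | None:
    if layout is None:
        return None
    regions = {}
    for name in ("lsc", "irb", "ssc", "ira"):
        start, length = getattr(layout, name)
        regions[name.upper().replace("IRA", "IRa").replace("IRB", "IRb")] = (
            start, length)
    hits = set()
    n = layout.genome_length
    for s, e in feature.intervals:
        mid = (s + e) // 2
        for rname, (rs, rl) in regions.items():
            if (mid - rs) % n < rl:
                hits.add(rname)
                break
    if len(hits) == 1:
        return hits.pop()
    return "spanning"


def extract_cds(genome: GenomeRecord, layout=None) -> list[CdsRecord]:
    """Splice every CDS feature and apply the analysis-set filters.

    Flags rather than failures: ``too_short`` (spliced length not > 300 nt),
    ``bad_start`` (first codon not ATG), ``bad_stop`` (last codon not a
    standard stop), ``internal_stop``, ``non_triplet``, and ``ir_duplicate``
    (identical gene name + identical spliced sequence already retained, as for
    genes duplicated between the two inverted repeats).
    """
    records: list[CdsRecord] = []
    seen: set[tuple[str, str]] = set()
    # order CDS features by genomic start so "first copy retained" is stable
    cds_feats = sorted(
        (f for f in genome.features if f.kind == "CDS"),
        key=lambda f: f.span,
    )
    for f in cds_feats:
        seq = splice(f, genome.sequence)
        flags: set[str] = set()
        if len(seq) % 3 != 0:
            flags.add("non_triplet")
        if len(seq) <= MIN_CDS_NT:
            flags.add("too_short")
        codons = tuple(seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3))
        if not codons or codons[0] != START_CODON:
            flags.add("bad_start")
        if "non_triplet" not in flags:
            if not codons or codons[-1] not in STOP_CODONS:
                flags.add("bad_stop")
            if any(c in STOP_CODONS for c in codons[:-1]):
                flags.add("internal_stop")
        else:
            if any(c in STOP_CODONS for c in codons[:-1]):
                flags.add("internal_stop")
        key = (f.gene_name, seq)
        if key in seen:
            flags.add("ir_duplicate")
        else:
            seen.add(key)
        records.append(CdsRecord(
            gene_name=f.gene_name,
            codons=codons,
            source_region=_locate_region(f, layout),
            filter_flags=frozenset(flags),
        ))
    return records


# ---------------------------------------------------------------------------
# gene classification
# ---------------------------------------------------------------------------

# name -> functional group, the conventional plastome gene inventory
GENE_GROUPS: dict[str, str] = {}
GENE_GROUPS.update({g: "photosystem I" for g in
                    ["psaA", "psaB", "psaC", "psaI", "psaJ", "psaM"]})
GENE_GROUPS.update({g: "photosystem II" for g in
                    ["psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH",
                     "psbI", "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT",
                     "psbZ"]})
GENE_GROUPS.update({g: "ATP synthase" for g in
                    ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"]})
GENE_GROUPS.update({g: "NADH dehydrogenase" for g in
                    ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG",
                     "ndhH", "ndhI", "ndhJ", "ndhK"]})
GENE_GROUPS.update({g: "cytochrome" for g in
                    ["petA", "petB", "petD", "petG", "petL", "petN"]})
GENE_GROUPS["rbcL"] = "Rubisco"
GENE_GROUPS.update({g: "protochlorophyllide reductase" for g in
                    ["chlB", "chlL", "chlN"]})
GENE_GROUPS.update({g: "ribosomal LSU" for g in
                    ["rpl2", "rpl14", "rpl16", "rpl20", "rpl21", "rpl22",
                     "rpl23", "rpl32", "rpl33", "rpl36"]})
GENE_GROUPS.update({g: "ribosomal SSU" for g in
                    ["rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12",
                     "rps14", "rps15", "rps18", "rps19"]})
GENE_GROUPS.update({g: "RNA polymerase" for g in
                    ["rpoA", "rpoB", "rpoC1", "rpoC2"]})
GENE_GROUPS.update({g: "other/ycf" for g in
                    ["accD", "cemA", "ccsA", "clpP", "matK", "infA", "ycf1",
                     "ycf2", "ycf3", "ycf4", "ycf12", "ycf66", "cysA", "cysT"]})


def classify_genes(genome: GenomeRecord) -> dict:
    """Tally annotated genes by kind, functional group and intron content.

    Duplicated (IR) genes are counted as annotated; a second tally of unique
    gene names is reported alongside, since published gene totals are
    ambiguous about double-counting IR duplicates.
    """
    by_kind = {k: 0 for k in ("CDS", "tRNA", "rRNA", "other")}
    by_group: dict[str, int] = {}
    intron_genes: list[str] = []
    unique_names: set[str] = set()
    for f in genome.features:
        by_kind[f.kind] += 1
        unique_names.add(f.gene_name)
        if f.kind == "CDS":
            group = GENE_GROUPS.get(f.gene_name)
            if group is None:
                group = "unclassified"
                logger.info("gene %s not in functional map; counted as "
                            "unclassified", f.gene_name)
            by_group[group] = by_group.get(group, 0) + 1
        if len(f.intervals) >= 2:
            intron_genes.append(f.gene_name)
    return {
        "by_kind": by_kind,
        "total": sum(by_kind.values()),
        "total_unique_names": len(unique_names),
        "by_group": dict(sorted(by_group.items())),
        "intron_genes": sorted(intron_genes),
        "n_intron_genes": len(intron_genes),
    }
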