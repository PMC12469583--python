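"""GenBank/FASTA I/O, splicing, CDS filtering and gene classification."""

import pytest

from plastchar._seq import revcomp
from plastchar.genome_io import (CdsRecord, Feature, GenomeRecord,
                                 classify_genes, extract_cds, read_alignment,
                                 read_genbank, splice, write_genbank)

MINI_GB = """\
LOCUS       MINI                      24 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  hand-written test record.
ACCESSION   MINI
FEATURES             Location/Qualifiers
     source          1..24
     CDS             complement(join(1..3,7..9))
                     /gene="toy"
ORIGIN
        1 aaacccgggt ttaaacccgg gttt
//
"""


def test_genbank_join_complement_grammar(tmp_path):
    """join/complement locations resolve to interval lists on the minus
    strand with 0-based half-open coordinates."""
    path = tmp_path / "mini.gb"
    path.write_text(MINI_GB)
    g = read_genbank(path)
    assert g.circular
    assert len(g.sequence) == 24
    (feat,) = g.features
    assert feat.strand == "-"
    assert sorted(feat.intervals) == [(0, 3), (6, 9)]
    # spliced product must match Biopython's extraction semantics:
    # complement(join(1..3,7..9)) -> revcomp(S[0:3] + S[6:9])
    assert splice(feat, g.sequence) == revcomp(g.sequence[0:3] + g.sequence[6:9])


def test_genbank_missing_sequence_errors(tmp_path):
    path = tmp_path / "empty.gb"
    path.write_text(MINI_GB.replace("aaacccgggt ttaaacccgg gttt",
                                    "nnnnnnnnnn nnnnnnnnnn nnnn"))
    with pytest.raises(ValueError):
        read_genbank(path)


def test_ambiguity_codes_rejected():
    with pytest.raises(ValueError, match="unsupported characters"):
        GenomeRecord(id="x", sequence="ACGTR")


def test_genbank_roundtrip(tmp_path, compact_plastome):
    """read(write(G)) preserves sequence, topology and every feature."""
    g = compact_plastome.genome
    path = tmp_path / "synthetic.gb"
    write_genbank(g, path)
    g2 = read_genbank(path)
    assert g2.sequence == g.sequence
    assert g2.circular == g.circular
    key = lambda f: (f.gene_name, f.kind, f.strand, f.intervals)
    assert sorted(map(key, g2.features)) == sorted(map(key, g.features))


def test_splice_strand_mirror_property():
    """Minus-strand extraction is the revcomp of the plus-strand extraction
    over the same intervals (interval order reversed for transcription)."""
    seq = "ATGAAACCCGGGTTTACGTACGT"
    plus = Feature("x", "CDS", "+", ((2, 8), (12, 18)))
    minus = Feature("x", "CDS", "-", ((12, 18), (2, 8)))
    assert splice(minus, seq) == revcomp(splice(plus, seq))
    assert len(splice(plus, seq)) == plus.length


def _genome_with_cds(cds_seqs, names=None):
    flank = "GATCGATCGA"
    seq = flank
    feats = []
    for idx, s in enumerate(cds_seqs):
        start = len(seq)
        seq += s
        feats.append(Feature(
            gene_name=(names[idx] if names else f"g{idx}"),
            kind="CDS", strand="+", intervals=((start, start + len(s)),)))
        seq += flank
    return GenomeRecord(id="t", sequence=seq, features=tuple(feats))


def _valid_cds(n_codons):
    return "ATG" + "GCT" * (n_codons - 2) + "TAA"


class TestExtractCdsFilters:
    def test_exactly_300_nt_is_too_short(self):
        g = _genome_with_cds([_valid_cds(100)])  # 300 nt: boundary excluded
        (rec,) = extract_cds(g)
        assert rec.filter_flags == {"too_short"}

    def test_301_plus_nt_passes(self):
        g = _genome_with_cds([_valid_cds(101)])
        (rec,) = extract_cds(g)
        assert rec.passes and rec.length_nt == 303

    def test_internal_stop_flagged(self):
        body = "ATG" + "GCT" * 50 + "TGA" + "GCT" * 50 + "TAA"
        g = _genome_with_cds([body])
        (rec,) = extract_cds(g)
        assert "internal_stop" in rec.filter_flags

    def test_bad_start_and_stop_flagged(self):
        body = "TTG" + "GCT" * 101 + "CCC"
        g = _genome_with_cds([body])
        (rec,) = extract_cds(g)
        assert {"bad_start", "bad_stop"} <= rec.filter_flags

    def test_non_triplet_flagged(self):
        body = _valid_cds(101) + "AC"
        g = _genome_with_cds([body])
        (rec,) = extract_cds(g)
        assert "non_triplet" in rec.filter_flags

    def test_ir_duplicate_exactly_one_retained(self):
        body = _valid_cds(101)
        g = _genome_with_cds([body, body], names=["ndhB", "ndhB"])
        recs = extract_cds(g)
        flags = sorted("ir_duplicate" in r.filter_flags for r in recs)
        assert flags == [False, True]

    def test_same_name_different_sequence_not_duplicate(self):
        g = _genome_with_cds([_valid_cds(101), _valid_cds(102)],
                             names=["x", "x"])
        recs = extract_cds(g)
        assert all("ir_duplicate" not in r.filter_flags for r in recs)

    def test_filtering_idempotent(self, compact_plastome, compact_layout):
        g = compact_plastome.genome
        first = extract_cds(g, compact_layout)
        second = extract_cds(g, compact_layout)
        assert [(r.gene_name, r.filter_flags) for r in first] == \
               [(r.gene_name, r.filter_flags) for r in second]

    def test_splice_length_consistency(self, compact_plastome):
        g = compact_plastome.genome
        for f in g.features:
            assert len(splice(f, g.sequence)) == f.length


class TestClassifyGenes:
    def test_empty_genome(self):
        g = GenomeRecord(id="e", sequence="ACGT" * 100)
        counts = classify_genes(g)
        assert counts["total"] == 0
        assert counts["by_kind"] == {"CDS": 0, "tRNA": 0, "rRNA": 0, "other": 0}

    def test_planted_trna_count(self, compact_plastome):
        counts = classify_genes(compact_plastome.genome)
        planted_trnas = sum(1 for g in compact_plastome.manifest["genes"]
                            if g["kind"] == "tRNA")
        assert counts["by_kind"]["tRNA"] == planted_trnas

    def test_intron_genes_counted(self, compact_plastome):
        counts = classify_genes(compact_plastome.genome)
        assert "atpF" in counts["intron_genes"]
        assert "ndhB" in counts["intron_genes"]

    def test_unknown_gene_unclassified(self):
        g = _genome_with_cds([_valid_cds(101)], names=["mystery1"])
        counts = classify_genes(g)
        assert counts["by_group"]["unclassified"] == 1

    def test_duplicates_counted_both_ways(self, compact_plastome):
        counts = classify_genes(compact_plastome.genome)
        assert counts["total"] > counts["total_unique_names"]


class TestReadAlignment:
    def test_equal_rows(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">t1\nACGTACGTAC\n>t2\nACGTACGTAC\n")
        aln = read_alignment(p)
        assert aln.ncol == 10 and aln.ntaxa == 2

    def test_ragged_rows_error_names_taxon(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">t1\nACGTACGTAC\n>shorty\nACGTACGTA\n")
        with pytest.raises(ValueError, match="shorty"):
            read_alignment(p)
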