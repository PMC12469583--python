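"""SSR scanning and dispersed-repeat mining against independent oracles."""

import numpy as np
import pytest

from oracles import brute_dispersed_tiny, brute_ssrs, oracle_dispersed
from plastchar._seq import complement, revcomp
from plastchar.repeats import (DEFAULT_SSR_THRESHOLDS, find_dispersed,
                               find_ssrs, summarize_dispersed, summarize_ssrs,
                               validate_repeat, validate_ssr)

FLANK_L = "GACTGCAGTCAGGATCCTAGGCATGCAAGCTTGGCACTGGCCG"
FLANK_R = "CCTGCAGGTCGACTCTAGAGGATCAGCTTGATACCGATGCAT"


def _random_seq(n, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


class TestSsr:
    def test_mono_run_reported(self):
        seq = FLANK_L + "T" * 12 + FLANK_R
        loci = find_ssrs(seq)
        assert [(l.motif, l.unit_count) for l in loci] == [("T", 12)]
        assert loci[0].start == len(FLANK_L)

    def test_below_threshold_not_reported(self):
        seq = FLANK_L + "A" * 9 + FLANK_R
        assert find_ssrs(seq) == []

    @pytest.mark.parametrize("period,motif,units", [
        (2, "AT", 6), (3, "AAT", 4), (4, "ATAG", 3),
        (5, "AATAT", 3), (6, "ATATGC", 3),
    ])
    def test_each_class_at_threshold(self, period, motif, units):
        # seal flanks so the planted run cannot extend by a partial unit
        left = "G" if motif[-1] != "G" else "C"
        right = "G" if motif[0] != "G" else "C"
        seq = FLANK_L + left + motif * units + right + FLANK_R
        loci = find_ssrs(seq)
        assert (motif, units) in [(l.motif, l.unit_count) for l in loci]

    def test_dinucleotide_not_double_reported_as_mono(self):
        seq = FLANK_L + "AT" * 6 + FLANK_R
        loci = find_ssrs(seq)
        assert [(l.motif, l.unit_count) for l in loci] == [("AT", 6)]

    def test_brute_force_scanner_agreement(self):
        """Greedy scan equals the brute all-(start, period) oracle on random
        sequences with planted runs of every class."""
        for seed in range(8):
            seq = (_random_seq(400, seed) + "T" * 11 + _random_seq(200, seed + 50)
                   + "AT" * 7 + _random_seq(300, seed + 100, gc=0.2)
                   + "ATATGC" * 3 + _random_seq(200, seed + 150))
            got = {(l.motif, l.unit_count, l.start, l.end)
                   for l in find_ssrs(seq)}
            assert got == brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)

    def test_planted_recovery_exact(self, compact_plastome):
        loci = find_ssrs(compact_plastome.genome)
        found = {(l.motif, l.unit_count, l.start, l.end) for l in loci}
        planted = {(s["motif"], s["unit_count"], s["start"], s["end"])
                   for s in compact_plastome.manifest["ssrs"]}
        assert planted <= found

    def test_every_reported_ssr_revalidates(self, compact_plastome):
        seq = compact_plastome.genome.sequence
        loci = find_ssrs(compact_plastome.genome)
        assert loci and all(validate_ssr(seq, l) for l in loci)

    def test_strand_consistency(self):
        """Scanning the reverse complement yields the mirrored loci."""
        seq = _random_seq(600, 3, gc=0.25) + "AAT" * 5 + _random_seq(400, 9)
        n = len(seq)
        fwd = find_ssrs(seq)
        rev = {(l.start, l.end) for l in find_ssrs(revcomp(seq))}
        for l in fwd:
            assert (n - l.end, n - l.start) in rev

    def test_region_annotation(self, compact_plastome, compact_layout):
        loci = find_ssrs(compact_plastome.genome, layout=compact_layout)
        by_coord = {(l.start, l.end): l.region for l in loci}
        for s in compact_plastome.manifest["ssrs"]:
            expect = {"lsc": "LSC", "ssc": "SSC", "irb": "IRb"}[s["region"]]
            assert by_coord[(s["start"], s["end"])] == expect

    def test_summaries(self):
        assert summarize_ssrs([])["total"] == 0
        seq = (FLANK_L + "AT" * 6 + FLANK_R + "AT" * 7 + FLANK_L
               + "TA" * 6 + FLANK_R)
        summ = summarize_ssrs(find_ssrs(seq))
        assert summ["by_motif"] == {"AT": 2, "TA": 1}
        assert summ["by_class"][2] == 3


class TestDispersed:
    def test_short_sequence_empty(self):
        assert find_dispersed("ACGTACGT") == []

    def test_planted_exact_forward_duplicate_found(self):
        rng = np.random.default_rng(17)
        core = _random_seq(40, 99)
        seq = _random_seq(2000, 1) + core + _random_seq(1000, 2) + core \
            + _random_seq(1000, 3)
        reps = find_dispersed(seq)
        p1, p2 = 2000, 3040
        covering = [r for r in reps if r.type == "F"
                    and r.pos1 <= p1 and p1 + 40 <= r.pos1 + r.length
                    and r.pos2 <= p2 and p2 + 40 <= r.pos2 + r.length]
        assert covering, "planted forward duplicate not recovered"
        assert set(reps) == {r for r in reps}  # no duplicate listings

    def test_planted_revcomp_copy_is_palindromic(self):
        core = _random_seq(45, 7)
        seq = _random_seq(1500, 4) + core + _random_seq(800, 5) \
            + revcomp(core) + _random_seq(700, 6)
        reps = find_dispersed(seq)
        assert any(r.type == "P" for r in reps)

    def test_output_equals_oracle_on_random_instances(self):
        """Seed-and-extend equals the exhaustive diagonal oracle, with and
        without planted repeats of all four types."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            seq = _random_seq(900, seed + 300)
            w = _random_seq(36, seed + 400)
            images = [w, revcomp(w), w[::-1], complement(w)]
            ins = images[seed % 4]
            seq = seq[:300] + w + seq[300:600] + ins + seq[600:]
            got = {(r.type, r.pos1, r.pos2, r.length, r.mismatches)
                   for r in find_dispersed(seq)}
            assert got == oracle_dispersed(seq)

    def test_tiny_brute_triple_agreement(self):
        """Implementation, diagonal oracle and the literal definition agree
        on tiny inputs at reduced parameters."""
        for seed in range(6):
            seq = _random_seq(90, seed + 1000)
            w = _random_seq(12, seed + 2000)
            seq = seq[:30] + w + seq[30:60] + revcomp(w) + seq[60:]
            got = {(r.type, r.pos1, r.pos2, r.length, r.mismatches)
                   for r in find_dispersed(seq, min_len=12, max_mismatch=1)}
            assert got == oracle_dispersed(seq, min_len=12, k=1)
            assert got == brute_dispersed_tiny(seq, min_len=12, k=1)

    def test_planted_recovery_exact(self, compact_plastome):
        reps = find_dispersed(compact_plastome.genome)
        found = {(r.type, r.pos1, r.pos2, r.length, r.mismatches)
                 for r in reps}
        planted = {(r["type"], r["pos1"], r["pos2"], r["length"],
                    r["mismatches"])
                   for r in compact_plastome.manifest["repeats"]}
        assert planted <= found

    def test_every_reported_repeat_revalidates(self, compact_plastome):
        seq = compact_plastome.genome.sequence
        reps = find_dispersed(compact_plastome.genome)
        assert reps and all(validate_repeat(seq, r) for r in reps)

    def test_ir_pair_tagged_and_excluded_from_summary(self, compact_plastome,
                                                      compact_layout):
        reps = find_dispersed(compact_plastome.genome,
                              layout=compact_layout)
        ir_pairs = [r for r in reps if r.is_ir_pair]
        assert ir_pairs and all(r.type == "P" for r in ir_pairs)
        assert max(r.length for r in ir_pairs) >= compact_layout.ir_length
        summ_excl = summarize_dispersed(reps)
        summ_incl = summarize_dispersed(reps, include_ir_pair=True)
        assert summ_incl["total"] == summ_excl["total"] + len(ir_pairs)
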