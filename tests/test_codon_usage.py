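"""Codon-usage-bias suite: closed forms, hand counts, independent ENC."""

from collections import Counter

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from plastchar.codon_usage import (CodonStats, FAMILIES, codon_composition,
                                   correlation_matrix, count_codons, enc,
                                   enc_expected, neutrality_regression,
                                   optimal_codons, optimal_codons_from_cds,
                                   pr2_coordinates, rscu, to_rna)
from plastchar.genome_io import CdsRecord
from plastchar.synth import CubProfile, generate_cds_set


def _cds(codons, name="g1"):
    return CdsRecord(gene_name=name, codons=tuple(codons))


class TestComposition:
    def test_hand_count_small_gene(self):
        """ATG GCT GCA TAA: stop dropped; GC by position over the three
        retained codons; synonymous-site stats over the two Ala codons."""
        stats = codon_composition(_cds(["ATG", "GCT", "GCA", "TAA"]))
        assert stats.gc1 == pytest.approx(2 / 3)
        assert stats.gc2 == pytest.approx(2 / 3)
        assert stats.gc3 == pytest.approx(1 / 3)  # thirds G, T, A
        assert stats.gc3s == pytest.approx(0.0)   # Ala thirds T, A
        assert stats.a3 == pytest.approx(0.5) and stats.t3 == pytest.approx(0.5)

    def test_third_position_fractions_sum_to_one(self):
        for rec in generate_cds_set(5, 200, CubProfile.from_at_bias(0.4), 3):
            s = codon_composition(rec)
            assert s.a3 + s.t3 + s.g3 + s.c3 == pytest.approx(1.0)
            assert 20 <= s.enc <= 61

    def test_gc3s_undefined_without_synonymous_codons(self):
        stats = codon_composition(_cds(["ATG", "TGG", "TAA"]))
        assert stats.gc3s is None

    def test_zero_codons_errors(self):
        with pytest.raises(ValueError):
            codon_composition(_cds(["TAA"]))


class TestRscu:
    def test_uniform_usage_all_ones(self):
        counts = {c: 7 for c in sum((list(v) for v in FAMILIES.values()), [])}
        tab = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in tab.values())

    def test_phe_hand_formula(self):
        tab = rscu({"TTT": 3, "TTC": 1})
        assert tab["UUU"] == pytest.approx(1.5)
        assert tab["UUC"] == pytest.approx(0.5)

    def test_unobserved_family_missing_not_zero(self):
        tab = rscu({"TTT": 3, "TTC": 1})
        assert tab["GGU"] is None

    def test_family_means_equal_one(self):
        rng = np.random.default_rng(8)
        codons = sum((list(v) for v in FAMILIES.values()), [])
        counts = {c: int(rng.integers(1, 50)) for c in codons}
        tab = rscu(counts)
        for aa, fam in FAMILIES.items():
            if len(fam) > 1:
                mean = np.mean([tab[to_rna(c)] for c in fam])
                assert mean == pytest.approx(1.0)


class TestEnc:
    def test_extreme_bias_is_exactly_20(self):
        counts = {fam[0]: 50 for fam in FAMILIES.values() if len(fam) > 1}
        assert enc(counts) == pytest.approx(20.0)

    def test_uniform_usage_capped_at_61(self):
        counts = {}
        for fam in FAMILIES.values():
            if len(fam) > 1:
                counts.update({c: 200 for c in fam})
        assert enc(counts) == 61.0

    def test_f3_imputed_when_ile_absent(self):
        counts = {}
        for aa, fam in FAMILIES.items():
            if len(fam) > 1 and aa != "I":
                counts.update({c: 30 for c in fam})
        assert enc(counts) is not None

    def test_missing_twofold_class_undefined(self):
        counts = {"GCT": 10, "GCC": 10, "GCA": 10, "GCG": 10}  # Ala only
        assert enc(counts) is None

    def test_matches_independent_homozygosity_computation(self):
        """ENC equals a from-scratch Wright computation that derives its
        synonymous families from Biopython's codon table."""
        table = unambiguous_dna_by_id[1]
        fams: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            fams.setdefault(aa, []).append(codon)
        fams = {aa: v for aa, v in fams.items() if len(v) > 1}

        def brute_enc(counts):
            per = {2: [], 3: [], 4: [], 6: []}
            for aa, cods in fams.items():
                ns = [counts.get(c, 0) for c in cods]
                n = sum(ns)
                if n < 2:
                    continue
                f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
                per[len(cods)].append(f)
            avg = {k: (sum(v) / len(v) if v else None) for k, v in per.items()}
            if avg[3] is None:
                avg[3] = (avg[2] + avg[4]) / 2
            val = 2 + 9 / avg[2] + 1 / avg[3] + 5 / avg[4] + 3 / avg[6]
            return min(val, 61.0)

        for seed in range(6):
            rec = generate_cds_set(1, 500, CubProfile.from_at_bias(0.5),
                                   seed)[0]
            counts = count_codons(rec)
            assert enc(counts) == pytest.approx(brute_enc(dict(counts)),
                                                abs=1e-9)

    def test_expected_curve_closed_form(self):
        assert enc_expected(0.0) == pytest.approx(31.0)
        assert enc_expected(0.5) == pytest.approx(60.5)
        assert enc_expected(1.0) == pytest.approx(32.0)
        with pytest.raises(ValueError):
            enc_expected(1.2)

    def test_curve_matches_simulation_without_selection(self):
        """Genes whose third positions follow mutational base frequencies
        alone give mean ENC near the null curve."""
        for gc3 in (0.3, 0.5):
            fams = {}
            base_p = {"A": (1 - gc3) / 2, "T": (1 - gc3) / 2,
                      "G": gc3 / 2, "C": gc3 / 2}
            from plastchar.codon_usage import DEGENERATE_FAMILIES
            for aa, cods in DEGENERATE_FAMILIES.items():
                w = {c: base_p[c[2]] for c in cods}
                tot = sum(w.values())
                fams[aa] = {c: v / tot for c, v in w.items()}
            profile = CubProfile(fams)
            recs = generate_cds_set(25, 700, profile, seed=int(gc3 * 100))
            encs = [enc(count_codons(r)) for r in recs]
            assert np.mean(encs) == pytest.approx(enc_expected(gc3), abs=2.5)


class TestNeutrality:
    def _stats(self, pts):
        return [CodonStats(f"g{i}", 300, 0.25, 0.25, 0.25, 0.25,
                           gc1=2 * y - 0.3, gc2=0.3, gc3=x, gc3s=x,
                           gc_all=0.3, enc=45.0)
                for i, (x, y) in enumerate(pts)]

    def test_points_on_diagonal(self):
        res = neutrality_regression(self._stats(
            [(0.1, 0.1), (0.2, 0.2), (0.3, 0.3), (0.4, 0.4)]))
        assert res["slope"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_flat_response(self):
        res = neutrality_regression(self._stats(
            [(0.1, 0.2), (0.2, 0.2), (0.3, 0.2)]))
        assert res["slope"] == pytest.approx(0.0)
        assert res["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_counts(self):
        res = neutrality_regression(self._stats(
            [(0.1, 0.3), (0.2, 0.3), (0.5, 0.3), (0.6, 0.3)]))
        assert res["n_above_diagonal"] == 2
        assert res["n_below_diagonal"] == 2

    def test_errors(self):
        with pytest.raises(ValueError):
            neutrality_regression(self._stats([(0.1, 0.1)]))
        with pytest.raises(ValueError):
            neutrality_regression(self._stats(
                [(0.2, 0.1), (0.2, 0.3), (0.2, 0.5)]))


class TestPr2:
    def _one(self, a3, t3, g3, c3):
        return CodonStats("g", 300, a3, t3, g3, c3, 0.3, 0.3, 0.3, 0.3,
                          0.3, 45.0)

    def test_no_bias_center(self):
        res = pr2_coordinates([self._one(0.25, 0.25, 0.25, 0.25)])
        assert res["points"][0]["x"] == pytest.approx(0.5)
        assert res["points"][0]["y"] == pytest.approx(0.5)
        assert res["quadrants"]["boundary"] == 1

    def test_all_t_thirds_missing_x(self):
        res = pr2_coordinates([self._one(0.0, 1.0, 0.0, 0.0)])
        assert res["points"][0]["x"] is None
        assert res["points"][0]["y"] == pytest.approx(0.0)

    def test_quadrant_tallies(self):
        stats = [self._one(0.1, 0.5, 0.3, 0.1),   # y<0.5, x>0.5
                 self._one(0.5, 0.1, 0.1, 0.3)]   # y>0.5, x<0.5
        res = pr2_coordinates(stats)
        assert res["quadrants"]["x>0.5,y<0.5"] == 1
        assert res["quadrants"]["x<0.5,y>0.5"] == 1


class TestCorrelation:
    def test_matrix_properties(self):
        recs = generate_cds_set(20, 250, CubProfile.from_at_bias(0.5), 12)
        stats = [codon_composition(r) for r in recs]
        out = correlation_matrix(stats)
        r = out["r"]
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        assert np.allclose(np.diag(r.values), 1.0)
        assert abs(r.loc["GC3", "GC3s"]) > 0.5  # strongly coupled by design

    def test_proportional_columns_correlate_perfectly(self):
        stats = [CodonStats(f"g{i}", 100 * (i + 1), 0.25, 0.25, 0.25, 0.25,
                            gc1=0.1 * (i + 1), gc2=0.05 * (i + 1),
                            gc3=0.3, gc3s=0.3, gc_all=0.3, enc=40.0)
                 for i in range(5)]
        out = correlation_matrix(stats)
        assert out["r"].loc["GC1", "GC2"] == pytest.approx(1.0)
        assert np.isnan(out["r"].loc["GC3", "ENC"])  # constant columns


class TestOptimalCodons:
    def test_identical_pools_no_optimal(self):
        counts = {c: 5 for fam in FAMILIES.values() for c in fam}
        entries = [(f"g{i}", counts, 30.0 + i) for i in range(20)]
        rep = optimal_codons(entries)
        assert rep.optimal == []
        assert len(rep.high_pool) == len(rep.low_pool) == 2
        assert set(rep.high_pool).isdisjoint(rep.low_pool)

    def test_too_few_genes_error(self):
        counts = {"TTT": 1}
        with pytest.raises(ValueError):
            optimal_codons([("a", counts, 30.0)])

    def test_enc_tie_broken_by_name(self):
        counts = {c: 5 for fam in FAMILIES.values() for c in fam}
        entries = [(name, counts, 30.0) for name in "qwertyuiopas"]
        rep = optimal_codons(entries)
        assert rep.high_pool == ("a", "e")  # alphabetical among ties

    def test_planted_optimal_set_recovered_exactly(self):
        """Three gene strata (extreme bias / intermediate / uniform) make
        the designated codons — and only those — optimal."""
        from plastchar.codon_usage import DEGENERATE_FAMILIES
        designated = {aa: sorted(c for c in fam if c[2] in "AT")[0]
                      for aa, fam in DEGENERATE_FAMILIES.items()}
        extreme = CubProfile.deterministic(designated)
        mid = CubProfile.concentrated(designated, 0.35)
        uniform = CubProfile.uniform()
        recs = (generate_cds_set(3, 300, extreme, 1, name_prefix="hi") +
                generate_cds_set(24, 300, mid, 2, name_prefix="md") +
                generate_cds_set(3, 300, uniform, 3, name_prefix="lo"))
        rep = optimal_codons_from_cds(recs)
        assert set(rep.high_pool) == {"hi001", "hi002", "hi003"}
        assert set(rep.low_pool) == {"lo001", "lo002", "lo003"}
        expected = sorted(to_rna(c) for c in designated.values())
        assert rep.optimal == expected

    def test_high_frequency_codons_AT_ending_under_strong_bias(self):
        recs = generate_cds_set(15, 300, CubProfile.from_at_bias(0.95), 21)
        rep = optimal_codons_from_cds(recs)
        hf = rep.high_frequency
        at_ending = [c for c in hf if c[2] in "AU"]
        assert len(at_ending) / len(hf) >= 0.9
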