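#!/usr/bin/env python
"""Codon-usage bias of the simulated specimens: full analysis suite.

Builds, per specimen, a ~53-gene coding panel at the specimen's
third-position A/U bias (the plastome records themselves carry only the
junction- and filter-exercising genes, so panels at the study's gene count
come from the same profiles), then runs the complete pipeline: per-gene
composition (GC1/GC2/GC3/GC3s/GCall, A3/T3/G3/C3, ENC), Pearson
correlations, the neutrality plot regression, ENC-plot points against the
mutation-only null curve, the PR2 plot, pooled RSCU with high-frequency
codons, and optimal codons via the ENC-decile dRSCU >= 0.08 rule.  Finally
the two specimens' optimal sets are intersected into a shared/specific
table.  Everything goes to results/codon_usage/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plastchar.codon_usage import (codon_composition, count_codons, enc,
                                   enc_expected, neutrality_regression,
                                   optimal_codons_from_cds, pr2_coordinates,
                                   correlation_matrix, rscu)
from plastchar.genome_io import extract_cds, read_genbank
from plastchar.synth import CubProfile, generate_cds_set

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "codon_usage"

PANEL = {"I": (0.60, 6_100), "II": (0.65, 6_200)}  # at_bias_3, seed


def analyse(label: str) -> dict:
    at_bias, seed = PANEL[label]
    genome = read_genbank(DATA / f"specimen_{label}.gb")
    genome_cds = [r for r in extract_cds(genome) if r.passes]
    print(f"specimen {label}: {len(genome_cds)} genome CDS pass the "
          "filters (>300 nt, ATG start, standard stop, no internal stop, "
          "IR duplicates removed)")
    panel = generate_cds_set(53, 350, CubProfile.from_at_bias(at_bias), seed,
                             name_prefix=f"{label.lower()}gene")
    stats = [codon_composition(r) for r in panel]
    pd.DataFrame([{
        "gene": s.gene_name, "length_nt": s.length_nt,
        "A3": s.a3, "T3": s.t3, "G3": s.g3, "C3": s.c3,
        "GC1": s.gc1, "GC2": s.gc2, "GC3": s.gc3, "GC12": s.gc12,
        "GC3s": s.gc3s, "GCall": s.gc_all, "ENC": s.enc,
    } for s in stats]).to_csv(OUT / f"codon_stats_{label}.tsv",
                              sep="\t", index=False)

    corr = correlation_matrix(stats)
    corr["r"].round(3).to_csv(OUT / f"correlation_r_{label}.tsv", sep="\t")
    corr["stars"].to_csv(OUT / f"correlation_stars_{label}.tsv", sep="\t")

    neut = neutrality_regression(stats)
    print(f"  neutrality plot: slope {neut['slope']:.4f}, "
          f"r^2 {neut['r_squared']:.4f}, two-tailed p {neut['p_slope_two_tailed']:.3g}; "
          f"{neut['n_above_diagonal']} genes above / "
          f"{neut['n_below_diagonal']} below the diagonal")

    enc_pts = pd.DataFrame({
        "gene": [s.gene_name for s in stats],
        "GC3s": [s.gc3s for s in stats],
        "ENC": [s.enc for s in stats],
        "ENC_expected": [enc_expected(s.gc3s) for s in stats],
    })
    enc_pts.to_csv(OUT / f"enc_plot_{label}.tsv", sep="\t", index=False)

    pr2 = pr2_coordinates(stats)
    pd.DataFrame(pr2["points"]).to_csv(OUT / f"pr2_points_{label}.tsv",
                                       sep="\t", index=False)
    print(f"  PR2 quadrants: {pr2['quadrants']}")

    pooled = rscu(count_codons(panel))
    hf = sorted(c for c, v in pooled.items() if v is not None and v > 1)
    at_ending = [c for c in hf if c.endswith(("A", "U"))]
    print(f"  {len(hf)} high-frequency codons (pooled RSCU > 1), "
          f"{len(at_ending)} of them A/U-ending "
          f"({100 * len(at_ending) / len(hf):.1f}%)")
    pd.Series(pooled, name="RSCU").rename_axis("codon").to_csv(
        OUT / f"rscu_pooled_{label}.tsv", sep="\t")

    report = optimal_codons_from_cds(panel)
    report.table.to_csv(OUT / f"optimal_codons_{label}.tsv", sep="\t")
    print(f"  optimal codons ({len(report.optimal)}): "
          f"{', '.join(report.optimal)}")
    return {"optimal": report.optimal, "high_frequency": hf,
            "neutrality": {k: neut[k] for k in
                           ("slope", "r_squared", "p_slope_two_tailed")}}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = {label: analyse(label) for label in ("I", "II")}
    shared = sorted(set(res["I"]["optimal"]) & set(res["II"]["optimal"]))
    only1 = sorted(set(res["I"]["optimal"]) - set(res["II"]["optimal"]))
    only2 = sorted(set(res["II"]["optimal"]) - set(res["I"]["optimal"]))
    table = pd.DataFrame([
        {"category": "shared", "codons": ", ".join(shared),
         "count": len(shared)},
        {"category": "I-specific", "codons": ", ".join(only1),
         "count": len(only1)},
        {"category": "II-specific", "codons": ", ".join(only2),
         "count": len(only2)},
    ])
    table.to_csv(OUT / "optimal_codons_shared.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    with open(OUT / "summary.json", "w") as fh:
        json.dump({"specimens": res, "shared_optimal": shared,
                   "I_specific": only1, "II_specific": only2}, fh, indent=2)
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
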