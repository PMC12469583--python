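#!/usr/bin/env python
"""Quadripartite structure, per-region GC, and IR junction distances.

Reads the archived GenBank records back (exercising the parser), re-detects
the inverted repeats annotation-free, tabulates region lengths and GC
(specimen x region), and reports signed gene-to-junction distances for the
conventional boundary markers (rpl23/trnM at JLB, trnN/ndhF at JSB, chlL at
JSA).  Tables go to results/structure/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plastchar.genome_io import classify_genes, read_genbank
from plastchar.structure import (detect_inverted_repeats, junction_distances,
                                 region_stats)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "structure"

JUNCTION_GENES = ["rpl23", "trnM", "trnN", "ndhF", "chlL"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows, junc_rows, genomes = [], [], []
    for label in ("I", "II"):
        g = read_genbank(DATA / f"specimen_{label}.gb")
        lay = detect_inverted_repeats(g)
        genomes.append((g, lay))
        stats = region_stats(g, lay)
        rows.append({
            "specimen": label, "size_bp": stats["total"]["length"],
            "lsc_bp": stats["LSC"]["length"], "ssc_bp": stats["SSC"]["length"],
            "ir_bp": stats["IRa"]["length"],
            "total_gc_pct": stats["total"]["gc_pct"],
            "lsc_gc_pct": stats["LSC"]["gc_pct"],
            "ssc_gc_pct": stats["SSC"]["gc_pct"],
            "ir_gc_pct": stats["IRa"]["gc_pct"],
        })
        counts = classify_genes(g)
        print(f"specimen {label}: {counts['total']} features "
              f"({counts['by_kind']['CDS']} CDS, "
              f"{counts['by_kind']['tRNA']} tRNA, "
              f"{counts['by_kind']['rRNA']} rRNA); "
              f"intron-containing: {', '.join(sorted(set(counts['intron_genes'])))}")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "region_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    report = junction_distances(genomes, JUNCTION_GENES)
    jdf = pd.DataFrame(report)
    jdf.to_csv(OUT / "junction_distances.tsv", sep="\t", index=False)
    key = jdf[(jdf.junction == "JSB") & (jdf.gene == "ndhF")]
    for _, r in key.iterrows():
        print(f"{r['genome']}: ndhF {('crosses JSB by ' + str(-r['distance']) + ' bp') if r['distance'] < 0 else 'inside SSC'}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
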