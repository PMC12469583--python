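#!/usr/bin/env python
"""SSR and dispersed-repeat landscape of the simulated plastomes.

Mines microsatellites in both specimens (MISA-style thresholds: mono >=10,
di >=6, tri >=4, tetra/penta/hexa >=3 units) and dispersed repeats
(>=30 bp, Hamming distance <=3, F/P/R/C types) in specimen I — the dispersed
sweep is the one genome-scale scan, so one specimen keeps this driver quick.
Per-locus tables and class summaries go to results/repeats/; summaries are
reported both without and with the IRa/IRb self-pair.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plastchar.genome_io import read_genbank
from plastchar.repeats import (find_dispersed, find_ssrs, summarize_dispersed,
                               summarize_ssrs)
from plastchar.structure import detect_inverted_repeats

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "repeats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for label in ("I", "II"):
        g = read_genbank(DATA / f"specimen_{label}.gb")
        lay = detect_inverted_repeats(g)
        loci = find_ssrs(g, layout=lay)
        pd.DataFrame([{
            "motif": l.motif, "units": l.unit_count,
            "start_1based": l.start + 1, "end": l.end, "region": l.region,
        } for l in loci]).to_csv(OUT / f"ssr_loci_{label}.tsv",
                                 sep="\t", index=False)
        summ = summarize_ssrs(loci)
        summaries[f"ssr_{label}"] = summ
        mono = {m: c for m, c in summ["by_motif"].items() if len(m) == 1}
        print(f"specimen {label}: {summ['total']} SSR loci; "
              f"mononucleotide tallies {mono}; "
              f"by class {summ['by_class']}")

    g = read_genbank(DATA / "specimen_I.gb")
    lay = detect_inverted_repeats(g)
    reps = find_dispersed(g, layout=lay)
    pd.DataFrame([{
        "type": r.type, "pos1_1based": r.pos1 + 1, "pos2_1based": r.pos2 + 1,
        "length": r.length, "mismatches": r.mismatches,
        "is_ir_pair": r.is_ir_pair,
    } for r in reps]).to_csv(OUT / "dispersed_I.tsv", sep="\t", index=False)
    summaries["dispersed_I"] = summarize_dispersed(reps)
    summaries["dispersed_I_with_ir_pair"] = summarize_dispersed(
        reps, include_ir_pair=True)
    print(f"specimen I dispersed repeats (IR self-pair excluded): "
          f"{summaries['dispersed_I']['total']} "
          f"by type {summaries['dispersed_I']['by_type']}; "
          f"including IR pair: {summaries['dispersed_I_with_ir_pair']['total']}")
    with open(OUT / "summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
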