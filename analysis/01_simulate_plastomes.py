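#!/usr/bin/env python
"""Simulate the two study plastomes and archive them with ground truth.

Generates the specimen I/II pair of synthetic moss-like chloroplast genomes
(124,264 and 124,440 bp; AT-rich single-copy regions, GC-rich 10 kb inverted
repeats; planted junction genes, SSRs of all six classes and dispersed
repeats of all four types), writes GenBank + FASTA + the ground-truth
manifests under results/data/, and prints what was planted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plastchar.genome_io import write_fasta, write_genbank
from plastchar.synth import generate_specimen_pair

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pair = generate_specimen_pair(seed=20_240)
    for label, sp in zip(("I", "II"), pair):
        g = sp.genome
        write_genbank(g, OUT / f"specimen_{label}.gb")
        write_fasta(g, OUT / f"specimen_{label}.fasta")
        sp.write_manifest(OUT / f"specimen_{label}.manifest.json")
        man = sp.manifest
        print(f"specimen {label}: {man['length']:,} bp "
              f"(LSC {man['regions']['lsc'][1]:,} / "
              f"IR {man['regions']['irb'][1]:,} x2 / "
              f"SSC {man['regions']['ssc'][1]:,}); "
              f"{len(man['genes'])} gene features, "
              f"{len(man['ssrs'])} planted SSRs, "
              f"{len(man['repeats'])} planted dispersed repeats")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
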