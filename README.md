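# plastchar

Characterization toolkit for quadripartite chloroplast genomes (plastomes),
written for comparative plastome studies in bryophytes and other land
plants. Given annotated GenBank/FASTA records and per-gene alignments, it
computes everything a plastome-description study reports downstream of
assembly and annotation:

- **Quadripartite structure** — annotation-free detection of the inverted
  repeats (IRa = reverse complement of IRb), region lengths and GC
  (LSC/SSC/IR), and signed gene-to-junction distances at JLB/JSB/JSA/JLA
  (negative = the gene crosses the junction by that many bp).
- **Repeats** — microsatellites (SSRs: perfect tandem runs of primitive
  1–6 nt motifs at thresholds 10/6/4/3/3/3 units) and maximal dispersed
  repeats ≥30 bp with Hamming distance ≤3 of all four types: forward (F),
  palindromic (P), reverse (R), complement (C).
- **Nucleotide diversity** — per-gene π (mean pairwise differences per
  site, complete deletion of gapped columns, uncorrected), 25 bp-step
  sliding windows, and hypervariable-gene calling at π > 0.08.
- **Codon-usage bias** — per-gene GC1/GC2/GC3/GC3s/GCall, A3/T3/G3/C3 and
  ENC (Wright's estimator, Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆); Pearson
  correlation matrices; the neutrality plot (GC12 on GC3 OLS); the
  ENC-plot with its null curve ENC = 2 + GC3 + 29/[GC3² + (1−GC3)²]; the
  PR2 plot A3/(A3+T3) vs G3/(G3+C3); pooled RSCU with high-frequency
  codons (RSCU > 1); and optimal codons — genes ranked by ENC, the top and
  bottom deciles pooled, and codons with genome-wide RSCU > 1 and
  ΔRSCU = RSCU_high − RSCU_low ≥ 0.08 called optimal.
- **Synthetic plastomes** — a seeded generator that plants all of the
  above (IRs, junction genes, SSRs, F/P/R/C repeats, codon-bias-tunable
  CDS panels, alignments at a target π) with a ground-truth manifest, so
  every detector is testable end to end without downloads.

The library lives in `src/plastchar/` (modules `genome_io`, `structure`,
`repeats`, `diversity`, `codon_usage`, `synth`); the numbered scripts in
`analysis/` drive a complete two-specimen study on synthetic data and
write tables under `results/`.

## Worked example

```bash
python analysis/01_simulate_plastomes.py
python analysis/02_structure_and_junctions.py
```

prints, for the simulated specimen pair:

```
specimen I: 124,264 bp (LSC 85,572 / IR 10,042 x2 / SSC 18,608); 16 gene features, 8 planted SSRs, 5 planted dispersed repeats
specimen  size_bp  lsc_bp  ssc_bp  ir_bp  total_gc_pct  lsc_gc_pct  ssc_gc_pct  ir_gc_pct
       I   124264   85572   18608  10042          30.0        27.2        30.4       41.7
      II   124440   85731   18609  10050          30.0        27.2        30.1       41.7
synthetic_20240: ndhF crosses JSB by 76 bp
```

i.e. the detector recovers the planted quadripartite layout exactly (the
GC-rich ~10 kb IRs against AT-rich single-copy regions) and the planted
junction anatomy: *ndhF* extends 76 bp across the IRb|SSC boundary, *trnM*
sits 62 bp inside the LSC at JLB, *chlL* 60 bp from JSA. Continuing,

```bash
python analysis/04_nucleotide_diversity.py
python analysis/05_codon_usage.py
```

reports the diversity panel (`pi range 0.04833-0.18044, mean 0.09718`) with
the seven genes simulated above the 0.08 threshold called hypervariable —
`matK, ycf2, rpoC2, ndhG, ndhF, ndhB, rpl32` — and the codon-usage suite
per specimen:

```
  neutrality plot: slope 0.0909, r^2 0.0085, two-tailed p 0.511; 53 genes above / 0 below the diagonal
  30 high-frequency codons (pooled RSCU > 1), 30 of them A/U-ending (100.0%)
  optimal codons (16): ACU, AGU, AUA, CAA, CAU, CCA, CGA, CUA, GAA, GAU, GCU, GGA, GGU, GUU, UCU, UUA
```

The flat, non-significant neutrality slope says third-position composition
varies essentially independently of positions 1–2 (selection-dominated
usage), every high-frequency codon ends in A/U as expected for a strongly
AT-biased plastome, and `optimal_codons_shared.tsv` intersects the two
specimens' optimal sets into shared and specimen-specific codons.

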