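# Methods

`plastchar` characterizes quadripartite chloroplast genomes (plastomes):
their LSC/IRb/SSC/IRa architecture and junction behaviour, their repeat
landscape, per-gene nucleotide diversity, and the full codon-usage-bias
suite up to optimal-codon identification. This note records the models and
procedures implemented, the defaults and why they were chosen, the design
decisions made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Coordinates and records

All internal coordinates are 0-based half-open; reports destined for human
reading emit 1-based inclusive positions (the GenBank convention), so file
round-trips are lossless. Feature intervals are stored in transcription
order (5' exon first); a minus-strand interval contributes the reverse
complement of its forward slice, which reproduces Biopython's extraction
semantics for `join`/`complement(join)` location grammars — the reader
verifies this against Biopython's own extraction at parse time and falls
back to the reversed part order for grammars stored the other way.
Trans-spliced annotations are honoured in annotation order; no reordering
is attempted. Ambiguity codes other than N are rejected at parse because
every downstream computation (codon tallies, Hamming scans) assumes an
unambiguous alphabet.

## Quadripartite structure

The layout detector is annotation-free: it returns the longest pair of
disjoint circular intervals whose sequences are exact reverse complements,
with both gaps nonempty; the longer gap is the LSC. Junctions are named
JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa), JLA (IRa|LSC), with IRb the
copy that follows the LSC clockwise. Implementation: exact 31-mers sampled
at a stride that cannot skip an IR of `min_ir_len` are matched against the
circular reverse complement and extended maximally; candidates shorter than
`min_ir_len` (default 1000 bp — moss IRs run ~10 kb, and the floor
suppresses short chance palindromes) are discarded. Ties break toward the
maximal length, then the smallest start. A `max_ir_mismatch` option exists
but defaults to 0: assembled plastomes carry literally identical IR copies,
and the exactness is what pins junctions to single-base precision. 
Detection is rotation-invariant (property-tested); `rotate_to_canonical`
places the LSC at the origin.

Signed junction distances follow the convention used in boundary-shift
figures: positive distances are the gap between the nearer gene end and the
junction; a gene crossing the junction reports the negative overlap into
the region on its far side; genes absent from a genome are reported as
absent rather than erroring, since gene loss at junctions is itself a
finding.

Per-region GC is (G+C)/(A+C+G+T) with N excluded from the denominator,
reported to one decimal as percentages.

## CDS extraction and the analysis set

Each CDS is spliced across its intervals and strand-resolved, then flagged
(never dropped silently) against the analysis-set criteria: spliced length
strictly greater than 300 nt, ATG start, standard stop (TAA/TAG/TGA), no
internal stop, length a multiple of three, and removal of inverted-repeat
duplicates — among CDS sharing a gene name and an identical spliced
sequence, exactly the first (by genomic position) is retained. The strict
`> 300` reading of the length filter is deliberate; a 300 nt gene is
excluded.

## Repeat mining

**SSRs.** Perfect tandem runs of a primitive 1–6 nt motif, thresholds
{mono ≥10, di ≥6, tri ≥4, tetra/penta/hexa ≥3} units — the MISA settings
conventional in plastome surveys. The scan finds, per period, maximal
match runs of the sequence against itself shifted by the period; each run
is assigned its smallest primitive period, unit counts are whole units,
and runs contained in a reported run of smaller period are not
double-reported. Motifs are tallied as read on the forward strand (A and T
counted separately), matching how plastome SSR tables are published.
Compound-SSR merging is not performed: published totals report per-class
counts, and merging conventions vary by tool; counts on real data may
shift slightly against tools that merge.

**Dispersed repeats.** Maximal pairs of segments ≥30 bp matching under one
of four transforms — F (direct), P (reverse complement), R (reverse), C
(complement) — with Hamming distance ≤3, the REPuter parameter set quoted
in plastome studies. No E-value filter is applied (the published criteria
are length and distance only), and overlapping maximal pairs are all
reported. Each unordered pair is reported once; a palindrome whose two
listings coincide appears once. Maximality means no single-base extension
keeps the pair within the mismatch budget, so a reported pair carries
exactly the budget's mismatches unless a sequence boundary intervenes.

The finder is seed-and-extend: any qualifying 30 bp window with ≤3
mismatches contains an exact run of at least ⌈(30−3)/4⌉ = 7 nt
(pigeonhole), so exact 7-mer matches locate every candidate diagonal; each
candidate diagonal is then swept exhaustively, with maximal windows read
off the gaps between mismatches k+1 apart (boundary sentinels included).
On genome-scale AT-rich input, chance 7-mers stop pruning, and the finder
switches to an exact dense pre-filter: a rolling mismatch count per
diagonal (numba-compiled, with an equivalent numpy fallback) flags the
diagonals containing at least one qualifying window; for the
reversal-based transforms a pair and its mirror sit symmetrically on one
diagonal, so half of each diagonal suffices for flagging. Output is
identical on either path — the tests hold the scanner equal to an
independently-coded exhaustive oracle (rank/two-pointer formulation) on
random instances, and to a literal walk of the definition on tiny inputs.

The IRa/IRb pair itself surfaces as a giant palindromic repeat; it is
tagged `is_ir_pair` when a layout is supplied and excluded from summary
counts by default, with an `include_ir_pair` toggle, because published
totals are ambiguous about whether the self-pair is counted. Summaries are
emitted both ways.

## Nucleotide diversity

Pi is the unweighted mean of pairwise Hamming differences per retained
site: columns containing any gap or ambiguous base are excluded entirely
(complete deletion), and no multiple-hit correction is applied — matching
the headline Pi of standard software with default site handling.
Alignments are inputs; the package intersects shared gene sets across
genomes and writes unaligned per-gene FASTA for external alignment, but
never aligns. Sliding windows advance by a step (default 25 bp) over
alignment columns, with the trailing partial window kept when at least one
step's worth of columns remains. Hypervariable calling is `pi > threshold`
(default 0.08), sorted descending with alphabetical tie-break. Because a
whole-gene window admits only one placement, both whole-gene and windowed
modes are provided.

## Codon-usage bias

The standard genetic code is used throughout (the plastid code differs
only in start-codon leniency, which the ATG filter has already imposed).
Per gene, the stop codon is excluded from every tally and the start codon
is included; GC1/GC2/GC3/GCall run over all retained codons, while
A3/T3/G3/C3 and GC3s run over the synonymously-variable codons only (AUG
and UGG excluded). RSCU is the observed count over the family mean;
unobserved families are reported missing, not zero.

ENC follows Wright's estimator: family homozygosity
F = (nΣp² − 1)/(n − 1) for families with n ≥ 2, averaged within
degeneracy classes, then Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at
61. Six-fold families (Leu, Ser, Arg) are treated as six-fold, matching
CodonW. A missing three-fold class (Ile unobserved) is imputed as the mean
of the two- and four-fold averages; a missing two-, four- or six-fold
class leaves the gene's ENC undefined. The ENC-plot null curve is
ENC = 2 + GC3 + 29/[GC3² + (1 − GC3)²]; a stochastic test verifies that
genes simulated with third positions driven by base frequencies alone fall
on the curve within sampling error.

The neutrality plot regresses GC12 = (GC1+GC2)/2 on GC3 by ordinary least
squares; because the slope t-test and the correlation test coincide in
simple OLS, both p-values are emitted. PR2 coordinates are
x = G3/(G3+C3), y = A3/(A3+T3) per gene, computed over all
synonymously-variable codons (a fourfold-only option exists), with
quadrant tallies about the no-bias point (0.5, 0.5).

Optimal codons: genes are sorted ascending by ENC (ties broken by name);
the first ⌈0.1·n⌉ genes form the putative high-expression pool and the
last ⌈0.1·n⌉ the low-expression pool (ceil guarantees nonempty pools;
53 genes give 6-gene pools). RSCU is computed on pooled counts within each
pool, ΔRSCU = RSCU_high − RSCU_low, and a codon is optimal when its
genome-wide pooled RSCU exceeds 1 (high frequency, evaluated at genome
level) and ΔRSCU ≥ 0.08 (high expression). The 0.08 threshold is the
methods-level convention; it is a parameter, not a constant, since some
papers quote 0.8 in discussion text.

## Synthetic data: what it emulates, what it does not

The generator builds a circle of LSC + IRb + SSC + IRa with IRa the exact
reverse complement of IRb, per-region background GC (defaults 26.0/25.1%
single-copy, 43.3% IR over 85,572/18,608/10,042 bp — magnitudes of a
sequenced moss plastome), annotated CDS/tRNA/rRNA features including
intron-split, minus-strand, junction-crossing and IR-duplicated genes,
SSRs of all six classes, and dispersed repeats of all four types. Every
planted element is recorded in a ground-truth manifest, and the central
acceptance property of the repository is that each detector recovers its
planted elements with exact coordinates.

Two generator details are load-bearing. Planted elements are *sealed*:
the bases immediately flanking a planted SSR or repeat are forced to break
the pattern, otherwise a chance flanking match would lawfully extend the
maximal element and shift its coordinates. Planted dispersed repeats carry
exactly the scanner's mismatch budget (3), because a pair with spare
budget is, by the maximality definition, not maximal at its planted
coordinates. Similarly the IR boundary bases are forced to mismatch their
circular partners so the exact-match IR ends precisely at the planted
junctions.

Coding panels are sampled codon-by-codon from per-family probability
profiles; `at_bias_3` tilts third positions toward A/U, emulating the
strong A/U-ending preference of bryophyte plastomes (at full bias only the
start codon contributes a G third position, so GC3 equals exactly
1/n_codons). Alignments mutate rows independently from a common ancestor
at the per-site rate that makes expected pi equal the requested diversity
(pi = 2μ − (4/3)μ², inverted in closed form, valid up to the saturation
limit 0.75). All randomness flows from one integer seed through a single
generator using integer draws, so output is byte-identical across
platforms.

What passing tests on synthetic data do *not* show: real plastomes carry
compound and imperfect repeats, annotation idiosyncrasies (pseudogenes,
partial features), heterogeneous per-gene codon composition beyond a
single family profile, and alignment error — none of which the generator
models (mutations are i.i.d.; there is no substitution-model or indel
process). Numbers published for real accessions additionally depend on the
counting conventions flagged above (compound SSR merging, the IR
self-pair), so per-tool agreement on totals is expected only up to those
conventions.

## Problem sizes and numerical choices

Unit tests run on a ~22 kb compact plastome with the full anatomy at 1/6
scale; the acceptance tests and `scripts/acceptance.py` run the full-size
(124 kb) genome once for planted-recovery, 100 random 2 kb instances for
oracle equality, and 50 seeds for diversity recovery — sizes chosen so the
statistical checks are comfortably stable. Degenerate inputs are handled
by reporting missing values (pi with no retained sites, RSCU for
unobserved families, ENC with missing classes, PR2 with zero denominators)
rather than coercing to zero, and by structured errors where a computation
is genuinely undefined (no qualifying IR pair, zero-variance regression).

## Known limitations

- IR detection with `max_ir_mismatch > 0` uses greedy symmetric extension;
  it is exact for the default 0 and heuristic otherwise.
- The SSR scanner reports perfect repeats only; imperfect/compound SSRs
  are out of scope.
- `extract_shared_genes` intersects by gene name; paralog disambiguation
  beyond the IR-duplicate rule is not attempted.
- ENC is undefined (reported missing) for very short genes lacking whole
  degeneracy classes, as in CodonW.
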