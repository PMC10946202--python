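# Methods

`nanochromprof` characterises macronuclear (MAC) genome assemblies of
hypotrich ciliates, whose somatic genomes are fragmented into gene-sized
"nanochromosomes" capped by short telomeric repeats. This note records the
models, parameter choices and numerical conventions behind each analysis,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinate and rounding conventions

Internal coordinates are 0-based half-open `[start, end)`; GFF3 is read and
written 1-based inclusive, and a read→write→read round trip is the
identity. Each gene is reduced to one primary transcript — the mRNA with
the longest summed CDS, ties broken by lexicographically smallest
transcript id — because all statistics are per-gene. Models violating the
structural invariants (unsorted/overlapping intervals, CDS outside the
exon union, features on unknown contigs, end ≤ start) are dropped with a
logged reason code, never repaired.

Percentages are rounded half-up to 1 decimal and ratios to 2 decimals,
matching the precision at which such tables are conventionally printed, so
that reproductions of published per-class percentages and multi-exon
ratios can be compared exactly. GC content is (G+C)/(A+C+G+T); N bases are
excluded from numerator and denominator, and an empty or all-N sequence is
missing, not zero.

## Telomere detection and contig classification

Spirotrich MAC telomeres are tandem arrays of an 8-mer unit — `CCCCAAAA`
(C4A4) on the 5' strand, `TTTTGGGG` (T4G4) on the 3' strand — averaging
only ~21 bp, i.e. two to three unit copies per end. The scanner finds, at
each contig end, the maximal run matching the periodic extension of the
unit whose outermost edge lies within `max_offset` (default 5 bp) of the
end. The repeat phase is free, because assembly breakpoints do not respect
it, and partial units extend a tract when `allow_partial` (default on). A
call requires `min_units` (default 2) full copies: two copies reproduce
"repeated" while a single chance octamer is rejected.

Because tracts are so short, an exact-match scanner is fragile: one
sequencing error can leave no 16-bp clean run anywhere in a 21-bp tract.
The scanner therefore tolerates up to `max_mismatches` (default 2)
isolated substitutions, crossing a mismatch only when (i) at least half a
unit has already matched — a run never starts on junk — and (ii) the next
base continues the period — two consecutive period breaks always end the
run, so an error-free tract is never extended past its true edge. At 1%
per-base substitution noise inside telomeres, contig-class recall on
synthetic mixtures is 0.97–0.99; at zero noise, recovery of class, tract
length and subtelomere length is exact.

A contig's class is the number of ends carrying a call (0/1/2;
2-telomere contigs are the complete nanochromosomes). Both orientations
are scanned and the one with more total detected units is kept (ties keep
the input orientation); calls are reported in input coordinates, so
classification is invariant under reverse-complementing any contig.
Subtelomere lengths run from a tract's inner edge to the nearest gene
*feature* boundary (not CDS) — gene bounds are the only annotation
consistently available across species; a side without a telomere is
missing, not zero, and a gene overlapping a tract clamps the length to 0
and flags the record.

Whether a published "average telomere size" counts partial units is
generally unstated; here the full detected tract length (partials
included) is used throughout.

## Genome profile and correlations

N50 is the largest L such that contigs ≥ L sum to at least half the
assembly (verified against a brute-force cumulative-sum oracle).
Genes-per-chromosome fractions and the chromosome-length correlation table
are computed over 2-telomere contigs only — only complete chromosomes have
a well-defined length — with a flag to widen to the whole assembly.
Spearman's rho is the Pearson correlation of average-rank vectors (the
conventional tie handling), snapped to ±1 within 1e-14 so monotone data
give exactly ±1; correlated features are gene number, gene/CDS/intron
length, 5'/3' subtelomere length, intergenic length, GC and telomere
length. Per-contig GC decomposes exactly into a coverage-weighted mean of
CDS and non-CDS compartment GCs (identity holds to 1e-12 by construction,
checked on every synthetic run).

## Stop-codon usage and code inference

Hypotrichs read UAA/UAG as glutamine and terminate only at UGA. For every
CDS-bearing gene the spliced, strand-oriented CDS is split into codons
(lengths not divisible by 3 are skipped and logged; codons containing N
are ignored). The final codon increments the terminal count; TAA/TAG/TGA
at any other in-frame position increment internal counts. A codon is
called sense ("Q", the hypotrich reassignment target — a labelling
convention, not an inference) when its internal rate is at least
`min_internal_rate` (1 per kb CDS) and its terminal share is below
`max_terminal_share` (0.1); it is called stop when its internal rate is
below 0.05 per kb and it terminates at least 10% of genes; anything else,
or fewer than `min_genes` (50) CDS genes, is ambiguous. Under a standard
code in-frame stops essentially never occur, while a reassigned sense
codon appears at tens of occurrences per kb, so the regimes sit orders of
magnitude apart; calibration runs recover the correct code in 100/100
replicates per regime at ≥100 genes. Terminal shares are emitted as the
per-gene usage analogue alongside genome-wide internal rates, since
published stop-usage panels rarely state which was plotted.

## Intron spectrum and branch points

Ciliate introns are tiny; the spectrum is an integer-length histogram with
the reported mass inside a size band (default 28–40 bp). Peaks are strict
local maxima of the dense histogram within that band (a plateau flanked by
smaller bins is reported once, at its smallest length), listed in
descending count order. Donor/acceptor dinucleotides give the canonical
GT–AG fraction.

Because nearly all introns of the modal size class share one exact length,
positional base frequencies are computed by stacking those introns without
alignment, indexed from the 3' end (−1 = last base). A branch-point
adenosine is called at any position in the intron's second half
(−⌊L/2⌋ … −3) whose A frequency exceeds 50%; positions −1/−2 are the
acceptor AG and are excluded by construction. Profiles are withheld below
`min_introns` (50) members, where a 50% threshold is sampling noise. A
`window=±1` option stacks neighbouring length classes right-anchored
(3'-aligned). With A planted at −5 in 80% of 500 introns over a uniform
background, exactly {−5} is called in ≥95/100 replicates; under a pure
uniform background the false-call rate is ≤1% (the binomial tail at
n = 500, p = 0.25 versus a 0.5 threshold is astronomically small).

## Multi-genome comparison

One row per genome: chromosome/gene length summaries, GC, single-gene
chromosome fraction, exon-count make-up, multi-exon ratio, and the
5'-vs-3' subtelomere comparison. The asymmetry test is a two-sided
Mann–Whitney U on the per-contig 5' and 3' subtelomere length populations
(published figures of this kind print p-values without naming a test;
Mann–Whitney is chosen because the lengths are non-normal, unpaired
populations). The exact null distribution is used when the smaller sample
has ≤20 values and no ties occur, otherwise the tie-corrected normal
approximation; direction is assigned by medians only when p < 0.05. The
handful of per-species tests are reported as raw p-values, without
multiplicity correction, with a note in the output metadata.

## The synthetic genome generator

The generator emits FASTA + GFF3 + truth tables with the statistical
structure the analyses assume, under one seed that fully determines the
output (byte-identical reruns). Defaults emulate a hypotrich MAC assembly:
class mixture 0.302/0.351/0.347 over 0/1/2-telomere contigs; telomere
tracts of ≥2 full units (geometric, p = 0.8421) plus a uniform 0–7 bp
partial, mean ≈ 21 bp; 1/2/≥3 genes per chromosome at 0.823/0.137/0.040;
CDS lengths gamma-distributed with mean ≈ 1530 bp; background (spacer and
intron) composition i.i.d. at GC 0.2839 with CDS codons at GC 0.30; half
of genes intronless, otherwise 1–4 GT–AG introns with a bimodal length
law placing 72.43% of mass in 28–40 bp and strict peaks at 31 and 34 bp;
5' subtelomeric spacers ~N(150, 40) and 3' ~N(100, 30) (the study
organism's 5'-longer asymmetry); the ciliate code with in-frame TAA/TAG
planted at 5% of codons and TGA terminal. Random draws exclude TAA/TAG/TGA
from ordinary body codons, so planted Q codons are exactly the in-frame
TAA/TAG of the emitted genome and recovery can be compared exactly.

Two constructions keep truth exactly re-derivable from the emitted
sequence: the repeat period is broken for two bases just past each tract's
inner edge (a property random subtelomeres have with probability ≈ 15/16
per end anyway), and contigs are emitted in the chromosome's conventional
orientation (5' C4A4 cap left). Orientation flipping is available as a
knob (`orientation_flip_prob`) for testing classifier invariance; it is
off by default because C4A4/T4G4 are mutual reverse complements, so strand
cannot be recovered from telomeres and random flips would erase the
contig-relative 5'/3' subtelomere asymmetry that the comparison module is
meant to detect. An optional branch-point A is planted at position −5
(3'-anchored) in a configurable fraction of introns; the default fraction
is 0, matching organisms with no conserved branch point. A separate
`corrupt` tool applies i.i.d. substitutions genome-wide for stress tests,
and `telomere_error_rate` mutates tract bases only.

What the generator does **not** emulate: repeat families and low-
complexity sequence, UTRs (exons equal CDS), alternative isoforms,
sequencing-depth structure, indels, chimeric or truncated-gene contigs,
and MIC/IES architecture. Passing recovery tests therefore demonstrates
correctness of the measurement logic on clean, well-formed input — not
robustness to mis-assembly or annotation error, which real data would add.

## Problem sizes and runtime

Recovery and invariant checks run on 1000- and 700-contig genomes
(~1.5–2.2 Mb, ~1200 genes, ~1000 introns), chosen so that every class and
the modal intron length class are well populated; calibration studies use
100 replicates of 500 introns (branch point) and 100 replicates per
genetic code of ≥100-gene genomes with shorter CDSs (mean 120 codons),
which separate the code regimes just as clearly as full-length genes. The
full test suite runs in well under a minute; `scripts/acceptance.py`
regenerates and re-measures everything in a few seconds.

## Known limitations

- Telomere units are supplied, not discovered; non-spirotrich repeat units
  work but defaults are C4A4/T4G4.
- The code detector distinguishes stop-vs-sense for the three standard
  stop codons only and labels reassigned codons "Q" by convention; it is a
  frequency heuristic at desk scale, not a replacement for profile-based
  genetic-code inference.
- Branch-point calling is positional (frequency > 50% at one 3'-anchored
  position in one length class); it does not model motif context or
  introns whose branch point drifts with length.
- Subtelomere statistics require both a telomere call and at least one
  annotated gene; contigs failing either are simply absent from those
  populations.
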