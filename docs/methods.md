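# Methods

This note records the models, parameter choices and numerical conventions
behind `tismap`, and what its synthetic benchmarks do and do not
demonstrate.

## Problem and model

A transfected plasmid integrates into a host genome at unknown loci, either
as a (near-)complete expression unit — promoter, coding sequence and
polyadenylation signal, the configuration that can actually express — or as
sheared fragments.  Long reads spanning an integration junction are
*chimeric*: part plasmid, part host.  The pipeline detects plasmid-derived
segments inside each read, treats the host-derived sequence immediately
flanking them as the localising signal, anchors those flanks on the
reference assembly, and reduces the resulting per-read breakpoints to a
small set of integration sites with a class label.

Coordinates are 0-based half-open everywhere internally; the only 1-based
surfaces are GFF3 input and the `Chr:pos` rendering in reports.

## Read filtering

Reads with length < 1000 bp or mean quality < 7 are removed; both removal
conditions are strict `<`, so boundary reads are kept.  Mean quality is the
probability-space mean `-10·log10(mean 10^(-Q/10))`, the definition used by
the common long-read filtering tools; by Jensen's inequality it never
exceeds the arithmetic mean of Phred scores and is dominated by the worst
bases.  An arithmetic-mean switch (`qc.arithmetic_mean`) exists for
sensitivity analysis because the filtering convention is not universal.

## Local alignment engine

Seeding uses exact k-mers (default k = 11; k-mers containing N are skipped,
and subject k-mers occurring more than 64 times are ignored as repetitive).
Seeds sharing a diagonal merge into runs; runs chain greedily when
query-ordered with gap ≤ 200 bp and diagonal shift ≤ 32.  Each chain is
extended from its first seed in both directions by banded affine-gap DP
(Gotoh recurrences; gap of length L costs open + L·extend) with BLAST-style
X-drop termination (default X = 100 score units).  The band half-width is
max(48, chain diagonal spread + 24), which covers the indel drift expected
at ≤ 10 % error over the segment lengths in play (drift is a mean-zero
random walk with sd ≈ √(L·p_indel) ≈ 16 for L = 5 kb at 4 % indels).

Scoring defaults are the standard nucleotide local-alignment values
(+2/−3, gap open 5, extend 2), so hit/no-hit decisions track the tool this
engine replaces.  N scores as a mismatch against everything, including N.
Extension runs in two passes: a score-only rolling-row pass bounds every
chain, and the traceback pass (which allocates band matrices) runs only for
chains that can reach the caller's E-value gate — a pure optimisation that
leaves the hit set at the gate unchanged.

Determinism: traceback ties resolve diagonal > up > left; equal-scoring
hits order by smaller subject coordinate; returned hits are reduced so no
two overlap by more than 50 % on the query (junction mapping requests the
unreduced list where runner-up placements feed the ambiguity flag).

A full Smith–Waterman (Gotoh) implementation with the same tie rules is the
testing oracle, guarded to 10^7 DP cells.  On planted homologies (≥ 80 bp,
≥ 85 % identity, ≥ 1 exact 11-mer) the engine's top score equals the
oracle's optimum; the oracle itself is cross-checked against Biopython's
`PairwiseAligner` in the test suite.

## E-value calibration

λ solves `Σ p_i p_j e^{λ s_ij} = 1` by bisection on (0, 10] to 1e-12.  K
uses the classical lattice series: with S_k the k-step score-sum
distribution (computed by convolution), δ the gcd of the attainable step
scores, and H the relative entropy,

    σ = Σ_k (1/k) [ P(S_k ≥ 0) + E(e^{λS_k}; S_k < 0) ]
    K = δ λ e^{−2σ} / ( H (1 − e^{−λδ}) )

truncated when terms fall below 1e-12.  The calibration reproduces the
published ungapped nucleotide values — (λ, K) = (1.10, 0.333) for +1/−1,
(0.634, 0.408) for +2/−3, (1.33, 0.621) for +1/−2 — to the printed
precision.  Gapped statistics are approximated by the ungapped values of
the same scheme: the only consumer is a pass/fail gate at E < 1e-30, which
spans thirty orders of magnitude, so ±tens of percent on K is immaterial.
Search-space lengths m and n are raw sequence lengths (no edge-effect
correction), with the plasmid as query against the read (m = plasmid
length) and the flank as query against the genome, preserving the original
search orientations.

## Junction mapping

Segments within 50 bp on the read, collinear on the plasmid and on the same
strand, merge before flank extraction (noisy reads split one integrated
fragment into several HSPs).  Up to 500 bases of flank are taken on each
side of the outermost segments; gaps between internal segments yield
tagged internal flanks.  Flanks shorter than 50 bp are discarded: at the
default scoring a 50 bp perfect match scores 100, below the ~145 needed to
reach E < 1e-30 against a megabase genome, so such flanks can never anchor
and would only add noise.

Each flank keeps one best genome hit (single target, single HSP; ties to
the smaller coordinate).  Because keeping a single target silently discards
near-ties, a flank whose runner-up placement scores ≥ 95 % of the best is
flagged ambiguous, and the flag propagates to any site the read supports.

The breakpoint is the genome coordinate adjacent to the anchor edge that
touches the plasmid segment: anchor end (`s_end`) for a flank left of its
segment on the + strand, anchor start for a flank right of it, mirrored on
the − strand.  Reads are processed in native orientation; this rule is
where strands are normalised.

## Site calling and classification

Breakpoints cluster by single linkage along each chromosome with a 100 bp
window — generous against the ≤ 10 bp jitter observed after DP anchoring at
8 % read error, and far below the ≥ 10 kb spacing of distinct planted
sites.  The site coordinate is the median member breakpoint (lower middle
on even counts), robust to stray anchors; the smallest and largest member
breakpoints are reported as auxiliary junction columns since a single
printed coordinate cannot distinguish left junction, right junction and
midpoint.  Support counts distinct reads; `min_support` defaults to 1 (the
original study's per-site depth is unstated) and the noisy benchmark uses 3.

A supporting read is unit-bearing when its merged plasmid segments cover
≥ 90 % of the annotated unit interval.  A site with at least one
unit-bearing read is `full_unit` even when fragment-bearing reads also
support it (`classes_present` records both): complete-unit presence is the
biologically interesting signal.  Without a unit annotation every site is
`fragment`, with a warning.

Annotation queries use the single-base site position, matching the
single-coordinate site representation; exon beats intron, ties go to the
first gene by coordinate, and UTR features count as exonic.  "Near" an
accessibility peak is within 1 kb by default (the qualitative observation
this mirrors gives no number).  Host-gene expression is copied verbatim
from a user table and never thresholded into low/high.

## Synthetic data

The generator emulates the study design at desk scale.  Defaults: 3
chromosomes × 1 Mb at GC 0.4 with gene models covering ~30 %; a 5 kb
plasmid (3 kb backbone + 2 kb unit); 4 full-unit insertions confined to
chromosome 1 (the unit plus 100 bp plasmid context) and 4 fragments of
200–1500 bp placed genome-wide, ≥ 10 kb apart and from chromosome ends;
reads at 15× coverage with log-normal lengths (mean 8 kb, sd 6 kb, min
200 bp) and i.i.d. per-base errors of 4 % substitution + 2 % insertion +
2 % deletion, qualities drawn around Phred 20 (correct bases) and 6
(error bases).  Error-free bases at Phred 20 and 8 % total error put
typical reads at mean Q ≈ 15, above the filter, while the 200 bp length
floor leaves some reads for the length rule to remove.  This scenario runs
the whole pipeline in a few minutes on one CPU; the sizes are the
package's standard benchmark conditions.

Two generator properties matter for interpretation:

* **Clean junctions.**  Each insertion point is resampled until the first
  4 bases at all four junction-adjacent pairings (insert edges vs genomic
  continuation, plasmid context vs genome) are pairwise mismatching.
  Random junctions carry ≥ 1 bp of chance microhomology ~25 % of the time,
  which makes the "true" coordinate ambiguous — the same modified genome
  arises from several (position, insert) pairs, and any caller's optimal
  local alignments shift by the shared bases.  Clean junctions make the
  planted coordinate well defined, so exact-recovery tests measure the
  pipeline's arithmetic rather than representation ambiguity.  Real
  junctions do not have this property: on real data, coordinates should be
  read as exact only up to microhomology.
* **i.i.d. errors.**  The error model has no homopolymer or sequence bias.
  The pipeline's robustness claims are therefore parameterised by total
  error rate, not error structure; structured nanopore error (and target-
  site duplication at insertions, which the generator also omits) could
  bias breakpoints by a few bases in ways these tests do not probe.

Passing the synthetic benchmarks shows the pipeline recovers planted truth
under the stated error regime; it does not certify performance on real
nanopore data, chimeric library artifacts, or repetitive genomes (the toy
genome is i.i.d. random, so flank anchoring is nearly always unique).

## Degenerate inputs and edge rules

Reads shorter than the seed produce no hits (warning).  Reads without
qualities pass the quality rule by definition and are counted.  A segment
starting at read position 0 (or ending at the read end) yields no flank on
that side and marks the evidence clipped.  `evalue_max = 0` yields an
empty, internally consistent run.  Sites beyond the declared chromosome
length abort the density map as corrupt input.  Multi-copy tandem
insertions at one locus are reported as one site (copy-number estimation
is out of scope), and clone identity is carried through as a label only —
`tismap compare` reports union/intersection of two runs' site lists
without deciding how they should be combined.

## Reproducibility

Every random artifact derives from explicit seeds; the pipeline itself is
randomness-free with fixed tie rules and sort orders, so identical inputs
give byte-identical outputs.  `scripts/acceptance.py --seed N --out f.json`
re-runs the standard study end to end and writes every measured quantity;
all numbers quoted in the README are outputs of that script or of the test
suite.
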