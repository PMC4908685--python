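# Methods

## The screen

Input records are spliced alignments: blocks in 0-based half-open BED
coordinates, an alignment strand, and a signed intron-orientation integer.
The alignment strand says how the cDNA aligned, not how it was
transcribed; transcription direction is the alignment strand when the
orientation integer is positive, its opposite when negative, and
undetermined when zero.  Undetermined records are dropped automatically
(and counted) rather than "removed manually": the screen is meant to run
unattended.  Only spliced records (≥ 2 blocks) are screened, so every
accepted call is backed by splicing evidence.

A record becomes a chimera call when all three criteria hold:

* **C1 (antisense initiation)** — the 1-bp TSS (alignment start on plus,
  last aligned base on minus) lies inside an annotated L1 whose strand is
  opposite the transcription direction.  If several antisense elements
  contain the TSS, the anchor is the element with the largest overlap with
  the TSS-containing block, ties to the smaller start — deterministic and
  logged in the call.
* **C2 (chimerism)** — ≥ 1 bp overlap between some block and some
  annotated gene exon (no minimum beyond 1 bp; the annotation, not an
  overlap heuristic, carries the information).  One `PairwiseOverlap`
  record per overlapped gene stores orientation (sense iff transcript and
  gene strands agree) and the signed distance from gene TSS to transcript
  TSS, positive meaning downstream in the gene's orientation.
* **C3 (exonization veto)** — no *independent* record (any different id;
  secondary alignments of the same id do not veto) shows the exon–L1–exon
  structure over the anchor: antisense to the element, ≥ 1 block
  overlapping it, and ≥ 1 block entirely on each side.  The veto is per
  anchor element, not per gene: one exonization-supporting record removes
  every candidate anchored in that element, because the ambiguity it
  demonstrates is a property of the element.

Multi-alignment records (same id aligned more than once) are flagged on
the call but never removed — each alignment is judged on its own
coordinates.  Subfamily age classes default to: L1HS = {L1HS, L1PA1};
L1PA2_8 = L1PA2…L1PA8; ancient_primate = other L1PA/L1PB/L1P names;
ancient_mammalian = the rest of the L1 family (L1M*, L1ME*, HAL1* —
half-L1s are included).  The map is overridable because the name→class
binning is a convention, not a fact of the annotation.

Long-read isoform validation is the same screen run on a second record
set, followed by intersection of accepted gene sets.

## Coding potential

ORFs are ATG-initiated, scanned in the three forward frames only
(sequences are already in transcription orientation; a reverse-strand scan
would contradict the screen's strand resolution).  Maximal means first ATG
after the previous stop; a codon containing N ends translation at the
preceding codon; 3'-incomplete ORFs are reported with `has_stop=False`;
lengths exclude the stop.  The coding call is ≥ 100 aa, applied to the
longest ORF per transcript.  The threshold follows the convention that
separates putative peptides from lncRNA-like transcripts; note it excludes
genuine short peptides (e.g. the ~71-aa ORF0 of young L1 5' UTRs).

## Consensus TSS placement

The transcript's first 1000 nt (the 5' end is what is being placed) are
locally aligned to the class consensus in both orientations.  Scoring:
match +2, mismatch −3, gap open −5, gap extend −2, where a length-k gap
costs open + k·extend; defaults chosen for the 80–99 % identity range of
L1 copies vs their consensus, configurable.  The engine is
Bio.Align.PairwiseAligner in local mode; tests hold it to an independent
quadratic affine-gap DP oracle.  Alignments scoring below 40 are treated
as unmappable and counted — on 100–300 bp queries, lower scores are
dominated by spurious anchors.  The TSS percent position is 100 ×
(consensus coordinate of the transcript's 5'-most aligned base) /
consensus length; for reverse-complement alignments that base maps to
`consensus_end − 1`.  One consensus per age class (4 sequences) rather
than per subfamily: within-class 5' UTR homology is what makes the
percent-position comparable, and the class→consensus map is configuration.

## Motif scanning

Counts + pseudocount (default 1 % of the column sum, split evenly across
bases) are column-normalized, divided by a uniform background (0.25 each)
and log2-transformed.  The relative score normalizes by the matrix's
attainable extremes (sums of per-column log-odds minima/maxima), matching
the common JASPAR-scan convention so a 90 % threshold is comparable.  Both
strands are scanned; minus-strand hits are reported on forward
coordinates.  Windows containing non-ACGT bases never hit.  Report tables
convert to the 1-based inclusive dialect (half-open [447, 453) prints as
448 to 453).

## Signal tracks and metaprofiles

Coverage is full-interval read depth (not 5'-end counting) per base, ×10⁶
/ library size; the library size is supplied by the caller because a
regional slice cannot know the library's total mapped reads.  Each
supplied record counts once (multi-mapping policy is upstream of this
package).  log2FC uses ε = 0.25 RPM on both numerator and denominator
(configurable); LOESS smoothing is tricube-weighted degree-1 local
regression over a span α (default 0.1) via statsmodels lowess with
robustness iterations off — exact on constants and straight lines, which
the tests assert at machine tolerance.

Metaprofiles average per-bp RPM depth in 20 × 100-bp bins over
[TSS − 1000, TSS + 1000), with minus-strand windows reversed before
averaging so bin 0 is always 1000 bp upstream of transcription; windows
leaving the reference are dropped and counted, not padded.  If an input
read set is given its binned profile is subtracted per TSS.
`strand_match=True` counts only reads on the TSS strand — the mode for
strand-specific nascent transcription (GRO) reads.

## Statistics

The strand-bias test is a chi-squared goodness of fit of the
sense/antisense overlap counts against an equal split — the only null
consistent with asking whether chimeras prefer either orientation; the
expected proportions are a parameter for other uses.  For extreme
statistics the survival function underflows, so a log-space value is also
computed (df = 1 via the normal log-CDF identity, general df via the
upper-incomplete-gamma asymptotic).  BH FDR is the standard step-up with
monotonicity enforcement.  Report percentages are rounded to one decimal
and always carried with numerator and denominator.

## The synthetic cohorts

The generator lays out independent loci on 1–few synthetic chromosomes:
each chimera locus holds an L1 whose genomic footprint is consensus
sequence (mutated at a configurable per-base rate, default 0.02; young
elements full length, ancient elements 5'-truncated by 25–45 %), a
two-exon gene, and spliced records whose first 150-bp block starts at the
planted TSS inside the element, antisense to it, splicing into the gene
exon.  Young-class TSSs are planted uniformly in consensus positions
150–600 (the antisense-promoter window of the 5' UTR; a fixed position,
e.g. 400, can be configured), ancient-class TSSs in the final 20 % of the
element.  Decoy loci add an independent exon–L1–exon record over the same
element; plain, orientation-zero and secondary-alignment records complete
the cohort.  Transcript sequences are extracted from the synthetic genome
through the same blocks the screen sees, so consensus mapping and ORF
calling operate on exactly the records the screen accepts.  Coding status
is planted by writing an ATG + 100–140 codon + stop ORF into the gene-exon
block (shared by all records of a locus); non-coding loci are scrubbed —
any ≥ 100 aa ORF is disrupted by an inserted stop outside the
consensus-derived 5' region, iterated to a fixpoint — so truth labels are
guaranteed, not probable.  Reads are planted as 36-bp intervals 0–200 bp
downstream of each TSS on the TSS strand over a uniform background, with
library sizes fixed at 10⁶.

Default cohort sizes (50 chimeras / 20 exonization decoys / 30 plain gene
ESTs / 5 orientation-zero / 5 multi-alignment records, sense fraction
0.921, coding fraction 0.27, age-class weights 2.6 / 15.6 / 15.6 / 66.3 %)
mirror the benchmarking conditions the test suite and acceptance script
use; larger runs only change the counts.  Every output is a deterministic
function of the seed, byte-for-byte.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: realistic genome composition (GC, nested or
fragmented repeats, tandem L1s), EST sequencing error beyond point
mutations on L1 footprints, alignment ambiguity (multi-alignments are
planted at barren loci, not homologous ones), overlapping genes, and
biological mixtures of ASP and exonization at one element.  The screen's
perfect sensitivity/specificity on these cohorts certifies the logic of
the criteria, not performance on noisy annotations.

## Problem sizes and runtime choices

Tests and the acceptance script run the screen on 20 seeded default
cohorts (~130 records each), oracle-equivalence suites on 100 random
instances per engine (queries ≤ 60 bp for the alignment DP oracle), TSS
recovery on 15–20 transcripts per condition, and coding recovery on a
1000-transcript cohort — sizes at which the brute-force oracles stay
exact and the whole suite completes in well under a minute of compute per
stage.

## Known limitations

* C3 requires only the exon–L1–exon structure of the vetoing record, not
  that it splice into the same gene; whether a same-gene restriction is
  more faithful is undecidable from the screen's definition alone.
* Consensus placement reports the single best local alignment; paralogous
  3'-end homology among ancient subfamilies can in principle attract a 5'
  end to the wrong region — the min-score threshold mitigates but does not
  eliminate this.
* The PWM scanner calibrates no p-values; the relative score is a matrix-
  intrinsic scale.
* `coverage_rpm` counts each supplied record once; fractional weighting of
  multi-mappers must happen upstream.
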