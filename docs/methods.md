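# Methods

## The model

A rolling-circle small-RNA library molecule is a circle of length
L = |insert| + |adapter| (inserts 15–200 nt, adapter ~21 nt). Reverse
transcription rolls the circle out into a linear concatemer of R tandem
copies, entering the circle at an arbitrary phase and stopping mid-copy, so
a read is

    read = rot_p(template) repeated R times, minus up to one template
           length at the tail,

on either strand, passed through the sequencer's error channel. Consensus
calling inverts this generative model copy by copy: find the period,
segment the copies, vote per column, resolve the rotation against the known
adapter, and trim.

## Simulator

`rollcall.simulate` implements exactly the generative model above.

* **Error channel.** Per original base: delete with probability
  `del_rate`; otherwise substitute (to a uniformly random *different* base)
  with probability `sub_rate`; after each emitted base, insert a uniformly
  random base with probability `ins_rate`. Errors are i.i.d. across
  positions and reads.
* **Qualities.** A constant Phred score q = round(−10·log₁₀(total error
  rate)), clipped to [2, 40] (40 when the channel is error-free). The
  implied error probability is then within the rounding factor 10^0.05 ≈
  1.12 of the configured rate. Optional per-base jitter (`quality_jitter`)
  is available; the pipeline only consumes the mean.
* **Phase and truncation.** The entry phase is uniform on the circle and
  the tail truncation uniform in [0, L), so first and last copies are
  usually partial — deliberately exercising the margin/flank handling of
  the repeat detector. `fixed_phase` / `fixed_tail` pin both for exact
  construction tests.
* **Defaults.** Repeat counts uniform 5–50 (the empirical copy-number
  distribution of real libraries is not well characterised; this spans the
  useful range and is configurable), strand fraction 0.5, seed 0. The
  noisy benchmark model is 8% total error split 50/25/25 between
  substitution/insertion/deletion — a round figure representative of
  current nanopore chemistry — over repeat counts uniform 10–40.
* **What it does not emulate.** No homopolymer-length or sequence-context
  error structure, no quality–error correlation along the read, no chimeric
  or adapter-dimer molecules, no coverage bias between templates. Passing
  tests therefore demonstrate correctness of the *inference* under an
  idealised independent-error channel, not performance on any particular
  flowcell chemistry.

## Read filter

Length strictly greater than `min_length` (default 1000) and mean quality
at least `min_mean_quality` (default 7). "Mean quality" is the arithmetic
mean of the Phred scores; the error-probability-weighted mean used by some
basecallers is available as `quality_metric="error_mean"` (it is dominated
by the worst bases and is always ≤ the arithmetic mean).

## Repeat detection

Six parameters, with defaults: k-mer size k = 5, sliding window 1000 bases
(50% overlap; the stride is a design choice — overlap avoids boundary
misses), peak height 10, gap 200, margin 200, letter consistency 0.5.

* A k-mer reaching `peak_height` occurrences within any single window is a
  periodicity candidate. A uniform random 1 kb sequence has ~1 expected
  occurrence per 5-mer, so reaching 10 by chance is vanishingly rare
  (measured false-positive rate < 1% over 1000 random reads).
* Candidate hit positions are split into runs at gaps > `gap`; runs of ≥
  `peak_height` hits span a region, extended by `margin` and clipped to the
  read; overlapping regions merge.
* **Period** = the mode, across contributing runs, of the rounded median
  inter-hit spacing. The median is robust to hits lost to errors (a lost
  hit doubles one spacing); the cross-k-mer mode suppresses k-mers that
  occur more than once per unit, whose median spacing is not the period.
  Rounding is half-up; mode ties break to the smaller period.
* **Anchoring.** Units are cut at the occurrences of one anchor k-mer: the
  most frequent k-mer whose own median spacing lies within ±25% of the
  period *and* whose inter-hit gaps are < 0.75 period in at most 20% of
  cases. The second condition disqualifies k-mers occurring twice per unit
  (their spacings alternate short/long; the long one can masquerade as the
  period while the short ones betray the duplication). Count ties break on
  the strand-canonical form min(kmer, revcomp(kmer)), and flank lengths are
  judged inclusive of the bounding anchor k-mer, which together make period
  and unit count exactly invariant under reverse complementation of the
  read.
* **Segmentation.** Spans between consecutive anchor hits covering j ≈ 2+
  periods (anchor lost to errors) are split evenly into j pieces; pieces
  and flanks shorter than half a period, or longer than 1.5 periods, are
  discarded. On error-free concatemers this yields the true copy count ±1
  (the partial first/last copies are kept only when at least half a
  period long).

Known limitation: when a region's `margin` extension reaches into genuinely
non-repetitive sequence (real reads with flanking junk), the extended flank
can contribute a noisy unit; on concatemer-only reads the margin clips at
the read boundary and the issue does not arise. Templates that are
internally repetitive at every k-mer (e.g. dinucleotide repeats) leave no
eligible anchor; such regions are rejected and logged rather than
mis-segmented.

## Consensus

Center-star multiple alignment: the unit closest to the median length is
the center (index ties to the first), every other unit is globally aligned
to it (match +2, mismatch −3, gap open −5, gap extend −2; a gap of length g
costs 5 + 2(g−1)), and pairwise alignments merge under "once a gap, always
a gap" with shared gap columns left-aligned — which makes the resulting
consensus independent of unit order. Units are near-identical short
strings, so center-star is essentially optimal here and has a brute-force
enumerable oracle; a partial-order aligner could be slotted behind the same
interface.

Column calling: emit the plurality base (ties A<C<G<T) unless the gap
symbol is the *strict* plurality with frequency ≥ the letter-consistency
threshold (0.5), in which case the column emits nothing. Insertion errors
appear in one unit each, producing 1-base columns that are suppressed;
deletion errors produce isolated gaps that are outvoted. The record also
carries the mean identity of units to the consensus over emitted columns.

## Phasing and trimming

All |s| rotations of the consensus are enumerated in offset order; the
adapter, as given and reverse-complemented (the consensus derives from
cDNA and may be either strand), is aligned globally to each rotation. For
each alignment the gap-free blocks touching the rotation's first or last
position are scored by their *matching* columns — a gap-free run of
mismatches carries no evidence of adapter placement — and the first
rotation achieving the maximum wins; orientation decides the strand label,
and minus-strand inserts are reverse-complemented to reference sense. The
adapter footprint contiguous with the anchored end is trimmed; what
remains is the insert.

A consensus whose best anchored run matches fewer than half the adapter's
bases (configurable) is flagged unphaseable and excluded from counting, as
is an empty insert (adapter-only circle). With a 21 nt adapter the chance
that a random 42-mer reaches 11 matching anchored columns in some rotation
is small but not zero; the threshold trades a rare false phase against
discarding genuinely noisy consensuses.

## Accuracy and bias

* **Identity.** Soft-clipped local alignment (same scoring); aligned_bases
  = alignment columns, edit_distance = mismatch + gap columns,
  percent_identity = 100·(aligned − edits)/aligned. The numerator equals
  the matching columns, so terminal errors that local alignment clips do
  not count against identity — the flip side of soft-clipping. A
  reference-length denominator, which charges clipped bases, is available
  via `denominator="reference"`. Pairs with no positive-scoring alignment
  (possible only for near-disjoint base content) are flagged at 0%.
* **Pool mapping.** Nearest pool member by global edit distance (edlib),
  accepted when the distance is ≤ 2 and the best hit unique; ambiguous or
  distant inserts count as unmapped. Pool members are short and mutually
  distinct, so bounded edit distance reproduces what a short-read mapper
  would do while remaining exactly testable.
* **Normalisation.** expected = total_mapped / pool_size;
  normalized = raw / expected (0 stays 0). With every member counted, the
  mean normalised count is 1 by construction.
* **Bias.** Percentage of pool members with normalised count within
  two-fold of expectation, read as the closed interval [0.5, 2.0]. The
  metric is invariant under rescaling all raw counts by a positive
  constant.

## Benchmark problem sizes

The bundled benchmarks (`rollcall.benchmarks`, also driven by
`scripts/acceptance.py`) use 1,000 noisy reads for the end-to-end accuracy
measurement, 200 error-free reads for the exact-recovery oracle, 200
insert/reference pairs for the identity-oracle comparison, and 200 noisy
reads for the repeat/length correlation — sizes at which the stochastic
fractions are stable to well under a percentage point while a full run
stays in the tens of seconds on one CPU. The error-free recovery benchmark
draws repeat counts uniform 15–50 and disables the length filter: with
peak height 10, a template k-mer needs ~11 complete copies to be
detectable at all, and the check targets recovery, not read QC. In the
noisy benchmark the ≥ 95% / = 100% identity percentages are computed over
the inserts the pipeline produces; reads rejected by the 1000 bp length
filter (repeat count below ~24 for the 42-mer circle) contribute none.
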