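# Methods

This note records the model as implemented, the numerical and design
choices that were genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Generative model

**Shearing.** Each simulation round tiles every chromosome of length
*L* with consecutive fragments: a uniform offset *u* ~ U[0, min(kθ, L))
is drawn per round, then fragment lengths are i.i.d. Gamma(shape *k*,
scale *θ*), drawn as continuous values and rounded half-up to integer
bp (minimum 1). Fragments partition [u, L) exactly; the fragment
truncated at the chromosome end is kept only if it reaches the minimum
length (the read length, when run through the pipeline). The random
per-round offset decorrelates cut sites across rounds — without it all
rounds would share fragment boundaries and replicate simulations would
be artificially concordant. Fragments shorter than the read length are
removed, with a counter, *before* pulldown, so one pulled fragment maps
to one emitted read (pair).

**Binding.** Peaks are first resolved into disjoint segments carrying
the per-base maximum score (so redundant or overlapping peak entries
cannot double-bind). A fragment overlapping at least one segment by at
least 1 bp is bound with probability equal to the maximum score among
the segments it touches; fragments overlapping nothing are never bound.
Any-overlap (rather than overlap-proportional) binding is a modeling
choice; the difference is confined to the one-fragment-length border of
each peak.

**Pulldown.** The model quantifies only the *relative* pulldown
probability of bound versus unbound fragments, the ratio
α = s(1−f)/((1−s)f); absolute pulldown efficiency is unidentifiable
from read data and deliberately unmodeled. Selection of `n_target`
fragments is weighted sampling without replacement with weight α for
bound and 1 for unbound fragments, implemented as **systematic
probability-proportional-to-size (PPS) sampling** after a random
permutation: inclusion probabilities are exactly πᵢ = min(1, c·wᵢ) with
c solved so Σπᵢ = n_target, and exactly n_target fragments are drawn.
This design was chosen over sequential weighted sampling
(Efraimidis–Spirakis) deliberately: sequential sampling progressively
depletes the high-weight class, so at the sampling fractions used in
realistic runs the realized bound/unbound ratio falls measurably below
α. Under PPS the expected selected-bound fraction is exactly
α·f_pool/(α·f_pool + 1 − f_pool) whenever no weight saturates (c·α ≤ 1),
which makes the enrichment ratio of the output match the closed form.
When the bound pool is too small for the requested draw the cap binds
and enrichment saturates — the summary's pool counts make this
visible, and the practical remedy is more simulation rounds.

**PCR.** Each selected fragment is emitted i ~ Geometric(p) times on
support {1, 2, …} (P(i) = p(1−p)^{i−1}); mean multiplicity 1/p. The
pulldown target is set to `numreads·p` so amplification lands on the
requested read count in expectation; the surplus is randomly truncated
and a deficit is topped up by extra pulldown passes (the deficit is
O(√numreads), so the extra passes are negligible in size). PCR
duplicates inherit their fragment's single-end strand: a duplicate is
the same molecule, and this keeps position+strand duplicate grouping
consistent with how duplicates are marked in real pipelines.

**Sequencing.** Single-end reads come from a uniformly chosen fragment
end (per distinct fragment), reverse-end reads reverse-complemented;
paired-end mate 1 reads the 5′ end forward and mate 2 the 3′ end
reverse-complemented, so the insert size equals the fragment length.
Per *emitted* base exactly one of {deletion, insertion, substitution,
none} occurs, with probabilities (del, ins, sub, 1−del−ins−sub):
substitution emits a uniformly chosen different base, insertion emits a
uniform base without consuming template, deletion skips one template
base and emits the next unchanged. If the template is exhausted before
the read is full, the read is padded with N — a documented convention,
as is the rule that template N bases pass through untouched. Quality
strings are a constant Phred-30 character: the model contains no
quality-score process and inventing one would suggest information the
simulation does not carry.

## Learning

* **Fragment length (paired).** Maximum-likelihood gamma fit
  (`scipy.stats.gamma.fit`, location fixed at 0) on |template length|
  of proper pairs, counted once per pair. Requires ≥ 50 observations;
  non-positive lengths and zero-variance samples are errors, not
  warnings.
* **Fragment length (single-end).** Strand cross-correlation: the
  Pearson correlation between forward-read and reverse-read 5′
  coverage profiles is computed at shifts d ∈ [readlen+1, 1500] (the
  phantom peak at the read length is excluded by construction),
  smoothed with a 31-bp triangular kernel (per-shift correlations are
  noisy; a triangular kernel preserves a unique peak), and the argmax
  shift is returned as the mean fragment length. The gamma model is
  then completed with a configurable default shape (5) and scale =
  mean/shape. This is an approximation and is flagged as such in the
  learn report: the argmax tracks the dominant shift, which for
  strongly right-skewed length distributions sits below the mean, and
  the signal sharpens as binding sites get narrower. It is reliable
  for point-like (TF-style) peaks and moderately concentrated length
  distributions; for broad domains, paired-end data should be used.
* **f.** Score-weighted merged peak length divided by genome length,
  clipped to (1e−6, 1−1e−6) so α is always finite.
* **s.** Fraction of non-duplicate reads whose leftmost aligned
  coordinate lies in a merged peak, clipped the same way. This is the
  uncorrected reads-in-peaks ratio (the FRIP convention); no
  correction is applied for reads expected in peaks by chance.
  Anchoring at the leftmost coordinate rather than the strand-aware 5′
  base shifts membership by less than one read length — negligible at
  peak scale — and requires no read-length bookkeeping.
* **p.** 1/n̄ over the duplicate histogram. Without duplicate flags,
  fragments are grouped by (chrom, leftmost position, strand) for
  single-end and (chrom, leftmost position, template length) for
  paired data — the same keys duplicate-marking tools use. Distinct
  fragments that collide on these keys by chance merge into one group;
  at toy-genome read densities this biases p down by ~2% at most,
  which is inside the recovery tolerances below.
* **MAPQ.** Records below MAPQ 10 (configurable) are excluded from all
  estimators to avoid multi-mapping artifacts.
* Sequencing error rates are user-set; no estimator is provided (they
  are not identifiable without alignments to a reference, which the
  learn inputs already presuppose — but estimating them from mismatch
  counts would fold real variants into the error rate).

## Synthetic data and what the benchmarks show

The fixture generator emits uniform-random references at a chosen GC
fraction and non-overlapping peak sets in two presets: TF-like (~200 bp
peaks, one per ~20 kb) and HM-like (~2 kb domains, one per ~40 kb).
There is no repeat structure, no mappability variation, no GC bias, no
chromatin-accessibility structure — the simulator never maps reads, so
none of these affect its own correctness, but passing benchmarks here
says nothing about aligner- or caller-induced artifacts on real
genomes.

Benchmark problem sizes were chosen as the smallest at which the
statistics under test are stable:

* **Enrichment ratio.** 10 Mb genome, 10 kb score-1.0 peaks, 200k
  selected fragments, no PCR, no errors. The read-start density ratio
  in peaks versus background matches α within 5% over
  (f, s) ∈ {0.01, 0.05} × {0.3, 0.5, 0.8}. Background excludes a
  1.5 kb flank around each peak: fragments that span a peak edge
  deposit read starts just outside it, and with a gamma(2, 100) length
  distribution the flank keeps the residual spill below 10⁻⁵ of reads.
  Inside a score-1 peak the density is exactly the bound inclusion
  rate (any read starting in a peak comes from a fragment overlapping
  it), so no interior correction is needed.
* **Parameter recovery.** 1 Mb genome, 5 kb score-1.0 peaks, 200k read
  pairs, grid f ∈ {0.01, 0.05}, s ∈ {0.2, 0.5, 0.8}, p ∈ {0.6, 0.9},
  gamma shapes 2 and 8 at mean 200 bp. Recovered s is within ±0.05,
  p within ±0.05, fragment mean within ±10%, f exact. Broad (5 kb)
  domains are used because the finite-fragment edge effects on FRIP
  scale as (fragment mean)/(peak width): bound fragments anchored just
  outside a peak depress measured s by roughly that factor, ~4% here
  versus ~50% if peaks were fragment-sized. The residual gamma-mean
  bias (+5% at shape 2) comes from discarding fragments shorter than
  the read length, which truncates the left tail.
* **Replicate reproducibility.** 1 Mb genome, 50 HM-like domains with
  uniform scores in [0.2, 1], s = 0.6, p = 0.9, 20k reads, 5 kb bins.
  Two independent-seed runs at 100 rounds correlate r ≥ 0.9 in peak
  bins, and the mean correlation over five seed pairs is non-decreasing
  across {1, 5, 25, 100} rounds. The four levels traverse distinct
  regimes — pool exhaustion, heavily capped, partially capped,
  uncapped pulldown — which is what makes the trend a property of the
  model rather than of sampling noise.
* **Error calibration.** 1M sequenced bases at substitution rate 0.01:
  the Hamming mismatch rate against the reference is within 3 binomial
  standard deviations, and the generator's own edit log agrees exactly
  with the external count.

Guidance carried into the CLI defaults: ~25–100 rounds suffice for
broad histone-modification targets while narrow TF targets need on the
order of 1000, because the bound pool per round is proportional to the
bound genome fraction.

## Numerical details and degenerate inputs

* Coordinates are 0-based half-open everywhere internally; SAM records
  are converted on read. All randomness flows from one user seed
  expanded into six independent per-stage streams (shear, bind,
  pulldown, PCR, strand, sequencing), so identical seeds give
  bit-identical outputs and a change in one stage's logic does not
  perturb the draws of another.
* The model file is strict JSON: unknown sections or keys are rejected
  (a typo like `"rate"` for `"scale"` fails loudly), every field is
  range-checked on read, and the gamma section records its own
  parameterization to prevent shape/rate confusion. α is never stored;
  it is always derived from (f, s).
* Degenerate cases: f or s at {0, 1} is a domain error (α undefined);
  p = 1 makes PCR the identity; an empty fragment pool, an empty peak
  list, an all-one-strand dataset, and a constant bin track are all
  errors with actionable messages rather than NaNs.
* Fragments with more than 50% N bases (configurable) are excluded
  before pulldown so assembly-gap-like regions cannot dominate the
  unmappable output.
* Chromosomes shorter than the read length are skipped with a warning.

## Known limitations

* No GC, accessibility, or cross-linking bias in pulldown; no
  locus-specific binding energies (peak scores are the only binding
  heterogeneity).
* No quality-score simulation, position-dependent error profiles, or
  adapter read-through.
* The single-end fragment-length heuristic degrades for broad peaks
  and heavy-tailed length distributions (see above).
* Peak calling, alignment and duplicate flagging are out of scope:
  peaks are always an input, and the idealized alignment-record
  converter assumes a perfect aligner.
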