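# Methods

`bequant` quantifies base-editing outcomes on paired sgRNA/target-site
libraries of the kind used to profile cytosine and adenine base editors at
scale: thousands of cassettes, each pairing a 20-nt spacer with a matching
target site carrying a substrate C or A at protospacer position 6 inside
variable sequence context, integrated into a cell line, edited, and sequenced
as paired-end reads. This note records the models, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Coordinate frame

All statistics use the protospacer frame: protospacer bases are positions
1–20, the PAM is 21–23, the base immediately upstream of the protospacer is
position 0, and upstream flank positions are negative. Mutation calls are
restricted to the window **−9..20** and to the four tracked substitution
classes (C→T, C→G, C→A, A→G); everything else — other substitutions, indels,
calls outside the window — is deliberately ignored, which suppresses both
clonal-expansion artifacts and sequencer read misassignment. Internally,
cassette slicing uses 0-based offsets; `LibraryMember` owns the conversion.

## Read processing

1. **Quality filter.** A read pair is discarded if any base inside the
   scored regions (the −9..20 window on the forward read, the 20-nt spacer
   on the reverse read) is below Q28. Bases outside those regions are
   unconstrained.
2. **Candidate nomination.** Members are indexed by non-overlapping 6-mer
   tiles across the 30-nt window (5 tiles, anchored at position −9). A read
   nominates every member sharing at least one tile-position-matched 6-mer,
   ranked by shared-tile count with member-id tie-breaks. Because tiles are
   disjoint, a single substitution corrupts at most one tile, so true members
   survive nomination with at least 4 of 5 tiles intact. The top 5 candidates
   proceed.
3. **Spacer match.** The sequenced spacer (reverse read) must equal a
   candidate's spacer exactly; reads whose spacer matches no candidate are
   counted as unassigned. Exact matching means a single spacer sequencing
   error (~2% of reads at Q30 error rates) unassigns the read; the per-run
   report makes this loss visible.
4. **Genotyping.** The forward read is globally aligned to each surviving
   candidate's cassette by Needleman–Wunsch with match +1, mismatch −1, gap
   open −5, gap extend 0, and free leading gaps on both sequences ("start
   gap = 0"); trailing gaps pay the opening penalty by default since the
   forward read is designed to cover the full window. The best-scoring
   candidate wins (score ties broken by member id); aligned columns in the
   window with a tracked substitution become calls. N scores as a mismatch
   (even against N) and never produces a call. Traceback tie-breaking is
   fixed (diagonal > up > left) so output is deterministic.

The implementation is a numba-compiled three-state (Gotoh) affine dynamic
program; tests verify it against exhaustive alignment enumeration and
against Biopython's `PairwiseAligner` in plain global mode.

Accounting is conserved by construction: kept + quality-discarded +
unassigned = total input reads, checked on every simulated run.

## Statistics

* **Batch screen.** For each (position, class), per-member frequencies are
  compared across batches (biological replicates by default) with one-way
  ANOVA; hypotheses with p below 0.005/m (m = testable hypotheses,
  family-wise α = 0.005) are flagged. Flags are reported, not removed, by
  default (a `drop_flagged` switch removes them); with two groups the F-test
  is equivalent to the two-sample t-test. Groups of identical values return
  p = 1 by convention; zero within-group variance with differing means
  returns p = 0.
* **Noise filter.** For each (member, position, class), with per-replicate
  counts kᵢ of nᵢ reads, the joint noise probability is
  ∏ᵢ P(Xᵢ ≥ kᵢ), Xᵢ ~ Binomial(nᵢ, 10⁻³) — 10⁻³ being the Q30 error rate.
  The mutation is kept iff this product is < 0.05. The tail-product is a
  deliberately conservative reading of "unlikely in both replicates": a
  mutation at k=1 of n=100 in one replicate alone is 9.5% likely under noise
  (rejected), but the same count in *both* replicates is 0.9% likely
  (kept), so reproducibly rare outcomes survive. Filtered mutations keep
  their denominators but have their numerators zeroed.
* **Pooling.** Replicate counts are summed before dividing: Σk/Σn, the
  maximum-likelihood Bernoulli rate, not the mean of per-replicate ratios.
  Zero pooled coverage is reported as missing, never as 0.
* **Profiles and window.** The per-position efficiency of a class is the
  unweighted mean over members carrying that substrate base at that position
  (only members with coverage contribute). The editing window is every
  position with C→T efficiency ≥ 30% of the peak position's efficiency; it
  is scale-invariant and reported as-is if non-contiguous.
* **Selectivity.** The geometric mean over window positions of the
  C→T : A→G efficiency ratio. Positions with zero or undefined A→G
  efficiency are excluded with a logged warning — the log-ratio is undefined
  there, and exclusion keeps the estimate conservative. This is a documented
  choice; the bound min ratio ≤ selectivity ≤ max ratio always holds.
* **Read-level statistics.** Average editing efficiency is the unweighted
  mean over members of the fraction of genotyped reads carrying ≥ 1 retained
  call of the class in the window; conditional co-editing is
  P(≥1 A→G call | ≥1 C→T call) over reads; the ABE:CBE ratio divides the
  two average efficiencies. All three are computed after the noise filter,
  so isolated sequencing errors rarely contribute.
* **Context motifs.** Member-level pooled efficiencies of one class at the
  designed target position (optionally pooled over window positions) are
  transformed with the stabilised logit log((x+ε)/((1−x)+ε)), ε = 0.001
  (natural log; the base only rescales weights). An 80:20 seeded split and a
  ridge regression (α = 10⁻⁵, unpenalised intercept) on one-hot context
  features at offsets −3..+3 (excluding the substrate itself) give weights
  reported after per-offset centering — removing the one-hot degeneracy —
  and a held-out Pearson R used as logo opacity (clipped at 0). Separate
  models are fitted per substrate base and outcome class. The denominator
  form (1−x)+ε is bitwise symmetric, so f(0.5) = 0 and f(1−x) = −f(x)
  exactly in floating point.
* **Editor comparison.** Paired member-level efficiencies of two editors are
  fitted by total least squares through the origin: the slope is the leading
  eigenvector direction of the 2×2 second-moment matrix, minimising squared
  orthogonal distances; the fold change is the reciprocal of the slope. TLS
  is used because both coordinates are measured with error — OLS would be
  attenuated toward zero, which the tests demonstrate by direct contrast.
  The origin constraint makes 1/β interpretable as a single fold change; an
  `intercept` flag provides the mean-centered (Deming) variant for
  sensitivity analysis, and a seeded percentile bootstrap over members gives
  optional confidence intervals.

## Synthetic-data generator

The generator is first-class, tested code: it emulates the integrated
context library so that every pipeline stage has an analytic or enumerable
ground truth.

* **Library.** Each member is a 94-nt cassette (protospacer start offset 29,
  NGG PAM, random flanks) with a substrate C or A at position 6. The first
  32 members enumerate all 16 (5′, 3′) dinucleotide contexts per substrate,
  guaranteeing full dinucleotide coverage at n ≥ 32; spacers are unique and
  generation is deterministic given the seed.
* **Editing model.** Additive on the log-odds scale: in reads where the
  editor engages at all (per-read Bernoulli, probability `engage_prob`),
  each substrate base at a position carrying a window weight converts with
  probability logistic(μ + window weight + Σ context weights over offsets
  −3..+3). C conversions become C→G / C→A with the byproduct fractions,
  else C→T; A conversions are A→G. The latent engagement couples edits on
  the same read — exactly the structure conditional co-editing measures —
  and `engage_prob = 1` reduces to independent sites. Additivity on the
  logit scale means the motif regression is correctly specified, making
  parameter recovery a meaningful test (note that any multiplicative factor
  such as sub-unity engagement or byproducts breaks exact logit-additivity,
  which is why the motif-recovery condition uses engagement 1 and no
  byproducts).
* **Reads.** Forward reads are the 94-nt cassette; reverse reads are 56 nt
  of a fixed-scaffold spacer cassette (never edited). Each base substitutes
  to one of the three other bases with probability 10⁻³ (Q30); qualities are
  Phred+33 at Q30 with an optional fraction demoted below Q28. Depth per
  member per replicate is Poisson(300), mimicking coverage dispersion
  without extra parameters. Read IDs encode the true member for testing
  only; the pipeline never reads them.
* **Ground truth.** `truth_statistics` applies the *same* formulas as the
  quantification stage to analytic expectations: per-position efficiency
  engage × mean over members of logistic(·), window by the 30% rule,
  selectivity as the geometric-mean ratio, read-level probabilities from
  the per-member products over sites.

### Benchmark presets (the study conditions)

* `cbe` — realistic narrow-window cytosine editor: window-weight core
  {3: 0, 4: 0.5, 5: 1.0, 6: 1.2, 7: 0.5, 8: 0} with a −3.5 log-odds
  bystander tail elsewhere in −9..20, TC-preferring context weights,
  byproducts 3% + 3%, engagement 0.45. Chosen to land average any-C→T
  efficiencies in the tens of percent with a 3–8 window centered on
  position 6, the regime these editors occupy.
* `benchmark` — parameter-recovery condition: same window core, zero
  context weights, engagement 1, and A-site weights constructed as
  logit(logistic(w_C)·f_T/25) so the truth window is exactly {3..8} and the
  truth selectivity exactly 25. Engagement 1 keeps per-position A→G counts
  (~5–6 per replicate at the window edges) far above the noise-filter
  boundary, so retention does not bias the selectivity estimate.
* `dual` — equal C and A window weights, engagement 0.6, 2% + 2%
  byproducts: a dual-editor condition whose latent engagement produces
  strong read-level co-editing.
* `null` — engagement 0: pure sequencing noise, used to characterise the
  noise filter's operating point.

## Problem sizes

The default verification scale is 200 members × 2 replicates ×
Poisson(300) reads (~120k read pairs per condition, processed in well under
a minute), 2,000 members for motif recovery, and 80 members for the
dual-editor statistics. These sizes make every recovery tolerance a
several-sigma margin while keeping a full run interactive.

## What passing tests do and do not show

The generator reproduces the structural features the statistics depend on —
coordinate frame, paired-read geometry, Q30 substitution noise, replicate
structure, coverage dispersion, latent co-editing, additive context effects —
and the pipeline provably recovers the generating parameters under them. It
does **not** model indels, PCR amplification bias, deaminase processivity
beyond the engagement latent, clonal expansion batch effects (batch labels
are emitted but exchangeable), or self-editing of the spacer cassette. On
real data those phenomena add error modes the synthetic benchmark cannot
certify; the per-run report (discarded/unassigned tallies, ANOVA flags,
selectivity exclusion warnings) is the instrument for noticing them.

## Numerical and degenerate-input conventions

* Alignment ties are broken deterministically; scores are exact floats of
  small integer sums, compared with a 10⁻⁹ tolerance in traceback.
* Binomial tails come from `scipy.stats.binom.sf`; k > n is an error.
* Zero-coverage efficiencies are missing, not zero; members with zero reads
  are excluded from member averages with a warning.
* Zero-variance motif targets yield all-zero weights and R = 0 with a
  warning; a degenerate (all-origin) TLS cloud is an explicit error.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; identical configuration and seed give
  byte-identical FASTQ output.
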