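# Methods

## 5′ profiles

A *5′ profile* maps every (reference, strand, position) to the number of
sequenced fragments whose 5′ end starts there. Three conventions fix the
counting:

- **Informative reads.** In a paired-end stranded library the read-2
  sequence begins at the fragment's 5′ end, so only read-2 records are
  counted, whether or not their mate aligned; in single-end libraries
  every record is informative. Multi-mapping (secondary/supplementary)
  records are always dropped; a mapping-quality cutoff can additionally
  be applied but is off by default, since the flag-based definition of
  uniqueness is aligner-dependent enough already.
- **5′ coordinate.** Forward-strand reads start at their leftmost
  aligned base, reverse-strand reads at their rightmost. The aligned
  span comes from the CIGAR (deletions/introns spanned), and
  soft-clipped bases are excluded: clipped bases are not supported by
  the genome and would shift the inferred cleavage position.
- **Coordinates.** 1-based inclusive per strand internally (SAM
  convention); the BEDGraph writer converts to 0-based half-open at the
  boundary. Profiles are strand-aware and the proportion statistic is
  computed per (strand, position), the natural reading for stranded
  libraries; `collapse_strands` provides the strand-summed alternative.

## Depth equalization

Raw libraries differ in depth, and the extreme classes of the statistic
below (positions with zero counts in one strain) are exquisitely
sensitive to depth. Instead of rate normalization, every library is
reduced to floor(0.9 × smallest library's unique-read count) records by
uniform sampling without replacement. Sizing happens after the
uniqueness filter and before the read-2 filter (a switch selects the
other order). Each library draws from its own RNG stream keyed by a
CRC32 hash of the library name under the pipeline seed, so adding or
reordering libraries never perturbs the sample drawn for the others.

## The proportion field and its histogram

After merging replicate profiles per strain (position-wise sum), every
position with at least one read start in either strain gets
P = mutant/(mutant + wt). The histogram keeps P = 0 and P = 1 as exact
singleton classes — safe under floating point because those values only
arise from a zero numerator or a zero complement — and splits the open
interval (0, 1) into 99 equal-width bins (percent resolution),
left-closed right-open with the last bin right-closed.

## The Bayesian Error Rate decision

The two extreme-class counts n0 and n1 are compared against the noise of
the histogram's interior, treated as background: σ is the sample
standard deviation (N−1 denominator, zero-count bins included) of the 99
interior bin counts. The counts are then modelled as two equal-prior
Gaussian classes with means n0 and n1 and common σ; the optimal
classifier errs with probability

    BER = Φ(−|n1 − n0| / (2σ)),

the misclassification mass beyond the midpoint between the class means.
BER < α (default 0.01, strict inequality) declares the excess
significant. Conventions at the edges: σ = 0 gives BER 0 for distinct
counts and 0.5 for equal counts; n0 = 0 makes the percent excess
100·(n1/n0 − 1) undefined and is reported as an infinite-excess flag
(the CLI exits with code 3). The interior-count SD is computed after
sorting the bin counts so that the result is bitwise invariant under bin
permutation; a strain swap (which reverses the bin order and exchanges
n0 with n1) then leaves σ and BER exactly unchanged.

Choosing the *interior bin counts* as the noise scale — rather than the
variance of the P values themselves — keeps the noise on the same scale
as the quantities being compared (counts of positions per class), which
is what a two-class decision on n0 vs n1 requires.

The per-position statistic makes no claim about *which* transcripts the
excess positions belong to; enrichment of a hit set against another
gene set is provided as an upper-tail hypergeometric test,
P(X ≥ overlap) with population = universe, successes = one set, draws =
the other.

## Synthetic data

The generator plants known structure so every stage is testable offline:

- **Sites.** `n_shared_sites` cleavage positions present in both strains
  and `n_exclusive_sites` mutant-only decay-intermediate positions are
  placed uniformly at random on distinct (strand, position) slots
  (exclusive sites are the tail of one permutation, hence disjoint from
  shared ones). `strand_fraction` (default 0.5) sets the forward-strand
  share.
- **Counts.** Each site draws an independent Poisson count per replicate
  — shared sites in both strains, exclusive sites in mutant replicates
  only. Poisson sampling alone then produces the background of
  strain-exclusive positions: a shared site lands in the P = 0 class
  with probability q(1 − q), q = exp(−R·λ_shared), R replicates.
- **Defaults as study conditions.** 4.0 Mb genome (the scale of a
  *Caulobacter crescentus* chromosome), 200 000 shared sites, λ = 0.3
  per site per replicate, 3 biological replicates per strain. This is
  the sparse-coverage regime in which most covered positions hold only a
  few reads and strain-exclusive positions are common — the regime in
  which the extreme classes of the P histogram carry the signal.
- **Calibration.** `FragmentationScenario.with_planted_excess(target)`
  solves the planted model in closed form for the number of exclusive
  sites that makes E[n1]/E[n0] − 1 equal the target:
  E = (target/100)·S·q(1−q)/(1−q_e). No empirical tuning is involved.
- **Alignments.** Each profile count expands into alignment records
  whose informative 5′ ends reproduce the profile exactly (bit equality
  round trip). In paired mode every fragment emits an informative R2
  plus a non-informative R1 mate (so half of the records must be removed
  by the read filter); in single mode every record is informative. SAM
  output carries minimal headers, flags and CIGARs only.
- **What it does not emulate.** Sequence content and base qualities,
  alignment and mapping errors, rRNA contamination, positional
  clustering of cleavage sites along transcripts, and count
  overdispersion beyond Poisson. Passing tests therefore demonstrate the
  statistical machinery and its calibration under the stated generative
  model, not robustness to artefacts of real libraries; on real data the
  depth-equalization and filtering steps address some (not all) of
  these.

A caveat the synthetic model makes visible: undersampling equalizes
*total* depth, so if planted mutant-only reads are a large fraction of
the mutant library, shared sites end up with asymmetric effective rates
and the background itself becomes asymmetric. Real decay intermediates
are a small fraction of a library; scenarios meant to mimic them should
keep the exclusive read mass small relative to the shared mass (the
stability fixtures in the test suite do).

## Decay kinetics

After rifampicin blocks transcription initiation, abundance follows
level(t) = level(0)·e^(−kt). The fit is ordinary least squares of
ln(level) on time with a free intercept (anchoring the intercept at the
observed t₀ point would give that noisy measurement infinite weight);
rate k = −slope, half-life = ln 2/k, with the fit's R² reported.
Non-positive levels carry no information on the log scale and are
dropped with a warning; fewer than three usable points is an error, not
a silent omission.

With sampling at 0/1/3/9 min, half-lives below 1 min decay away before
the second point and half-lives above 15 min barely move over the
window; estimates outside the (min_hl, max_hl) = (1, 15) min window —
both bounds configurable, comparisons strict — are flagged `too_fast` /
`too_stable` and the half-life is reported as not calculable rather than
as an unreliable number. Half-life is invariant to multiplicative
rescaling of a series, so RPKM, mRNA-fraction and 2^−ΔΔCt inputs are
interchangeable up to the intercept.

The synthetic decay generator draws level(t) = level₀·2^(−t/h)·e^ε with
ε ~ N(0, ln(1 + cv²)), the log-normal scale whose multiplicative
coefficient of variation is `noise_cv`. Error propagation fixes what
recovery rates are achievable: the slope's standard error is
σ_ε/√Sxx, so at cv = 0.1 and t = (0,1,3,9) the relative error of a 3 min
half-life estimate has SD ≈ 6 %, and roughly nine seeds in ten land
within 10 % of truth — a property of the design window, not of the
fitting code.

Supporting utilities follow their textbook definitions: RPKM
(reads/(length/10³)/(total/10⁶), totals either supplied or taken as
column sums), bulk mRNA fraction per time point, Welch's unequal-variance
two-sided t-test with Welch–Satterthwaite degrees of freedom (p = 1 by
convention when both groups are constant and equal), standard step-up
Benjamini–Hochberg adjustment, and 2^−ΔΔCt relative quantification
against an internal reference gene and the t₀ baseline. Per-gene
comparisons between strains test the decay *rates* across replicates, so
genes whose half-life is flagged not-calculable but whose rate is finite
still contribute.

## Problem sizes and numerical conventions

The acceptance checks run 100-seed calibrations at the default
genome-scale scenario (about a minute in total); record-level fixtures
(round trips, undersampling stability) use 10⁴–10⁵ reads per library,
large enough that the extreme-class counts are in the thousands and
resampling noise on the excess estimate is ~1–3 %. Determinism is
end-to-end: every generator and the undersampler are pure functions of
their seed, JSON output is written with sorted keys, and manifests
contain no timestamps, so identical configuration plus seed reproduces
every artifact byte-for-byte.

## Known limitations

- The Gaussian two-class reading of the decision problem fixes the
  numeric scale of BER; other plausible noise models for the extreme
  counts (e.g. Poisson) would give different absolute error rates,
  though the same ordering.
- The background σ mixes sampling noise with the systematic shape of the
  interior histogram; in spiky low-count regimes this inflates σ and
  makes the decision conservative.
- Strand-exclusive background levels depend on sequencing depth even
  after equalization; comparisons are only meaningful between the two
  depth-matched strains of one run, not across runs.
- Per-gene attribution of excess positions, spike-in normalization and
  transcription-onset corrections for the decay fits are out of scope.
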