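# Methods

## Scope and data model

`ribostat` tests two kinds of per-transcript hypotheses on sequencing count
tables:

1. **Differential translation efficiency.** Matched ribosome-footprint
   (RPF) and RNA-seq counts per transcript and sample; the question is
   whether the RPF:RNA ratio (translation efficiency, TE) differs across
   conditions.
2. **Differential poly(A)-site usage.** 3'-end read counts per annotated
   poly(A) site; the question is whether the distribution of reads over a
   transcript's sites shifts across conditions (3' UTR shortening or
   lengthening).

Both are framed as per-transcript regressions on read-type odds, so they
accommodate arbitrary designs — any number of groups, replicates,
continuous covariates, batch indicators — without distributional
assumptions on the counts themselves beyond the sampling model.

## The TER test

TE is modelled as the odds that a read drawn from a sample's pooled
RPF+RNA reads is an RPF read. Per transcript:

    logit P(read = RPF) = log(RPF/RNA) = α + Σᵢ βᵢ xᵢ

Each sample contributes its RPF count as binomial "successes" and RNA
count as "failures". The per-read Bernoulli likelihood and the per-sample
aggregated binomial likelihood are proportional, so the aggregated fit is
used. Counts enter as real-valued likelihood weights: normalized and
bias-corrected counts are fractional, and rounding them would introduce a
depth-dependent bias.

The TE ratio between two covariate settings x₁, x₂ is

    TER = TE₂/TE₁ = exp{ Σᵢ βᵢ (x_{i,2} − x_{i,1}) }

and logTER is the corresponding linear contrast. For two unreplicated
samples with one binary covariate, the fit is saturated and β equals the
2×2 log odds ratio exactly; `ter_2x2_oracle` exposes the chi-square and
Fisher versions of that degenerate case as a built-in cross-check.

Numerical details:

* own Newton solver with step-halving (`_logit.py`), tolerance 1e-10,
  iteration cap 100, ridge 1e-8 on the Hessian solve only;
* Wald p-values (two-sided normal on β/SE); |β| > 10 flags separation and
  the p-value for each coefficient is recomputed by a likelihood-ratio
  test, since the Wald statistic collapses under separation;
* transcripts with normalized RPF+RNA below `min_total` (default 10) in
  any sample are reported NA;
* `pseudocount="auto"` applies Haldane 0.5 only to transcripts with a
  zero cell, so positive tables keep exact oracle equivalence;
* optional quasi-binomial SE inflation (`dispersion=True`): Pearson
  χ²/df floored at 1, for data overdispersed relative to binomial;
* Benjamini–Hochberg FDR across testable transcripts.

### Empirical-null recalibration

When differential translation is predominantly one-directional, the
median-of-ratios size factors absorb part of the genuine group shift:
affected samples' factors are tilted by the changed transcripts, which
imparts a small common offset to every transcript's logTER. The TER test
is powerful (within-sample odds noise is close to multinomial sampling),
so at deep coverage this composition offset alone can push many null
transcripts past nominal thresholds.

`summary(..., empirical_null=True)` addresses this with the standard
empirical-null device: the contrast z-values are standardized by their
transcriptome-wide median and MAD (consistent for the null location/scale
when most transcripts are unchanged), p-values are recomputed from the
recalibrated z, and logTER is median-centered. It is off by default —
with balanced or sparse effects it is a near no-op — and exposed as
`--empirical-null` on the CLI. It assumes, as all such corrections do,
that the majority of transcripts are not differentially translated.

## Median-of-ratios normalization

Per matrix (RNA and RPF separately): the reference pseudo-sample is the
per-transcript geometric mean across samples, over transcripts with
strictly positive counts everywhere (the geometric mean is undefined at
zero; excluded transcripts are still normalized). Each sample's factor is
the median of its count/reference ratios, with the median taken in log
space — identical to the plain median at odd transcript counts, and the
geometric rather than arithmetic midpoint of the two central ratios at
even counts, matching the DESeq2 convention (verified against pydeseq2 to
1e-10 in the tests). Factors are invariant to a global rescaling of all
counts and to row permutation.

## CELP stalling-bias correction

Ribosome stalling piles RPF reads onto particular codons; those reads
mark locally obstructed elongation, not increased translation, and
inflate per-transcript RPF totals. The correction:

1. **Smoothing.** Each sample's codon-count profile is smoothed by a
   deterministic local linear regression: at codon i, a weighted line is
   fitted over codons within ±radius (default 5) with tricube weights
   w(d) = (1 − (|d|/(radius+1))³)³, and the prediction at i (clipped at
   0) is the smoothed count. Because the interior weights are symmetric,
   the centered prediction reduces to a fixed convolution kernel; edge
   positions use per-position least-squares kernels, and transcripts
   shorter than 2·radius+1 use every codon in every window. Smoothing is
   deliberate: stalling peaks reproduce in approximate, not exact,
   positions across replicates, obstructions span adjacent codons, and
   P-site assignment carries positional uncertainty.
2. **Background.** M = median of the sample's non-zero smoothed counts —
   the transcript's background translation level.
3. **Bias coefficient.** b_i = geometric mean over the sample pool of
   smoothed_i / M. The pool is all samples by default (appropriate when
   the goal is debiasing before the TER test); per-group pools are
   available when group-specific stalling is itself of interest. The same
   pool is used for the backgrounds and the ratios.
4. **Debiasing.** Corrected codon count = smoothed_i / b_i; corrected
   transcript count = Σᵢ. Values are real and feed the TER test without
   rounding.

Zero handling: codons where any pooled sample has zero smoothed count (or
a zero background) keep b = 1 — zeros carry no evidence of stalling, and
an epsilon floor would manufacture signal. Transcripts with all-zero
background are passed through unchanged and flagged. b is applied in both
directions (b < 1 inflates valleys), exactly as defined; `clip_at_one`
restricts correction to peaks for users who only want stalling removed.
b is invariant to per-sample depth by construction (each sample's ratio
is taken against its own background), so smoothing runs on raw counts.

## Poly(A)-site usage tests

Per transcript with S ≥ 2 annotated sites, site counts are modelled with
a baseline-category multinomial logit:

    log(site_m / site_ref) = α_m + Σᵢ β_{m,i} xᵢ ,  m ≠ ref

fitted by Newton iteration on the full multinomial log-likelihood with
real-valued counts (tolerance 1e-10, cap 100, reference category last).
The intercept-only null has the closed-form pooled-proportion MLE. Three
modes:

* **overall** — deviance 2(ℓ_full − ℓ_null) vs chi-square with
  (S−1)·p_cov df; exactly one test per transcript, sidestepping unequal
  site counts in the multiple-testing budget. For S = 2 and a saturated
  binary design this deviance is algebraically the G-statistic of the
  2×2 table (asserted in the tests).
* **vs_reference** — Wald tests per non-reference site; the reference is
  the alphabetically first site by default, with `proximal` and
  user-supplied alternatives.
* **pairwise** — a binomial logit per unordered site pair, ordered
  proximal-first; the highest-resolution view. Samples with zero total
  for a pair are dropped from that pair and counted in the output.

**logAPAR** is the condition coefficient of the pairwise fit between the
most proximal (rank 1) and most distal (rank S) site, with
log(proximal/distal) as the modelled odds: **logAPAR > 0 means
relatively more proximal usage at the higher covariate level; a
proximal-to-distal switch (3' UTR lengthening) is negative.** The sign
convention is fixed here because the defining phrase "proximal-to-distal
ratio" does not by itself pin the algebraic direction. An `adjacent`
option tests all rank-adjacent pairs instead; natural log is the default
with a log2 display option.

Proximal/distal ranks are transcript-relative and strand-aware: from a
BED6 of site positions, rank 1 is the smallest transcript-relative
coordinate (lowest start on +, highest end on − strands). Without a BED,
lexicographic site-id order is used with a warning.

Site×sample matrices are median-of-ratios normalized before fitting;
within-transcript proportions are scale-invariant, so this only matters
for pooled summaries. BH correction is applied within each mode across
test rows.

## Binned enrichment

Transcripts ranked by a statistic (logTER, logAPAR) are split into
`nbins` equally populated bins (default 10; contiguous rank blocks with
sizes differing by ≤1, stable id order breaking ties). Per bin, a target
set is tested for over/under-representation:

* hypergeometric: both one-sided tails; the smaller is reported with its
  direction (none when the count equals its expectation);
* logistic: membership regressed on the bin indicator, Wald p, with a
  likelihood-ratio fallback when a pure bin separates perfectly.

The global association is the plug-in mutual information (base 2)
between bin index and membership, standardized against `n_perm`
label permutations (default 1,000, seeded): z = (MI_obs − mean)/sd. The
plain empirical MI estimator is used, with no pseudocounts. A two-sided
Wilcoxon rank-sum (`rank_association`) compares an annotated subset's
statistic against background — exact for small tie-free groups,
normal approximation with tie correction otherwise.

## Synthetic data

The generator emulates the structure the tests assume, with truth tables
for every planted effect.

**Paired RPF/RNA.** Baseline expression is log-normal (median 200 reads,
sd_log 0.7); per-(transcript, sample) abundance is gamma with dispersion
φ = 0.1 (variance μ + φμ²); both assays are Poisson reads of that
*shared* abundance, scaled by per-sample depths (log-normal, sd 0.2) and,
for RPF, by the transcript's TE odds (log-normal, sd 0.3) times
exp(logTER) in the second group. Sharing the latent abundance between the
two assays reflects paired library preparation from one biological
sample: marginally each matrix is negative binomial, while the
within-sample RPF:RNA odds carries only sampling noise — the regime the
binomial TER model describes. Defaults: 2,000 transcripts, 150 codons,
3 vs 3 samples, 10% of transcripts at logTER = ln 2. Stalling is planted
as ×10 multiplicative peaks at 5 random codons; codon profiles are
multinomial splits of each transcript's RPF total (totals inflated by
(L + (fold−1)m)/L), so matrix and profile views agree by construction.

**Poly(A) sites.** 2–4 sites per transcript, baseline usage from a
symmetric Dirichlet(2), 500 reads per site per sample, 3 samples per
condition; 10% of transcripts get +1.0 added to the proximal site's
log-odds in condition 2.

What the generator does **not** emulate: positional read biases other
than multiplicative stalling peaks, shared dispersion trends across
transcripts, correlated effects between neighbouring transcripts, isoform
mixtures, and real annotation ambiguity. Passing tests therefore
demonstrate correctness of the estimators and calibration under the
assumed sampling model, not robustness to every artifact of real
libraries. If real RPF/RNA replicate variability exceeds the paired
sampling model (extra-binomial TE noise), the plain test is
anti-conservative; the `dispersion` flag is the lever for that regime.

## Problem sizes and tolerances

The validation suite uses the sizes its claims are stated at: 200 random
2×2 tables (β vs log-odds-ratio to 1e-6), 2,000 transcripts for TER
calibration (rejection within [0.03, 0.07] at α = 0.05) and recovery
(mean planted-effect estimate within ±0.1 of ln 2; empirical FDR ≤ 0.15
at BH 0.1, with empirical-null recalibration — see above), 200
spiked/twin profile pairs for stalling-bias reduction, 1,000 transcripts
for usage-test calibration and recovery (δ = 1.0 within ±0.15), and the
exact 100-transcript enrichment example (top-bin p = 1/C(100,10),
MI = 0.468996 bits, permutation z > 5). Wald-vs-chi-square p agreement
(within a factor of 2) is checked on tables with null-to-moderate
effects, where both asymptotic approximations are valid; in the far tail
the two reference distributions diverge from each other by construction.

## Known limitations

* The TER test inherits binomial sampling assumptions within samples;
  biological TE variability across replicates beyond that requires the
  quasi-binomial flag (or more replicates).
* Empirical-null recalibration assumes most transcripts are null; with
  transcriptome-scale shifts it will absorb real signal.
* CELP corrects multiplicative, locally smooth occupancy artifacts; it
  cannot distinguish a genuine uniform elevation of elongation time from
  higher initiation.
* One representative isoform per transcript id is assumed throughout; no
  isoform deconvolution.
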