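# Methods

## The measurement model

The SSS test quantifies auditory-motor synchronization as the phase
stability between the slow amplitude modulations of a heard syllable
stream and of the participant's own whispered productions. The chain
is:

1. **Pre-filter.** Both recordings are low-passed at 3 kHz
   (4th-order Butterworth, forward–backward so the filter is zero
   phase) to suppress background noise. Zero-phase filtering matters
   throughout: any group delay would shift one envelope against the
   other and bias the phase difference directly.
2. **Envelope.** The amplitude envelope is the modulus of the
   analytic signal (Hilbert transform) at the native rate.
3. **Resample and band-pass.** Envelopes are resampled to 100 Hz
   (polyphase, anti-aliased, output length `round(duration × 100)`)
   and band-passed 3.5–5.5 Hz (2nd-order Butterworth, zero phase).
   The band brackets the stimulus rates (4.3–4.7 Hz) so the phase
   tracks syllable-level rhythm.
4. **Phase and PLV.** Instantaneous phases come from a second Hilbert
   transform. The phase-locking value over a window of T samples is
   `|mean(exp(i(θ₁−θ₂)))|`, computed in 5 s windows with 2 s overlap
   (hop 3 s, read as adjacent windows *sharing* 2 s). Only complete
   windows enter the average — a partial trailing window would weight
   its samples differently — and no samples are trimmed at the edges;
   window coverage of the full signal is the protocol reading, and
   edge effects of the Hilbert transform are far smaller than
   between-participant differences.

For a 60 s run this yields 19 windows. The PLV of two independent
band-limited envelopes does not fall to 0: for T independent uniform
phase differences E[PLV] = (√π/2)/√T, and band-pass filtering
correlates neighbouring samples, which raises the effective floor to
roughly 0.1–0.3. "No synchronization" therefore means PLV near that
floor, not near zero.

**Spectral profile.** The rhythm-stability comparison between groups
uses the DFT of the *unfiltered* envelope (no windowing), restricted
to 1–10 Hz and normalized to sum to 1. It must precede the
3.5–5.5 Hz band-pass, since after it there is no out-of-band power
left to compare against.

## Mixture classification

Cohort PLVs are fitted with 1-D Gaussian mixtures (k = 1, 2, 3) by EM
with per-component variances, at most 140 iterations. Model choice
is by AIC = 2p − 2 ln L with p = 3k − 1 free parameters; raw AIC on
these likelihoods reproduces the negative AIC magnitudes reported for
real cohorts at n ≈ 60. Non-converged candidates leave the
comparison, which is how a three-component fit on strongly two-lobed
data typically drops out.

Numerical choices, all of which were genuinely open:

* **Initialization** is deterministic: component means at the k
  evenly spaced sample quantiles, equal weights, pooled variance.
  This removes label-switching and restart flakiness on 1-D data;
  seeded random multi-start (`n_init > 1`) exists for hard cases.
* **Convergence** means the relative log-likelihood change fell below
  1e-6 before the iteration cap.
* **Variance floor** 1e-10 (squared PLV). A component at the floor
  has collapsed onto a (numerically) single point and flags the fit
  as non-converged. The floor is deliberately far below any real
  between-participant spread: simulated tightly coupled participants
  can legitimately cluster with SD of a few 1e-4, which must count as
  a valid component, while truly degenerate (identical-value) input
  still collapses.
* **Labels**: posterior responsibility, higher-mean component =
  "high"; exact posterior ties (measure zero) break toward "low".
  The reported `boundary_plv` is the posterior crossing between the
  component means when it exists.

## Cohort statistics

* **One-sample KS**: raw values against a standard normal *without*
  standardizing. For PLVs confined to [0, 1] the statistic is
  dominated by the gap below the smallest observation, giving the
  D ≈ 0.6 scale reported for real cohorts — it acts as a bounded
  effect-size measure of non-normality, which is how the protocol
  family uses it. A fit-then-test (Lilliefors-style) variant sits
  behind `standardize=True`; its asymptotic p is anti-conservative
  and is flagged in the result.
* **Monte-Carlo CIs** (`mc_confidence_interval`) are percentile
  intervals of a seeded null simulation; the KS helpers attach a
  binomial CI on the Monte-Carlo exceedance probability of D.
* **Mann–Whitney U**: exact two-sided p by enumerating all
  assignments of the pooled values when n₁+n₂ ≤ 16 (handles ties by
  construction), normal approximation with tie and continuity
  correction above. Effect size is the rank-biserial correlation
  r = 1 − 2U/(n₁n₂) with U the first sample's statistic.
* **Fisher exact**: two-sided p by hypergeometric tail summation
  (scipy); effect size is the sample cross-product odds ratio with
  the Woolf log-normal CI `exp(ln OR ± 1.96 √Σ1/count)`. The
  conditional-MLE odds ratio is reported alongside, because the two
  estimators differ on unbalanced tables and published values do not
  always say which was used. Zero cells yield a degenerate OR with a
  warning, no continuity correction.
* **Spearman**: average ranks for ties; CI by Fisher z with
  1.96/√(n−3).
* **Bayes factor**: JZS BF01 via adaptive quadrature (tolerance 1e-5)
  of the marginal likelihood under a Cauchy(0, √2/2) prior on the
  standardized effect, using the Welch (unequal-variance) t statistic
  and degrees of freedom. Posterior mean and credible interval of
  the effect come from a dense grid around the sample effect; above
  df ≈ 150 the noncentral-t density is replaced by its normal limit,
  which is accurate there and avoids numerical overflow.

No multiple-testing correction is applied anywhere, matching the
protocol's reporting.

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes, not the
sound of speech:

* **Stimulus**: one raised-cosine burst (default width 0.11 s ≈ one
  "ta") per syllable, `floor(plateau_s × rate)` syllables per
  constant-rate plateau, no gaps. Only envelope periodicity matters
  to the PLV chain, so no diphone or formant synthesis is attempted.
  `plateau_s` defaults to 12 s (five plateaus fill the 1-min
  stimulus exactly); the literal 10 s-per-step reading (50 s total)
  is a supported preset, as the two readings cannot be reconciled
  from the protocol description alone.
* **Coupled producers** place a burst at each stimulus syllable plus
  a von Mises phase jitter with concentration κ — the canonical
  circular noise with a single knob mapping monotonically to PLV
  (κ = 0 uniform jitter, κ → ∞ perfect locking).
* **Self-paced producers** (idealized low synchronizers) tick at an
  intrinsic rate, default 3.5 Hz, with a mean-reverting (AR(1),
  coefficient 0.5 per burst) tempo drift of stationary SD 0.3 Hz.
* **Motor noise**: every burst in both modes receives Gaussian timing
  jitter (SD 5 ms). Human productions are not metronomic; without
  any production noise all self-paced simulants would be
  bit-identical in phase and collapse any mixture fit.
* **Cohorts**: PLVs from a two-component Gaussian mixture truncated
  to [0, 1] by rejection sampling (clipping would pile mass on the
  bounds), defaults at the observed component parameters
  (weights 0.62/0.38, means 0.48/0.77, SDs 0.106/0.045); sex with
  group-dependent male probability, age with group-dependent spread,
  years of education, and musical training tied to PLV through a
  Gaussian copula (`music_plv_rho`, default 0.2) with an ordinal
  expertise level derived from it.

**Calibration of the drift model.** The self-paced parameters were
set so the generator reproduces the two qualitative phenomena the
analysis is built to detect, and then frozen. First, group spectra:
with zero drift a fixed-rate burst train has a *sharper* line
spectrum than the accelerating coupled producers, inverting the real
contrast (high synchronizers show the clearer syllabic-rate peak
because their rhythm is stable while lows drift); drift of ~0.3 Hz
restores the realistic ordering. Second, bimodality: the intrinsic
rate sits below the stimulus band because a rate close to the
stimulus lets drift excursions produce spells of partial locking,
skewing the low-PLV cluster until an information criterion sometimes
prefers a third tail component. With the frozen defaults, AIC
selects two components on ≈94% of simulated 60-participant cohorts
(30 coupled κ=16, 30 self-paced), with label agreement 100% whenever
it does; the residual preference for a third component on a few
draws is a small-sample property of AIC on the skewed PLV noise
floor, and is reported honestly where it occurs.

**What the generator does not emulate** — and hence what passing
tests do not show about real data: real phonetic variability
(12 distinct syllables, diphone acoustics), whispered-speech noise
spectra, attention lapses and partial compliance, real low
synchronizers' intermittent *attempts* to synchronize (their PLVs
center near 0.48, well above the chance floor of the idealized
self-paced model), and any neural or behavioral correlates of group
membership. Conclusions about the analysis code transfer to real
data; conclusions about effect sizes do not.

## Quality control

Silence detection operationalizes the exclusion rule "silent for
longer than 4 s" (strictly greater): the rectified signal is smoothed
with a 50 ms moving average, samples below 5% of the 95th-percentile
amplitude count as silent, and the longest run is compared against
the threshold. The threshold is relative, so the verdict is
invariant to global gain. The other exclusion grounds used with real
recordings (voiced instead of whispered speech, heavy background
noise) are experimenter judgments; they are carried as manual flags
plus a reported RMS level, not decided automatically.

## Pipeline sizes and determinism

Synthetic end-to-end runs use 60 participants × 60 s envelopes at
100 Hz, which keeps a full pipeline execution (QC, PLV, mixture,
statistics, artifact writing) under a few seconds; WAV-based runs at
8–16 kHz scale linearly in sample rate. All stochastic stages
(generator, EM multi-start, Monte-Carlo CIs) take explicit seeds, and
identical configurations produce byte-identical CSV outputs.

## Known limitations

* The exact quantity bracketed by the published Monte-Carlo
  confidence intervals is not stated in the protocol family; the
  package brackets the Monte-Carlo p-estimate by default and exposes
  the statistic-percentile interval as the general-purpose tool.
* The "normalized" variant of AIC mentioned in protocol descriptions
  is undefined there; raw AIC reproduces the published model ordering
  and is used.
* Published odds ratios are not always the sample cross-product
  ratio; both estimators are computed, only the sample OR carries
  the CI.
* `extract_phase` on a numerically zero envelope returns arbitrary
  phase; PLV on such input is meaningless, and the QC stage is the
  intended guard.
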