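# speechsync

Analysis pipeline for the **Speech-to-Speech Synchronization (SSS)
test**: a short behavioral protocol in which a participant whispers
the syllable "ta" along with a heard syllable stream whose rate
accelerates from 4.3 to 4.7 syllables/s. The stability of the phase
relation between heard and produced speech separates people into
**high** and **low auditory-motor synchronizers** — a bimodal, not
normal, population distribution. The package is for researchers who
run the SSS test (or study auditory-motor coupling more generally) and
want the complete measurement and statistics chain as tested,
reusable Python.

## What it computes

**Synchrony.** For each participant the amplitude envelope of the
audio is taken as the modulus of the analytic (Hilbert) signal,
resampled to 100 Hz and band-passed 3.5–5.5 Hz (zero phase); the
instantaneous phases θ₁(t) of the heard and θ₂(t) of the produced
envelope give the phase-locking value over each analysis window of T
samples,

    PLV = (1/T) | Σₜ exp(i (θ₁(t) − θ₂(t))) |,

computed in 5 s windows with 2 s overlap and averaged — one PLV per
participant, 1 = perfect locking, ≈0 = none.

**Classification.** One-dimensional Gaussian mixtures with k = 1, 2, 3
components are fitted to the cohort's PLVs by EM (implemented
in-repo, at most 140 iterations); the Akaike Information Criterion,
AIC = 2(3k−1) − 2 ln L, selects k, and with k = 2 each participant is
assigned to the component with the larger posterior responsibility
(higher-mean component = high synchronizer).

**Cohort statistics.** One- and two-sample Kolmogorov–Smirnov tests,
Mann–Whitney U with rank-biserial effect sizes (exact by enumeration
at small n), Fisher's exact test with the sample odds ratio and Woolf
CI, Spearman correlation, Monte-Carlo confidence intervals, and the
JZS (Cauchy-prior) Bayes factor for the two-cohort comparison.

**Synthetic data.** A first-class generator produces the accelerating
stimulus envelope, simulated productions with controlled phase
coupling (von Mises jitter, concentration κ) or self-paced drifting
tempo, and simulated cohorts (PLV mixture + covariates), so the whole
pipeline is testable without recordings.

## Worked example

```python
import speechsync as ss

spec = ss.StimulusSpec()                       # 4.3→4.7 Hz, 12 s plateaus, 60 s
stim = ss.generate_stimulus_envelope(spec)
stim_banded = ss.resample_and_band(stim)       # 100 Hz, 3.5–5.5 Hz

prod = ss.simulate_production(
    stim, ss.SyntheticParticipantSpec(coupling_kappa=16.0, seed=1),
    stim_spec=spec)
res = ss.compute_plv(ss.phase_pair(stim_banded, ss.resample_and_band(prod)))
print(res.plv_mean, res.n_windows)
```

prints `0.987 19` — a tightly coupled producer holds a near-perfect
phase relation across all 19 windows of the 60 s run, while a
self-paced producer at 3.5 Hz comes out at `0.134` (the chance floor
for band-limited envelopes). Classifying a simulated 61-participant
cohort (`examples/02_mixture_classification.py`) prints

```
AIC selects k = 2 components
high synchronizers: n = 24, component mean = 0.77, weight = 0.38
low  synchronizers: n = 37, component mean = 0.47, weight = 0.62
```

— the bimodal structure the test is known for. The `examples/`
directory has one short script per capability; `speechsync --help`
exposes the same stages as a command-line pipeline (`simulate`, `qc`,
`plv`, `classify`, `stats`, `run`, `replicate`).

## Documentation

`docs/methods.md` describes the measurement model, the synthetic-data
generator and its calibration, numerical choices and known
limitations.
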