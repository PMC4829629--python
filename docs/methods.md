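# Methods

## Model and assumptions

Let `Y_ik` be the voltage of channel `i = 1..C` in trial `k = 1..K` at
one sample, after average referencing.  The bias analysis assumes

1. `E(Y_ik) = μ_i` — each channel has its own mean (the stimulus-locked
   signal),
2. `Var(Y_ik) = σ_i²` — each channel has its own noise variance,
3. `Cov(Y_ik, Y_im) = 0` — trials are independent (non-phase-locked
   activity does not carry over between epochs),
4. `Cov(Y_ik, Y_jk) = ρ_ij` — channels within a trial are correlated
   (volume conduction), identically across trials.  `ρ_ij` denotes a
   covariance here even though the symbol conventionally denotes a
   correlation.

GFP of the K-trial average ERP is the population (divide-by-`C`)
spatial standard deviation, never the `C−1` variant.  Its delta-method
expectation is

```
E(GFP) = sqrt( (1/C) Σ_i (σ_i²/K + μ_i²)
               − ( Σ_i 2 μ_i² σ_i² + (1/K) Σ_{i>j} μ_i μ_j ρ_ij )
                 / ( K (C−1) sqrt( [ (1/(C−1)) Σ_i (σ_i²/K + μ_i²) ]³ ) ) )
```

The correction term is small in the regimes this package targets and
hard to isolate empirically, so Monte-Carlo validation gates only on
the leading term `sqrt((1/C) Σ_i (σ_i²/K + μ_i²))`
against Monte-Carlo simulation (5% tolerance at `C ≥ 32`, `K ≥ 10`);
the correction term vanishes in the zero-mean and `K → ∞` cases that
the unit tests pin down.  Monte-Carlo validation uses zero-spatial-mean
`μ` patterns and average-referenced noise so that the spatial-mean
subtraction inside GFP matches the moment bookkeeping; a negative outer
radicand raises an error carrying the radicand rather than silently
clipping.  Because the leading term decays like `1/K`, `E(GFP)` is
strictly decreasing in the trial count for zero-mean data — the bias
that invalidates naive unbalanced comparisons.

## The tests

**Unbalanced paired permutation test.**  For each of `n_resamples`
(default 2000, observed labelling included as one entry): shuffle each
subject's trial labels uniformly while preserving that subject's A and
B counts, average the relabelled trials into condition ERPs, take GFP
traces, form `dGFP = GFP(A′) − GFP(B′)` and average over subjects.  One
shared shuffle per resample covers all timepoints, which is what makes
the maximum-statistic and cluster corrections coherent.  The two-tailed
p-value at each timepoint is `2·min(#≤, #≥)/n`, capped at 1, with the
observed statistic a member of the null — so p is always a multiple of
`2/n` and never 0.  The default sign convention is `A − B`
(configurable; the direction is a pure reporting convention and leaves
two-tailed p-values unchanged).

**Comparators.**  The conventional paired permutation test sign-flips
per-subject condition-GFP differences (all `2^N` flips enumerated when
`2^N ≤ n_resamples`, random flips with the observed pattern included
otherwise).  The paired-samples T test uses the `ddof=1` variance of
the per-subject differences, `df = N − 1`, two-tailed.  Zero-variance
timepoints follow an explicit convention (zero mean → t = 0, p = 1;
nonzero mean → p = 0, flagged) instead of propagating NaN.

**Corrections.**  FDR uses the statsmodels step-up implementations (BH
default, BY optional).  The maximum-statistic correction takes per-row
maxima of |dGFP|; a timepoint is rejected when the share of row maxima
at least as large as its |observed dGFP| is ≤ α (the counting form of
the (1−α)-quantile rule; on symmetric nulls it reduces to the
uncorrected two-tailed decision when only one timepoint is tested).
The cluster-size correction forms maximal runs of consecutive
timepoints with uncorrected p < .05 (inclusion criterion); the null
run-length distribution treats each null row in turn as the observed
statistic against the full null, so every row is scored exactly as the
observed row is and the null is internally consistent.  Cluster p is the share of null maxima at least as long.

**Seeding.**  A single master seed spawns independent per-subject
streams (`numpy.random.SeedSequence`), so results are bit-reproducible
and independent of iteration order.  Identical seeds give bit-identical
results objects and output files.

## Synthetic data

The generator draws i.i.d. trials of zero-mean Gaussian noise with a
configurable C×C channel covariance — exactly assumptions (1)–(4), with
`μ = 0` so the null of no condition difference is true by construction.
Defaults mirror a typical mid-density recording: 64 channels, 256 Hz, 178 trials per subject, 13 subjects,
equicorrelated covariance with per-channel SD 12 µV and inter-channel
correlation ρ = 0.2.  The 12 µV default places the shipped effect sweep
(1.17–3.59 µV RMS) at SNR ≈ 0.10–0.30, the regime the sensitivity
analysis is designed to span.  Optional variance-preserving Gaussian
temporal smoothing (cutoff in Hz) makes timepoints correlated — raw
white noise in time renders time-series corrections trivial — and
`trial_sd_scale` adds uniform multiplicative between-subject noise
scaling.

Condition effects are an additive offset, positive on the first half of
the channels and negative on the second half, at spatial RMS amplitude
`a` (so the pattern's GFP equals `a`), applied inside a configurable
time window (default: the whole epoch).  Labels are assigned by
`split_labels`: `round(ratio·K)` trials A (nearest integer, ties to
even, minimum 1), positions uniform at random.  SNR is the RMS of the
effect over its window divided by the RMS residual of the epochs about
their per-subject trial mean.

What the generator does *not* emulate: real ERP waveforms, heavy-tailed
or artifact-contaminated noise, non-stationarity within epochs, and
between-channel variance heterogeneity.  The validity and power
properties verified here depend only on within-subject trial
exchangeability and the moment structure above, but passing tests on
this generator do not certify behaviour under, e.g., heavy-tailed
noise.

## Experiment harnesses

**Validity.**  A fixed multi-subject null dataset is generated once
(mirroring a real recording re-split many times); each repetition draws
fresh labels per subject at the requested imbalance ratio and runs the
selected tests.  The false positive rate is pooled over timepoints and
repetitions; rejections at distinct timepoints are nearly independent
because the generator's noise is independent across samples, so the
pooled rate carries close to the nominal binomial precision.  Reports carry t-based 95% CIs over per-repetition
FPRs and a two-tailed one-sample t test against the nominal α.
Repetitions default to 100 and are an ordinary configuration value.

**Sensitivity.**  Condition A is fixed at 30 trials; Condition B is
sized to realise each ratio in {1/2, 1/3, 1/4, 1/5}; the offset effect
is injected into the A trials at each amplitude of the sweep
{1.17, …, 3.59} µV RMS.  TPR is the rejection proportion pooled over
the effect-window timepoints and repetitions — the same pooling as the
validity FPR, so TPR falls back to α at zero effect; rejections outside
the window are not counted.  Each ratio's power curve is summarised by
a two-parameter binomial-MLE logistic in SNR; `snr_at_half =
−intercept/slope`, flagged when extrapolated beyond the swept range or
non-identifiable (complete separation / degenerate curves — returned as
a flag, never a crash).

## Problem sizes

The shipped statistical checks run at a reduced scale chosen for a
desktop machine: 8 channels, 16 timepoints, 13 subjects, 178 trials
per subject, 100 repetitions × 2000 resamplings for validity;
`scripts/acceptance.py` uses 128 timepoints × 150 repetitions so each
pooled rate carries a binomial SE near 0.001.  The power check uses
50 repetitions × 1000 resamplings with noise SD calibrated to 20 µV so
that the effect sweep straddles the detection transition in the
reduced 30+30-trial configuration.  All quantities scale to the full
64-channel geometry unchanged; channel count affects only the
per-subject GFP noise floor, not the validity of the permutation
scheme.

## Known limitations

- The `E(GFP)` correction term is reproduced as printed but not
  independently validated; only the leading term is Monte-Carlo-gated.
- Only two conditions and the GFP-difference statistic are supported;
  one-tailed variants and other summary statistics (global
  dissimilarity, GFP of the difference ERP) are out of scope.
- No channel-space corrections (electrode adjacency, cluster t-mass);
  corrections operate on the timepoint axis only.
- Inputs must be pre-epoched and artifact-free; no filtering, ICA or
  epoching is provided.  HDF5 is the only on-disk format (an adapter
  for acquisition formats is a documented extension point, not
  implemented).
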