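# Methods

## Signal model

The analysis rests on the dichotomous fGn/fBm model of scale-free
signals. Fractional Gaussian noise (fGn) with Hurst exponent H ∈ (0, 1)
is the stationary process with autocovariance

    γ(k) = σ²/2 ( |k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H} ),

and power spectrum S(f) ∝ |f|^{−β} with β = 2H − 1 at low frequencies.
Fractional Brownian motion (fBm) is its cumulative sum, nonstationary,
with β = 2H + 1. A measured signal must be assigned to one class before
its estimated exponent can be interpreted; regional BOLD series at
TR = 2 s typically fall in the fGn regime with H near but below 1, so the
deviation 1 − H_fGn is the quantity carried into group analyses.

## Synthetic data

`synthetic_data` generates every input with known ground truth.

* **fGn** is simulated *exactly* by circulant embedding (Davies–Harte):
  the 2n-point circulant extension of the Toeplitz covariance is
  diagonalised by FFT and a Gaussian vector is coloured by the square
  root of its eigenvalues. The embedding's eigenvalues are checked, and
  a dense Cholesky factorisation is used if any were negative (for fGn
  they are not, but the guard is in place and the route can be forced).
  Exactness matters here: spectral approximations carry O(1/N) covariance
  errors that would bias Hurst recovery at N = 425, the series length
  this package targets. The generator is validated by comparing the full
  sample covariance at small n against γ(k) entrywise.
* **fBm** is the cumulative sum of the fGn drawn from the same spec, so
  differencing recovers the generating noise bit-for-bit.
* **Confounds** are random-phase sinusoids, one per physiological band
  (respiratory 0.1–0.5 Hz, cardiac 0.6–1.2 Hz), with amplitude defaulting
  to 0. Only the band limits are conventionally known, so a sinusoid is
  the minimal model. An active band must lie below the Nyquist frequency;
  at TR = 2 s (Nyquist 0.25 Hz) both bands alias and are therefore only
  usable on faster-sampled fixtures.
* **4D fixtures** embed a known signal in a sphere of voxels plus
  independent Gaussian noise, with a diagonal voxel-to-mm affine.
* **Cohorts** draw per-group deviation scores from Normal(mean, sd) and
  covariates jointly bivariate-normal with a planted per-group
  correlation. Defaults mirror the target study design: 38 high- vs 65
  low-impulsivity subjects and planted correlations 0.36 / −0.03 for the
  connectivity covariate. Default deviation means (0.10/0.05 at SD 0.12)
  sit on the 1 − 0.93 ≈ 0.07 scale of regional BOLD cohorts.

What the generator does *not* emulate: hemodynamic convolution, task
structure, spatial autocorrelation of noise, motion, or multi-subject
registration. Passing tests therefore demonstrate correctness of the
estimators and statistics under the stated statistical model, not
robustness to every artifact of real acquisitions.

## ROI extraction

Voxel membership is center-in-sphere with a closed boundary (ties at
exactly the radius are included), evaluated through the image affine; no
resampling, no brain mask. Aggregation is the arithmetic mean. Linear
detrending is least-squares by default — the residual has exactly zero
mean and zero slope — with an endpoints mode (line through first and last
sample) available for compatibility with that convention. Least-squares
is the default because it is the actual behaviour of the detrending
routines commonly cited for this step, and the spectral and fractal
estimators assume the mean and drift are gone.

## Spectral screen

Raw periodogram at the Fourier frequencies k/(N·Δt), zero frequency
excluded, normalised so in-band powers sum to the series variance
(Parseval). β is the negative OLS slope of log power on log frequency
inside the fit band, by default from the lowest Fourier frequency up to
0.1 Hz — the power-law approximation improves toward f → 0 and the
neurally driven BOLD content sits below 0.1 Hz. The band is configurable
and a Welch-averaged estimator is available for variance reduction.
Zero-power bins are dropped from the fit with a warning. The
scale-invariance gate passes iff −1 < β < 3 (strict); signals outside it
are refused by the classifier rather than mislabelled.

## AFA

The estimator integrates the (mean-removed) signal into its random-walk
profile, as DFA does; this makes the fluctuation exponent equal H for fGn
input and H + 1 for fBm input. The profile is covered by windows of odd
length w = 2n + 1 stepping by n points; an order-2 polynomial is fitted
in each window and consecutive fits are blended over their n + 1 shared
samples with weights (1 − l/n, l/n), yielding one globally continuous
trend — the feature that distinguishes AFA from per-box detrending. When
the last regular window does not reach the end of the series, an extra
window is anchored to end exactly at sample N and blended over the
(larger) overlap, so every sample has a trend value. H is the OLS slope
of log₂F(w) against log₂w over the window grid.

Defaults: n = 5..13 (w = 11..27), order 2 — a grid suited to series of a
few hundred samples. Monte-Carlo calibration at N = 425 shows ensemble
bias below 0.01 and per-realization SD ≈ 0.09 for H ∈ [0.7, 0.9]; the
acceptance suite re-derives this. At these small windows the walk regime
(exponents above 1) shows a downward small-scale crossover; analyses of
walk-like signals should widen the window grid with the series length.
Exactly constant input yields an all-zero fluctuation function, which
`fit_hurst` reports as a degenerate-input error rather than NaN.

## DFA

Classical per-box DFA (cumulative-sum profile, non-overlapping boxes,
per-box polynomial detrend of order 1 by default, RMS fluctuation,
log-log OLS). Default box sizes are 12 log-spaced values from 10 to N/8:
boxes under ~10 samples carry the documented small-box polynomial-fit
bias, and above N/8 too few boxes enter the RMS for an unbiased
fluctuation estimate. Note the trend-elimination order: order-m DFA
removes polynomial trends of order m − 1 *in the signal* (the profile
integrates one order), so immunity to linear signal trends requires
order 2.

## Classification

fGn when the DFA exponent < 1 and β < 1; fBm when both > 1; `ambiguous`
when the indicators conflict. Optional guard zones of configurable width
around 1 turn borderline values into `ambiguous`; the default width is 0
because at N = 425 the estimator spread (≈ 0.1) would otherwise send a
large fraction of genuinely fGn signals with H near 1 into the ambiguous
bin. DFA is the classifying exponent (the conventional instrument for
the dichotomy); the AFA estimate supplies H_fGn, and both are stored as
evidence. Per-subject labels enable per-subject deviations; the
group-level argument (mean H significantly below 1) is reproduced
separately by the one-sample t in `group_stats`.

## Group statistics

* One-sample t oriented as t = (null − M)·√n / SD with df = n − 1, so a
  cohort mean below 1 prints a positive statistic; raw-value and
  (M, SD, n) summary inputs agree to machine precision.
* Per-group Pearson correlations (Spearman optional), p from
  t = r√(n−2)/√(1−r²).
* Between-group contrast by Fisher's r-to-z:
  z = (atanh r_high − atanh r_low) / √(1/(n_high−3) + 1/(n_low−3)), the
  standard two-sample comparison of independent correlations; its type-I
  rate at the study's group sizes (38/65) is verified at 5% ± 1.5% over
  2 000 null cohorts in the acceptance suite.
* FDR by Benjamini–Hochberg step-up at q = 0.05 (Benjamini–Yekutieli
  behind a flag).

## Pipeline and problem sizes

The pipeline is deterministic given config and seed; per-series failures
abort with the offending subject/ROI, while contrasts that are undefined
for a covariate (fewer than 4 classified fGn subjects in a group) are
skipped with a warning. The synthetic demonstration cohort mirrors the
target design (103 subjects split 38/65, two ROIs, N = 425 at TR = 2 s,
group deviation means 0.10/0.05 for ACC and 0.12/0.07 for NAcc, planted
covariate correlations 0.36/−0.03 against the true ACC deviation, true H
clipped to [0.6, 0.98]).

Because estimated deviations at N = 425 carry ≈ 0.095 estimation noise
against a true between-subject spread of 0.08, the planted correlation of
0.36 attenuates to roughly 0.23 in estimated scores; single demo runs
therefore flag the planted covariate only sporadically, and the test
suite asserts the systematic (ensemble) contrast instead. Monte-Carlo
suite sizes — 500 replicates per H for recovery, 100 per ensemble for
classification, 50 for cross-estimator consistency, 2 000 cohorts for
calibration — were chosen to keep Monte-Carlo error a few times smaller
than each tolerance they support.

## Known limitations

* Monofractal analysis only; no multifractal spectrum or wavelet-leader
  estimation.
* The classifier implements the DFA- and β-based rules of the
  classification battery; signal-summation-conversion and bridge-detrended
  variants are out of scope.
* Connectivity enters only as a numeric covariate table; no effective-
  connectivity modelling is performed here.
* No preprocessing (slice timing, realignment, normalisation, smoothing)
  and no high-pass filtering or global-mean correction; inputs are
  assumed preprocessed apart from linear detrending.
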