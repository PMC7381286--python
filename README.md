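# fractalbold

Fractal scaling analysis of BOLD fMRI ROI time series: Hurst-exponent
estimation by adaptive fractal analysis (AFA), spectral scale-invariance
screening, dichotomous fGn/fBm signal classification, 1−H deviation
scores, and the group-level statistics that relate those deviations to
phenotype groups and connectivity covariates.

## The problem

Resting and task fMRI signals exhibit long-range temporal correlations.
The Hurst exponent H quantifies them: H ≈ 0.5 means no memory, H → 1
means strongly persistent, "well-attuned" dynamics. In cohort studies the
*deviation* 1 − H of a region's signal from the H ≈ 1 regime is used as a
marker of altered network function, and is correlated against behavioural
phenotypes (e.g. an impulsivity split at ≥ 3 premature responses in a
serial reaction-time task) and effective-connectivity estimates.

This package implements that analysis chain for regional (spherical-ROI)
time series, and — because such cohort data are rarely shared — ships a
first-class synthetic-data module with *exact* fractional Gaussian noise
so every stage can be validated against known ground truth.

## The method

For a series u(i), i = 1..N (default N = 425 volumes at TR = 2 s):

1. **Extraction** — mean signal over a 10 mm sphere of voxels around a mm
   coordinate, then least-squares linear detrending.
2. **Spectral screen** — periodogram, OLS fit of log S(f) on log f over a
   low-frequency band (≤ 0.1 Hz) giving S(f) ≈ C·|f|^(−β); only signals
   with −1 < β < 3 are scale-invariant enough to classify.
3. **AFA** — the series is integrated into its random-walk profile, a
   globally smooth trend v(i) is built from order-2 polynomial fits in
   overlapping windows w = 2n+1 (n = 5..13) blended linearly over their
   overlaps, and

       F(w) = sqrt( (1/N) Σᵢ (u(i) − v(i))² ) ∝ w^H,

   with H the slope of log₂F(w) vs log₂w. Classical DFA is computed
   alongside as a cross-check.
4. **Classification** — fGn when the DFA exponent and β are below 1, fBm
   when both are above 1, ambiguous on conflict; for fGn signals
   H = H_fGn and the deviation score is 1 − H_fGn.
5. **Group statistics** — one-sample t of H against 1 (oriented so
   smaller-than-1 gives positive t), per-group Pearson correlations of
   deviations with covariates, Fisher r-to-z contrast between the groups,
   Benjamini–Hochberg FDR over the family of contrasts.

## Worked example

```python
from fractalbold import (FgnSpec, generate_fgn, detrend_linear, periodogram,
                         fit_beta, scale_invariance_gate, afa_hurst, dfa,
                         classify_signal, one_sample_t, compare_correlations)

# one synthetic BOLD-like series with known ground truth H = 0.9
ts = detrend_linear(generate_fgn(FgnSpec(hurst=0.9, n_samples=425, seed=42)))
psd = fit_beta(periodogram(ts))
ok, report = scale_invariance_gate(psd)
afa = afa_hurst(ts)
d = dfa(ts)
cls = classify_signal(afa.hurst, d.hurst, psd.beta)
print(f"beta = {psd.beta:.2f} (gate passed: {ok})")
print(f"H_afa = {afa.hurst:.3f} (r^2 = {afa.r_squared:.3f}), H_dfa = {d.hurst:.3f}")
print(f"class = {cls.label}, deviation 1-H = {cls.deviation:.3f}")

# group statistics straight from cohort summary numbers
t = one_sample_t(mean=0.93, sd=0.12, n=103, null_value=1.0)
print(f"t(H_ACC vs 1) = {t.t_statistic:.2f}, df = {t.df}, p = {t.p_two_sided:.2e}")
c = compare_correlations(r_low=-0.03, n_low=65, r_high=0.36, n_high=38)
print(f"Fisher z = {c.z_statistic:.2f}, p = {c.p_value:.3f}")
```

prints

```
beta = 0.76 (gate passed: True)
H_afa = 0.798 (r^2 = 0.985), H_dfa = 0.768
class = fGn, deviation 1-H = 0.202
t(H_ACC vs 1) = 5.92, df = 102, p = 4.36e-08
Fisher z = 1.92, p = 0.054
```

A single N = 425 realization carries a sampling spread of about ±0.1 in
H (this seed drew a low one); the ensemble mean recovers the true value
to within 0.01 (see the acceptance outputs below). The t statistic says
a cohort with mean H = 0.93 (SD 0.12, n = 103) lies significantly below
the well-attuned value 1; the Fisher z contrasts a correlation of 0.36
in a 38-subject group against −0.03 in a 65-subject group.

## Command line

```sh
fractalbold demo --seed 7 --out demo/            # synthetic cohort (103 subjects, 2 ROIs)
fractalbold extract --image img.nii --rois rois.tsv --out series.tsv
fractalbold spectrum --series series.tsv --out beta.tsv
fractalbold hurst --series series.tsv --method afa --out hurst.tsv
fractalbold groupstats --cohort cohort.tsv --covariates ACC_to_l_HC --out stats.tsv
fractalbold run --config run.yaml                # full pipeline
```

The pipeline writes per-subject/ROI metrics, group tests, correlation
contrasts and a YAML provenance echo; identical config + seed gives
byte-identical outputs.

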