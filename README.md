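# bpsignal

Do office, home, ambulatory-daytime and ambulatory-nighttime blood-pressure
(BP) responses to an antihypertensive drug measure one common signal — and
which way of measuring the response gives the most power to find a genetic
predictor of that response?

`bpsignal` implements, as a tested Python pipeline, the measurement-error
framework behind those questions, for biostatisticians and pharmacogenomics
study designers:

- **Same-signal test.** The four measured responses per subject are stacked
  and modeled with covariate-by-method interactions under a cluster-robust
  (GEE-type) covariance; a joint Wald test of the interactions asks whether
  the known predictors of response (race, log plasma renin activity, sex, …)
  depend on the measurement method.
- **Signal/noise decomposition.** Writing method *m*'s pretreatment-adjusted
  response as `y_m = s + e_m` with a shared latent signal `s` and independent
  method noise, every pairwise covariance estimates the signal variance σ²ₛ;
  the decomposition uses the mean of the six pairwise covariances, and
  `noise_m = var(y_m) − σ²ₛ`, `SNR_m = σ²ₛ / noise_m`.
- **Minimum-variance weighted averages.** Weights proportional to the row
  sums of the inverse inter-method covariance matrix minimize the variance of
  a unit-sum combination of methods, maximizing its SNR.
- **Power engine.** For an additive biallelic SNP (MAF *p*, genotype variance
  2p(1−p)) tested at two-sided level α, the required noncentrality is
  `ncp = z(1−α/2) + z(power)`, the detectable fraction of signal variance at
  sample size *n* solves `√(n·r²/(1−r²)) = ncp`, and measurement noise
  attenuates it by λ = 1 + 1/SNR.  The engine converts a decomposition into
  per-scheme power and required sample sizes, and validates itself by
  Monte-Carlo simulation of the Wald regression.
- **Calibrated synthetic cohorts.** A generator emulating a PEAR-style
  monotherapy trial (atenolol / hydrochlorothiazide, systolic / diastolic,
  covariate effects and per-method response moments calibrated to the
  published summaries, optional SNP under Hardy-Weinberg equilibrium) makes
  every stage testable without subject-level data.

## Worked example

```python
import bpsignal as bp

cfg = bp.default_config("atenolol", "systolic", n_subjects=4000, seed=3)
cohort = bp.generate_cohort(cfg)
panel = bp.adjust_pretreatment(bp.compute_responses(cohort, "atenolol", "systolic"))

dec = bp.estimate_signal_noise(panel)
print(round(dec.signal_var, 2), dec.noise_vars.round(1), dec.snr.round(2))
# 64.35 [160.7  25.6  43.3  87.1] [0.4  2.51 1.49 0.74]

ws = bp.min_variance_weights(dec.cov_matrix, bp.METHODS, dec.signal_var)
print(ws.weights.round(3), round(ws.combined_snr, 2))
# [0.076 0.484 0.287 0.152] 5.13

table = bp.scheme_power_table(dec, [ws], bp.PowerSpec())
print(table[["scheme", "snr", "power_at_n", "n_for_target_power"]].round(3))
```

```
                          scheme    snr  power_at_n  n_for_target_power
0                         signal    inf       0.800                 300
1                         office  0.400       0.013                1149
2                           home  2.514       0.411                 436
3                        amb_day  1.486       0.239                 529
4                      amb_night  0.739       0.067                 760
5  office+home+amb_day+amb_night  5.131       0.597                 367
```

Reading the output: the estimated signal variance is ≈64 mmHg²; home and
ambulatory-daytime responses carry more signal than noise (SNR 2.5 and 1.5)
while office and nighttime responses are mostly noise (SNR 0.4 and 0.7).
A SNP with MAF 0.2 detectable with 80% power at n = 300 on a noise-free
signal measurement would be detected with only 1% power via office responses
(n = 1149 for 80% power), but the minimum-variance weighted average of all
four methods (weights above, SNR 5.1) keeps power at 60% and the required
sample size at 367 — within 26% of the noise-free 300.

The same stages are available from the shell:

```bash
bpsignal simulate --out cohort.csv --seed 3 --n 4000
bpsignal analyze signalnoise --in cohort.csv --drug atenolol \
    --endpoint systolic --out-prefix dec
bpsignal power --decomposition dec.json --out power.csv
bpsignal run --out bundle/ --seed 7          # full pipeline report bundle
```

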