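# Methods

## The measurement model

Each subject's BP response to monotherapy (post-treatment average minus
pretreatment average, mmHg, negative for declines) is observed by four
methods: office, home, ambulatory daytime, ambulatory nighttime. The
working model is

    y_im = s_i + δ_m + γ_m (p_im − μ_p) + e_im ,

where `s_i` is the latent drug-response *signal* shared by all methods,
`δ_m` a method-specific mean offset, `p_im` the method's pretreatment
level (regression to the mean: γ_m < 0), and `e_im ~ N(0, σ²_{e,m})`
independent method noise. The signal itself is a linear function of
subject covariates (race, sex, log plasma renin activity, log hypertension
years, serum ALT), optionally an additive SNP, plus a normal residual.

Under this model, after the pretreatment term is regressed out per method,
the covariance matrix of the four responses is compound-symmetric up to
the noise diagonal: every off-diagonal entry estimates the signal variance
σ²ₛ. The decomposition therefore uses the mean of the six pairwise
covariances as σ̂²ₛ and `noise_m = var(y_m) − σ̂²ₛ`. A negative noise
estimate (a method variance below the mean covariance) is reported with a
flag and an undefined SNR rather than clipped to zero; silent truncation
would bias the power stage.

## Pretreatment adjustment

Each method's raw response is residualized on its own pretreatment value
(simple least squares with intercept), and the column mean is restored so
the adjusted response keeps its mmHg location. Cross-method pretreatment
terms are not used. The mean restoration is a presentation choice only:
covariances, SNRs and every downstream quantity are invariant to it.
Subjects missing any method are excluded (complete-case) because the
covariance step needs a complete N×4 matrix; the count is logged.

## Predictor models and backward elimination

Predictor models are OLS fits of one method's adjusted response
(default: home, the highest-SNR single method; any method can be chosen)
on subject covariates. Backward elimination works per drug arm across the
two endpoints: a candidate is retained only while significant (p < 0.05,
fixed a priori) for **both** the systolic and diastolic responses; the
weakest candidate — the one with the largest *minimum* p-value across the
two endpoints — is dropped and the models refit, one drop at a time. If
nothing survives, intercept-only models are returned with a warning.
Designs with condition number above 1e10 raise a collinearity error.

## The same-signal test

The four adjusted responses per subject are stacked long and modeled as

    covariates + method indicators + covariate×method interactions,

estimated by GEE with an exchangeable working correlation over the four
within-subject rows (independence available as an option; estimation
failures fall back to it with a warning). The joint Wald test that all
interaction coefficients vanish is the test of the same-signal null; with
four methods and k covariates it has 3k degrees of freedom.

Finite-sample inference. The asymptotic chi-square reference for a
high-dimensional Wald quadratic form in an estimated cluster-robust
covariance over-rejects in finite samples (at n = 500 subjects and 15 df
the statistic's null mean/variance are inflated to ≈15.9/36 versus the
nominal 15/30, giving ≈7% rejection at the 5% level). The default
inference therefore combines two standard small-sample remedies: the
Mancl–DeRouen bias-corrected sandwich, and a Hotelling T² (scaled F)
reference with nominal size m = clusters − mean parameters:

    W · (m − d + 1) / (d · m)  ~  F(d, m − d + 1),   d = 3k.

Null simulations at n = 500 put the type-I error of this combination at
0.050–0.059. The asymptotic reference remains available
(`reference="chisq"`); exact SAS-GENMOD internals are out of scope. When a
model fits the stacked data perfectly (zero residuals), the sandwich is
exactly zero and the test returns statistic 0, p = 1, rather than
amplifying floating-point noise.

## Minimum-variance weighted averages

For a subset of methods with covariance submatrix Σ, the unit-sum weights
minimizing `wᵀΣw` are `w ∝ Σ⁻¹1` — the row sums of the inverse covariance
matrix, normalized to sum to one. Normalization keeps the combination an
unbiased estimate of the signal plus its mean and does not change the
combination's SNR. When the noises are uncorrelated this reduces to
classical precision weighting (w ∝ 1/noise), and the combined SNR equals
the sum of the member SNRs. `combined_noise = wᵀΣw − σ̂²ₛ` uses the
full-panel signal estimate. Singular submatrices raise an error naming the
subset; singleton subsets get weight 1.

## Power and sample size

The association design is a biallelic SNP, additively coded 0/1/2 with
genotype variance 2p(1−p) under Hardy-Weinberg equilibrium, tested by Wald
regression at two-sided level α (default 5×10⁻⁸, the genome-wide
Bonferroni convention). The anchor is the effect detectable with power
1−β at a reference n on a *perfect* (noise-free) measurement of the
signal:

    ncp = z(1−α/2) + z(1−β),       r²_signal = ncp² / (ncp² + n_ref),
    β_allele = sqrt(r²_signal · σ²ₛ / (2p(1−p))) .

Measurement noise inflates the response variance by λ = 1 + 1/SNR and
attenuates the explainable fraction to `r²_scheme = r²_signal / λ`
(classical measurement-error attenuation; verified against empirical R²
in large simulations). Then

    power(n) = Φ( sqrt(n · r² / (1−r²)) − z(1−α/2) ),
    n(power) = ceil( ncp² (1−r²) / r² ) ,

with the negligible wrong-sign tail omitted; at r² = 0 the power formula
returns α/2, the one-tail null rate. Sample sizes report both the ceiling
and the unrounded value; a 1e−8 slack in the ceiling guards against
floating-point noise when the inversion is exact.

The normal approximation is the default because the anchor quantities
(ncp = 6.29, r² = 11.7% at n = 300) are exactly the sums of normal
quantiles. An `approx="nct"` variant computes the exact rejection rate of
the finite-sample Wald chi-square — the t statistic scaled by
sqrt(n/(n−2)) (maximum-likelihood residual variance, the GEE/GENMOD
convention) against the normal critical value — via the noncentral t
distribution, with a chi-square–mixture quadrature fallback where scipy's
`nct` loses accuracy in far tails. At n ≈ 300 the two differ by well
under one percentage point; at n = 100 with α = 5×10⁻⁸ the normal
approximation is off by up to ≈0.016 absolute, and the nct variant is the
one that tracks Monte-Carlo rejection rates to binomial error.

`simulate_association_power` is the Monte-Carlo validator. Its default
`effect_scale="r_squared"` scales the slope to each replicate's realized
genotype spread, so every replicate is generated at the stated R² and the
noncentrality matches the engine's assumption exactly. The alternative
`"per_allele"` holds the mmHg/allele effect fixed, letting the realized
noncentrality vary with the genotype draw; that design variability
attenuates power by ≈0.8 percentage points at n = 300 (a Jensen effect
the analytic framework, like any fixed-ncp calculation, does not model).

## The synthetic-data generator

The generator emulates a two-arm monotherapy trial (atenolol 293 /
hydrochlorothiazide 302 in the source study; default 300 per arm here).
What it reproduces, per (drug, endpoint):

- Covariate marginals: race Bernoulli(0.41), male Bernoulli(0.47); plasma
  renin activity log-normal with natural-scale mean 1.0 and SD 1.2
  ng·mL⁻¹·hr⁻¹ (log-scale μ = −0.446, σ = 0.944); hypertension duration as
  log(years+1) ~ N(1.80, 0.76²), tolerating zero durations (the source's
  transform is unstated); serum ALT ~ N(29.1, 15.9) U/L.
- Covariate effects on the signal taken verbatim from the published
  per-arm regression models (e.g. atenolol systolic: intercept −14.1,
  race +6.3, log-PRA −4.4, male +2.3, log-htn-years +1.3, ALT +0.08);
  the intercept is the reference-category (non-black female) mean, with
  continuous covariates centered at their population means, which is what
  makes the published coefficients usable as-is.
- Total signal variances 64 / 31 / 44.8 / 19 mmHg² (atenolol sys/dia,
  HCTZ sys/dia). Three of the four are implied exactly by the published
  per-allele effect sizes through β = √(r²σ²ₛ/0.32); for atenolol
  systolic the implied 74.9 would push the nighttime SNR to 1.0 under the
  published total variances, so 64 is used to preserve the qualitative
  SNR ordering (home ≈ day > 1 > night > office) that the source reports.
  The residual signal variance is the total minus the analytic covariate
  contribution.
- Per-method noise variances chosen so raw response variances match the
  published totals (office 15.6², home 10.4², … for atenolol systolic)
  after subtracting the signal and the pretreatment contribution; method
  mean offsets reproduce the published per-method mean responses.
- Pretreatment levels: a shared subject level plus a small method-specific
  deviation (marginal mean/SD 151.5/13.8 systolic, 98.2/6.3 diastolic),
  with regression-to-the-mean slopes γ = −0.3 for every method — a modest
  value; the source reports the direction but no magnitude.
- Genotypes Binomial(2, MAF) under HWE; the SNP effect is zero by default
  and the genotype column is ignored by every estimation stage (it exists
  for power-validation Monte Carlo).
- An optional eligibility filter (home diastolic ≥ 85 and office
  diastolic ≥ 90 mmHg, the trial's entry thresholds). It is **off** by
  default: the induced selection is not modeled by the variance machinery;
  the filter exists to probe that sensitivity.

What it does not emulate: individual readings within a visit (only the
pre/post averages the analysis consumes), dose titration, longitudinal
visit structure, cross-endpoint signal correlation (the two endpoints'
signals are conditionally independent given covariates), and any
covariate dependence beyond the linear model above. Passing tests
therefore show that the estimators recover the truth *of this model*, not
that real BP-response data satisfy it.

`response_covariance_truth`, `response_mean_truth` and
`signal_variance_truth` expose the population moments implied by a
configuration; the test suite uses them as oracles. A fixed seed
reproduces a cohort byte-identically.

## Pipeline and artifacts

`run_pipeline` chains simulate → prep → predictors → signal/noise → power
per (drug, endpoint), persisting every intermediate as CSV/JSON so each
stage is independently re-runnable, and writes a manifest with the seed,
package version, subject counts entering/leaving each stage, and SHA-256
hashes of every artifact (fixed seed ⇒ byte-identical bundles). The
inter-method correlation range of adjusted responses is logged as a
diagnostic. Test problem sizes: calibration and recovery checks run at
n = 2 000–5 000 subjects with 20–200 replicates, the same-signal
calibration at n = 500 with 1000 null replicates, and Monte-Carlo power
validation at 10⁵ replicates; these sizes make the Monte-Carlo error
small against each test's tolerance.

## Known limitations

- The signal estimator averages six correlated covariances; no shrinkage
  or confidence intervals are provided (the framework reports none).
- The same-signal test's exchangeable working correlation is a
  convenience; the robust covariance keeps it valid, but efficiency under
  strong heteroscedasticity across methods is not optimal.
- The power engine treats the SNP as explaining a *fixed* fraction of
  signal variance; winner's curse, LD with the causal variant and
  imputation quality are out of scope.
- Eligibility selection, if enabled, truncates the pretreatment
  distribution and biases the variance decomposition; no correction is
  attempted.
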