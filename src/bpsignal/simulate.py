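"""Synthetic cohort generator for antihypertensive BP-response studies.

The generator emulates a PEAR-like monotherapy trial: each subject has a
latent blood-pressure response *signal* (the true drug effect, mmHg,
negative for declines) driven by covariates and optionally by a biallelic
SNP in Hardy-Weinberg equilibrium.  The four measurement methods (office,
home, ambulatory daytime, ambulatory nighttime) each observe

    response_m = signal + offset_m + gamma_m * (pretreat_m - pretreat_mean)
                 + noise_m,        noise_m ~ N(0, noise_vars[m]),

so the inter-method covariance of the responses, after the pretreatment
term is regressed out, is compound-symmetric: a shared signal variance on
the off-diagonals plus method-specific noise on the diagonal.  This is the
measurement model that the downstream signal/noise decomposition assumes,
and the ``latent_signal`` column is retained so tests can check truth
recovery (it is oracle-only and ignored by every estimation stage).

Default parameters are calibrated to the published PEAR monotherapy
summaries: covariate prevalences and scales from the trial's descriptive
table, covariate effects on the signal from its predictor models, and
per-method response means/SDs from its response summary table.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

METHODS = ("office", "home", "amb_day", "amb_night")
ENDPOINTS = ("systolic", "diastolic")
DRUGS = ("atenolol", "hctz")
COVARIATES = ("race_black", "male", "log_pra", "log_htn_years", "alt")

#: default effects of the predictors on the latent signal, mmHg per unit
#: (race/sex indicators uncentered; continuous covariates centered at their
#: population means so the intercept is the reference-category signal mean)
_CALIBRATION = {
    ("atenolol", "systolic"): dict(
        intercept=-14.1,
        beta={"race_black": 6.3, "log_pra": -4.4, "male": 2.3,
              "log_htn_years": 1.3, "alt": 0.08},
        signal_var=64.0,
        noise_vars=(162.2, 27.0, 42.1, 85.3),
        table_means=(-13.5, -8.3, -12.2, -8.9),
    ),
    ("atenolol", "diastolic"): dict(
        intercept=-11.8,
        beta={"race_black": 4.8, "log_pra": -2.5, "male": 2.9,
              "log_htn_years": 1.0, "alt": 0.04},
        signal_var=31.0,
        noise_vars=(53.8, 11.7, 27.8, 65.4),
        table_means=(-10.5, -7.8, -9.2, -7.0),
    ),
    ("hctz", "systolic"): dict(
        intercept=-11.8,
        beta={"race_black": -2.9, "log_pra": 0.7, "male": 4.2,
              "log_htn_years": 0.0, "alt": 0.0},
        signal_var=44.8,
        noise_vars=(125.8, 20.9, 34.1, 84.5),
        table_means=(-13.2, -9.4, -10.8, -10.6),
    ),
    ("hctz", "diastolic"): dict(
        intercept=-6.7,
        beta={"race_black": -2.0, "log_pra": 0.7, "male": 2.7,
              "log_htn_years": 0.0, "alt": 0.0},
        signal_var=19.0,
        noise_vars=(39.8, 13.4, 26.4, 58.4),
        table_means=(-6.8, -5.3, -6.1, -6.5),
    ),
}

_PRETREAT = {
    # marginal per-method pretreatment mean/SD plus the SD of the
    # method-specific deviation around the subject's shared pretreatment level
    "systolic": dict(pretreat_mean=151.5, pretreat_sd=13.8, pretreat_method_sd=4.0),
    "diastolic": dict(pretreat_mean=98.2, pretreat_sd=6.3, pretreat_method_sd=2.5),
}


@dataclass
class CovariateParams:
    """Marginal distributions of the subject-level covariates.

    Renin activity is log-normal with mean 1.0 and SD 1.2 ng/mL/hr on the
    natural scale; hypertension duration is modeled as log(years + 1) so a
    zero duration is representable.
    """

    race_prev: float = 0.41
    male_prev: float = 0.47
    log_pra_mean: float = -0.44600
    log_pra_sd: float = 0.94446
    log_htn_mean: float = 1.80072
    log_htn_sd: float = 0.76308
    alt_mean: float = 29.1
    alt_sd: float = 15.9

    def variances(self) -> dict[str, float]:
        return {
            "race_black": self.race_prev * (1 - self.race_prev),
            "male": self.male_prev * (1 - self.male_prev),
            "log_pra": self.log_pra_sd ** 2,
            "log_htn_years": self.log_htn_sd ** 2,
            "alt": self.alt_sd ** 2,
        }

    def means(self) -> dict[str, float]:
        return {
            "race_black": self.race_prev,
            "male": self.male_prev,
            "log_pra": self.log_pra_mean,
            "log_htn_years": self.log_htn_mean,
            "alt": self.alt_mean,
        }


@dataclass
class GeneratorConfig:
    """Full specification of one simulated (drug, endpoint) cohort."""

    n_subjects: int = 300
    drug: str = "atenolol"
    endpoint: str = "systolic"
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    intercept: float = -14.1
    beta: dict[str, float] = field(default_factory=dict)
    signal_resid_var: float = 33.0
    noise_vars: tuple[float, float, float, float] = (162.2, 27.0, 42.1, 85.3)
    method_offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    pretreat_mean: float = 151.5
    pretreat_sd: float = 13.8
    pretreat_method_sd: float = 4.0
    gamma: tuple[float, float, float, float] = (-0.3, -0.3, -0.3, -0.3)
    maf: float = 0.2
    beta_snp: float = 0.0
    seed: int = 0
    apply_eligibility: bool = False
    #: covariate -> per-method extra effect, added post-noise to single
    #: methods; breaks the same-signal model on purpose (default none)
    method_specific_betas: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects >= 2):
            raise ValidationError(f"n_subjects must be an integer >= 2, got {self.n_subjects}")
        if self.drug not in DRUGS:
            raise ValidationError(f"drug must be one of {DRUGS}, got {self.drug!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValidationError(f"maf must lie in [0, 0.5], got {self.maf}")
        if self.signal_resid_var < 0:
            raise ValidationError(f"signal_resid_var must be >= 0, got {self.signal_resid_var}")
        if len(self.noise_vars) != 4 or any(v < 0 for v in self.noise_vars):
            raise ValidationError(f"noise_vars must be 4 nonnegative values, got {self.noise_vars}")
        if len(self.gamma) != 4:
            raise ValidationError(f"gamma must have 4 entries, got {self.gamma}")
        if len(self.method_offsets) != 4:
            raise ValidationError(f"method_offsets must have 4 entries, got {self.method_offsets}")
        if self.pretreat_sd <= 0:
            raise ValidationError(f"pretreat_sd must be > 0, got {self.pretreat_sd}")
        if not 0 <= self.pretreat_method_sd < self.pretreat_sd:
            raise ValidationError(
                "pretreat_method_sd must be in [0, pretreat_sd), got "
                f"{self.pretreat_method_sd}"
            )
        unknown = set(self.beta) - set(COVARIATES)
        if unknown:
            raise ValidationError(f"beta names unknown covariates: {sorted(unknown)}")
        unknown = set(self.method_specific_betas) - set(COVARIATES)
        if unknown:
            raise ValidationError(
                f"method_specific_betas names unknown covariates: {sorted(unknown)}"
            )

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_vars"] = list(self.noise_vars)
        d["method_offsets"] = list(self.method_offsets)
        d["gamma"] = list(self.gamma)
        d["method_specific_betas"] = {
            k: list(v) for k, v in self.method_specific_betas.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "covariate_params" in d and isinstance(d["covariate_params"], Mapping):
            d["covariate_params"] = CovariateParams(**d["covariate_params"])
        for key in ("noise_vars", "method_offsets", "gamma"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        if "method_specific_betas" in d:
            d["method_specific_betas"] = {
                k: tuple(float(x) for x in v)
                for k, v in d["method_specific_betas"].items()
            }
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(drug: str = "atenolol", endpoint: str = "systolic",
                   n_subjects: int = 300, seed: int = 0,
                   **overrides) -> GeneratorConfig:
    """Build the calibrated default configuration for one (drug, endpoint).

    The intercept, covariate effects, total signal variance and per-method
    noise variances reproduce the published monotherapy summaries;
    ``signal_resid_var`` is the total signal variance minus the analytic
    covariate contribution, so the latent signal's variance equals the
    calibrated total.  Per-method mean offsets reproduce the published
    per-method mean responses.
    """
    if (drug, endpoint) not in _CALIBRATION:
        raise ValidationError(f"no calibration for drug={drug!r}, endpoint={endpoint!r}")
    cal = _CALIBRATION[(drug, endpoint)]
    cov = overrides.pop("covariate_params", CovariateParams())
    variances = cov.variances()
    cov_contrib = sum(b * b * variances[name] for name, b in cal["beta"].items())
    resid = cal["signal_var"] - cov_contrib
    if resid < 0:  # pragma: no cover - calibration guard
        raise ValidationError("covariate effects exceed the calibrated signal variance")
    base_mean = (cal["intercept"]
                 + cov.race_prev * cal["beta"]["race_black"]
                 + cov.male_prev * cal["beta"]["male"])
    offsets = tuple(m - base_mean for m in cal["table_means"])
    cfg = GeneratorConfig(
        n_subjects=n_subjects,
        drug=drug,
        endpoint=endpoint,
        covariate_params=cov,
        intercept=cal["intercept"],
        beta=dict(cal["beta"]),
        signal_resid_var=resid,
        noise_vars=cal["noise_vars"],
        method_offsets=offsets,
        seed=seed,
        **_PRETREAT[endpoint],
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown config field: {key}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# analytic truth helpers (used as oracles by the test suite)

def signal_variance_truth(config: GeneratorConfig) -> float:
    """Population variance of the latent signal implied by a config."""
    variances = config.covariate_params.variances()
    v = config.signal_resid_var
    v += sum(b * b * variances[name] for name, b in config.beta.items())
    v += config.beta_snp ** 2 * 2 * config.maf * (1 - config.maf)
    return v


def response_covariance_truth(config: GeneratorConfig, adjusted: bool = False) -> np.ndarray:
    """Population 4x4 covariance of the (raw or pretreatment-adjusted) responses.

    Raw:      sigma_s^2 * J + shared_var * gamma gamma^T
              + diag(gamma^2 * method_var + noise_vars)
    Adjusted: sigma_s^2 * J + diag(noise_vars)
    """
    s = signal_variance_truth(config)
    cov = np.full((4, 4), s)
    noise = np.asarray(config.noise_vars, dtype=float)
    if adjusted:
        cov[np.diag_indices(4)] += noise
        return cov
    g = np.asarray(config.gamma, dtype=float)
    shared_var = config.pretreat_sd ** 2 - config.pretreat_method_sd ** 2
    cov += shared_var * np.outer(g, g)
    cov[np.diag_indices(4)] += g * g * config.pretreat_method_sd ** 2 + noise
    return cov


def response_mean_truth(config: GeneratorConfig) -> np.ndarray:
    """Population per-method mean response implied by a config."""
    cov = config.covariate_params
    base = (config.intercept
            + cov.race_prev * config.beta.get("race_black", 0.0)
            + cov.male_prev * config.beta.get("male", 0.0)
            + 2 * config.maf * config.beta_snp)
    means = base + np.asarray(config.method_offsets, dtype=float)
    for name, deltas in config.method_specific_betas.items():
        means = means + np.asarray(deltas, dtype=float) * cov.means()[name]
    return means


# ---------------------------------------------------------------------------
# generation

def _draw_covariates(rng: np.random.Generator, n: int, p: CovariateParams) -> pd.DataFrame:
    return pd.DataFrame({
        "race_black": rng.binomial(1, p.race_prev, n),
        "male": rng.binomial(1, p.male_prev, n),
        "log_pra": rng.normal(p.log_pra_mean, p.log_pra_sd, n),
        "log_htn_years": rng.normal(p.log_htn_mean, p.log_htn_sd, n),
        "alt": rng.normal(p.alt_mean, p.alt_sd, n),
    })


def _endpoint_block(rng: np.random.Generator, config: GeneratorConfig,
                    covariates: pd.DataFrame, genotype: np.ndarray) -> pd.DataFrame:
    n = len(covariates)
    p = config.covariate_params
    means = p.means()
    signal = np.full(n, config.intercept, dtype=float)
    for name, b in config.beta.items():
        x = covariates[name].to_numpy(dtype=float)
        if name not in ("race_black", "male"):
            x = x - means[name]  # centered so the intercept is the reference mean
        signal += b * x
    signal += config.beta_snp * genotype
    signal += rng.normal(0.0, math.sqrt(config.signal_resid_var), n)

    shared_sd = math.sqrt(config.pretreat_sd ** 2 - config.pretreat_method_sd ** 2)
    shared_pre = rng.normal(config.pretreat_mean, shared_sd, n)

    block = {f"latent_signal_{config.endpoint}": signal}
    for m, method in enumerate(METHODS):
        pre = shared_pre + rng.normal(0.0, config.pretreat_method_sd, n)
        resp = (signal
                + config.method_offsets[m]
                + config.gamma[m] * (pre - config.pretreat_mean)
                + rng.normal(0.0, math.sqrt(config.noise_vars[m]), n))
        for name, deltas in config.method_specific_betas.items():
            resp = resp + deltas[m] * covariates[name].to_numpy(dtype=float)
        block[f"pre_{method}_{config.endpoint}"] = pre
        block[f"post_{method}_{config.endpoint}"] = pre + resp
    return pd.DataFrame(block)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a single-endpoint cohort table.

    One row per subject: arm, covariates, genotype (0/1/2 under HWE at the
    configured MAF), per-method pre/post-treatment BP averages, and the
    oracle-only latent signal. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    covariates = _draw_covariates(rng, n, config.covariate_params)
    genotype = rng.binomial(2, config.maf, n)
    block = _endpoint_block(rng, config, covariates, genotype)
    cohort = pd.concat(
        [pd.DataFrame({"subject_id": np.arange(n), "arm": config.drug}),
         covariates, pd.Series(genotype, name="genotype"), block],
        axis=1,
    )
    if config.apply_eligibility:
        cohort = apply_eligibility_filter(cohort)
    return cohort


def generate_study(config_systolic: GeneratorConfig,
                   config_diastolic: GeneratorConfig) -> pd.DataFrame:
    """Generate a two-endpoint cohort with shared subjects.

    Covariates and genotype are drawn once (from the systolic config's seed)
    and both endpoints' responses are generated for the same subjects, as a
    backward-elimination run across endpoints requires. The two endpoints'
    latent signals are conditionally independent given the covariates.
    """
    for cfg in (config_systolic, config_diastolic):
        cfg.validate()
    if config_systolic.drug != config_diastolic.drug:
        raise ValidationError("drug must match between the endpoint configs")
    if config_systolic.n_subjects != config_diastolic.n_subjects:
        raise ValidationError("n_subjects must match between the endpoint configs")
    if (config_systolic.endpoint, config_diastolic.endpoint) != ("systolic", "diastolic"):
        raise ValidationError("configs must be (systolic, diastolic) in that order")
    rng = np.random.default_rng(config_systolic.seed)
    n = config_systolic.n_subjects
    covariates = _draw_covariates(rng, n, config_systolic.covariate_params)
    genotype = rng.binomial(2, config_systolic.maf, n)
    blocks = [_endpoint_block(rng, cfg, covariates, genotype)
              for cfg in (config_systolic, config_diastolic)]
    cohort = pd.concat(
        [pd.DataFrame({"subject_id": np.arange(n), "arm": config_systolic.drug}),
         covariates, pd.Series(genotype, name="genotype"), *blocks],
        axis=1,
    )
    if config_systolic.apply_eligibility:
        cohort = apply_eligibility_filter(cohort)
    return cohort


def apply_eligibility_filter(cohort: pd.DataFrame,
                             home_dbp_min: float = 85.0,
                             office_dbp_min: float = 90.0) -> pd.DataFrame:
    """Retain subjects meeting the trial's diastolic BP entry thresholds.

    Keeps rows with pretreatment home DBP >= ``home_dbp_min`` AND
    pretreatment office DBP >= ``office_dbp_min`` (trial defaults 85/90).
    Note the induced selection is not modeled by the downstream variance
    machinery; the filter is off by default and exists to probe sensitivity.
    """
    for name, thr in (("home_dbp_min", home_dbp_min), ("office_dbp_min", office_dbp_min)):
        if not isinstance(thr, (int, float, np.integer, np.floating)) or isinstance(thr, bool):
            raise ValidationError(f"{name} must be numeric, got {thr!r}")
    for col in ("pre_home_diastolic", "pre_office_diastolic"):
        if col not in cohort.columns:
            raise ValidationError(f"eligibility filter requires column {col!r}")
    keep = ((cohort["pre_home_diastolic"] >= home_dbp_min)
            & (cohort["pre_office_diastolic"] >= office_dbp_min))
    return cohort.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as comma-delimited text; missing genotypes are empty."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    if "genotype" in cohort.columns:
        cohort["genotype"] = cohort["genotype"].astype("Int64")
    return cohort
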