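"""Analytic power and sample size for detecting a SNP behind the BP-response signal.

The association design is a single biallelic SNP, additively coded (0/1/2,
genotype variance 2p(1-p) under Hardy-Weinberg equilibrium), tested by Wald
regression of the quantitative response at a two-sided level alpha. The
anchor is the effect size detectable with a reference power at a reference
sample size under a *perfect* measurement of the signal (no noise); the
required noncentrality is the sum of two standard-normal quantiles,

    ncp = z(1 - alpha/2) + z(power),

and the fraction of signal variance that effect explains solves
sqrt(n * r2 / (1 - r2)) = ncp.  Measurement noise inflates the response
variance by lambda = 1 + 1/SNR, attenuating the explainable fraction to
r2 / lambda (classical measurement-error attenuation), which maps directly
to the power at a given n and the n required for a target power.

Power uses the normal approximation Phi(sqrt(n r2/(1-r2)) - z(1-alpha/2));
the far-tail term is negligible at any useful power. An exact
noncentral-t variant (modeling the finite-sample Wald chi-square with
maximum-likelihood residual variance) is available via ``approx="nct"``;
at n around 300 the two differ by well under one percentage point, but the
nct variant tracks Monte-Carlo rejection rates to binomial error even at
small n and extreme alpha.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .signalnoise import SignalNoiseDecomposition, WeightedAverageSpec


@dataclass
class PowerSpec:
    """Association-design assumptions anchoring the power analysis."""

    maf: float = 0.2
    alpha: float = 5e-8
    n_ref: int = 300
    power_ref: float = 0.8
    signal_var: float | None = None   # mmHg^2, for effect-size conversion

    def validate(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValidationError(f"maf must lie in (0, 0.5], got {self.maf}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.power_ref < 1:
            raise ValidationError(f"power_ref must lie in (0, 1), got {self.power_ref}")
        if self.n_ref < 2:
            raise ValidationError(f"n_ref must be >= 2, got {self.n_ref}")


@dataclass
class PowerResult:
    """Derived quantities for one measurement scheme."""

    scheme: str
    snr: float
    variance_inflation: float       # lambda = 1 + 1/SNR; 1 = perfect measurement
    r2_signal: float
    r2_scheme: float
    beta_per_allele: float | None   # mmHg/allele; None without a signal variance
    power_at_n: float
    n_for_target_power: int
    n_unrounded: float


def required_ncp(alpha: float, power: float) -> float:
    """Noncentrality needed for the given two-sided level and power."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0 < power < 1:
        raise ValidationError(f"power must lie in (0, 1), got {power}")
    return float(stats.norm.isf(alpha / 2) + stats.norm.ppf(power))


def detectable_r2(ncp: float, n: int) -> float:
    """Variance fraction detectable with noncentrality ``ncp`` at sample size ``n``.

    Solves sqrt(n * r2 / (1 - r2)) = ncp, i.e. r2 = ncp^2 / (ncp^2 + n).
    """
    if ncp < 0:
        raise ValidationError(f"ncp must be >= 0, got {ncp}")
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    return float(ncp * ncp / (ncp * ncp + n))


def allele_effect_size(r2_signal: float, signal_var: float, maf: float) -> float:
    """Per-allele effect (mmHg/allele) explaining ``r2_signal`` of the signal."""
    if not 0 <= r2_signal < 1:
        raise ValidationError(f"r2_signal must lie in [0, 1), got {r2_signal}")
    if signal_var <= 0:
        raise ValidationError(f"signal_var must be > 0, got {signal_var}")
    var_g = 2 * maf * (1 - maf)
    if var_g <= 0:
        raise ValidationError(f"degenerate genotype: maf={maf} gives zero variance")
    return math.sqrt(r2_signal * signal_var / var_g)


def _nct_power(delta: float, n: int, z: float) -> float:
    """P(|Wald| > z) where Wald = t * sqrt(n/(n-2)) and t ~ nct(n-2, delta)."""
    df = n - 2
    thr = z * math.sqrt(df / n)
    upper = stats.nct.sf(thr, df, delta)
    lower = stats.nct.cdf(-thr, df, delta)
    if np.isnan(upper) or np.isnan(lower):
        # scipy's nct is unstable in far tails; integrate over the chi-square
        # denominator instead: P(t > thr) = E_W[Phi(delta - thr*sqrt(W/df))]
        w, step = np.linspace(max(df - 10 * math.sqrt(2 * df), 1e-9),
                              df + 10 * math.sqrt(2 * df), 4001, retstep=True)
        pdf = stats.chi2.pdf(w, df)
        upper = float(np.trapezoid(stats.norm.cdf(delta - thr * np.sqrt(w / df)) * pdf, dx=step))
        lower = float(np.trapezoid(stats.norm.cdf(-delta - thr * np.sqrt(w / df)) * pdf, dx=step))
    return float(upper + lower)


def power_at_n(n: int, r2_scheme: float, alpha: float, approx: str = "normal") -> float:
    """Power of the two-sided Wald test at sample size ``n``.

    ``approx="normal"`` (default): Phi(sqrt(n r2/(1-r2)) - z(1-alpha/2)); at
    r2 = 0 this returns alpha/2, the one-tail null rate (the wrong-sign tail
    is not counted). ``approx="nct"``: exact noncentral-t rate of the
    MLE-variance Wald chi-square, both tails.
    """
    if not 0 <= r2_scheme < 1:
        raise ValidationError(f"r2_scheme must lie in [0, 1), got {r2_scheme}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if n < 3:
        raise ValidationError(f"n must be >= 3, got {n}")
    z = stats.norm.isf(alpha / 2)
    delta = math.sqrt(n * r2_scheme / (1 - r2_scheme))
    if approx == "normal":
        return float(stats.norm.cdf(delta - z))
    if approx == "nct":
        return _nct_power(delta, n, z)
    raise ValidationError(f"approx must be 'normal' or 'nct', got {approx!r}")


def sample_size_for_power(r2_scheme: float, alpha: float, power: float) -> int:
    """Smallest n with analytic power >= ``power`` (ceil of the exact solution)."""
    n, _ = _sample_size(r2_scheme, alpha, power)
    return n


def _sample_size(r2_scheme: float, alpha: float, power: float) -> tuple[int, float]:
    if not 0 <= r2_scheme < 1:
        raise ValidationError(f"r2_scheme must lie in [0, 1), got {r2_scheme}")
    if r2_scheme == 0:
        warnings.warn("r2_scheme = 0: no finite sample size achieves the target power")
        return np.iinfo(np.int64).max, math.inf
    ncp = required_ncp(alpha, power)
    exact = ncp * ncp * (1 - r2_scheme) / r2_scheme
    # guard against fp noise pushing an exact integer solution up by one
    return int(math.ceil(exact - 1e-8)), float(exact)


def simulate_association_power(n: int, r2: float, alpha: float, maf: float = 0.2,
                               n_reps: int = 100_000,
                               rng: np.random.Generator | int | None = None,
                               effect_scale: str = "r_squared",
                               chunk: int = 5_000) -> float:
    """Monte-Carlo rejection rate of the additive-SNP Wald regression.

    Each replicate draws ``n`` genotypes from Binomial(2, maf) and a
    phenotype with the SNP explaining ``r2`` of its variance, fits the
    simple regression, and rejects when the Wald chi-square (slope over its
    MLE-variance standard error) exceeds the two-sided normal critical
    value — the large-sample test the analytic engine models.

    ``effect_scale="r_squared"`` (default) scales the slope to the
    replicate's realized genotype spread so every replicate is generated at
    the stated R²; ``"per_allele"`` holds the mmHg/allele effect fixed at
    the value implied by the population genotype variance 2p(1-p), letting
    the realized noncentrality vary with the genotype draw (about one
    percentage point lower power at n = 300 from that design variability).
    """
    if effect_scale not in ("r_squared", "per_allele"):
        raise ValidationError(f"effect_scale must be 'r_squared' or 'per_allele'")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    z = stats.norm.isf(alpha / 2)
    slope_pop = math.sqrt(r2 / (1 - r2) / (2 * maf * (1 - maf)))  # sigma_e = 1
    n_reject = 0
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        G = rng.binomial(2, maf, size=(b, n)).astype(float)
        G -= G.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", G, G)
        sxx = np.maximum(sxx, 1e-300)  # all-identical genotype draws never reject
        E = rng.standard_normal((b, n))
        E -= E.mean(axis=1, keepdims=True)
        if effect_scale == "r_squared":
            scale = math.sqrt(n * r2 / (1 - r2)) / np.sqrt(sxx)
        else:
            scale = slope_pop
        Y = scale[..., None] * G + E if effect_scale == "r_squared" else slope_pop * G + E
        sxy = np.einsum("ij,ij->i", G, Y)
        syy = np.einsum("ij,ij->i", Y, Y)
        slope = sxy / sxx
        rss = syy - slope * sxy
        sigma2_mle = np.maximum(rss, 0.0) / n
        wald = slope * np.sqrt(sxx / np.maximum(sigma2_mle, 1e-300))
        n_reject += int(np.count_nonzero(np.abs(wald) > z))
        done += b
    return n_reject / n_reps


def scheme_power_table(decomposition: SignalNoiseDecomposition,
                       weighted_specs: Sequence[WeightedAverageSpec] = (),
                       spec: PowerSpec = None) -> pd.DataFrame:
    """Power/sample-size table across measurement schemes.

    One row for the perfect signal measurement (lambda = 1) and one per
    single method and weighted-average scheme; schemes with a negative
    noise estimate (undefined SNR) are kept as warning rows with NaN
    power. Scheme power ordering equals SNR ordering.
    """
    if spec is None:
        spec = PowerSpec()
    spec.validate()
    ncp = required_ncp(spec.alpha, spec.power_ref)
    r2_signal = detectable_r2(ncp, spec.n_ref)
    signal_var = spec.signal_var if spec.signal_var is not None else decomposition.signal_var
    beta = allele_effect_size(r2_signal, signal_var, spec.maf) if signal_var > 0 else None

    rows = []

    def add_row(scheme, snr):
        if not np.isfinite(snr) or snr <= 0:
            warnings.warn(f"scheme {scheme!r} has undefined SNR (negative noise); "
                          "power not computed")
            rows.append(dict(scheme=scheme, snr=np.nan, variance_inflation=np.nan,
                             r2_scheme=np.nan, power_at_n=np.nan,
                             n_for_target_power=np.nan, n_unrounded=np.nan))
            return
        lam = 1.0 + 1.0 / snr if np.isfinite(snr) else 1.0
        r2s = r2_signal / lam
        n_req, n_exact = _sample_size(r2s, spec.alpha, spec.power_ref)
        rows.append(dict(scheme=scheme, snr=float(snr), variance_inflation=lam,
                         r2_scheme=r2s,
                         power_at_n=power_at_n(spec.n_ref, r2s, spec.alpha),
                         n_for_target_power=n_req, n_unrounded=n_exact))

    n_sig, n_sig_exact = _sample_size(r2_signal, spec.alpha, spec.power_ref)
    rows.append(dict(scheme="signal", snr=np.inf, variance_inflation=1.0,
                     r2_scheme=r2_signal,
                     power_at_n=power_at_n(spec.n_ref, r2_signal, spec.alpha),
                     n_for_target_power=n_sig, n_unrounded=n_sig_exact))
    for m, snr in zip(decomposition.methods, decomposition.snr):
        add_row(m, snr)
    for ws in weighted_specs:
        add_row("+".join(ws.methods), ws.combined_snr)
    out = pd.DataFrame(rows)
    out.insert(1, "r2_signal", r2_signal)
    out.insert(2, "beta_per_allele", beta)
    return out
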