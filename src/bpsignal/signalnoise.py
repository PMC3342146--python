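"""Signal/noise variance decomposition and minimum-variance weighted averages.

Under the same-signal measurement model, every pairwise covariance between
two methods' (pretreatment-adjusted) responses is an unbiased estimate of
the shared signal variance, so the signal is estimated as the mean of the
six pairwise covariances of the N x 4 response matrix.  Each method's noise
is its total variance minus the signal; the signal-to-noise ratio (SNR) is
their quotient.  A negative noise estimate (possible when a method's
variance falls below the mean covariance) is reported with a flag and an
undefined SNR rather than clipped, since silent truncation would bias the
downstream power analysis.

The minimum-variance unit-sum combination of a subset of methods has
weights proportional to the row sums of the inverse of the subset's
covariance matrix; for uncorrelated noises this reduces to the classical
precision weights (weight proportional to 1/noise variance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InsufficientDataError, SingularMatrixError, ValidationError
from .prep import ResponsePanel
from .simulate import METHODS


@dataclass
class SignalNoiseDecomposition:
    """Signal variance, per-method noise and SNR for one (drug, endpoint)."""

    drug: str
    endpoint: str
    methods: tuple[str, ...]
    cov_matrix: np.ndarray          # mmHg^2
    signal_var: float               # mmHg^2
    noise_vars: np.ndarray          # mmHg^2
    snr: np.ndarray                 # dimensionless; NaN where noise <= 0
    n_subjects: int
    negative_noise: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "endpoint": self.endpoint,
            "methods": list(self.methods),
            "cov_matrix": self.cov_matrix.tolist(),
            "signal_var": float(self.signal_var),
            "noise_vars": self.noise_vars.tolist(),
            "snr": [None if not np.isfinite(s) else float(s) for s in self.snr],
            "n_subjects": int(self.n_subjects),
            "negative_noise": list(self.negative_noise),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SignalNoiseDecomposition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            drug=d["drug"], endpoint=d["endpoint"], methods=tuple(d["methods"]),
            cov_matrix=np.asarray(d["cov_matrix"], dtype=float),
            signal_var=d["signal_var"],
            noise_vars=np.asarray(d["noise_vars"], dtype=float),
            snr=np.asarray([np.nan if s is None else s for s in d["snr"]], dtype=float),
            n_subjects=d["n_subjects"],
            negative_noise=tuple(d["negative_noise"]),
        )


@dataclass
class WeightedAverageSpec:
    """Unit-sum weights over a subset of methods and the combination's variance."""

    methods: tuple[str, ...]
    weights: np.ndarray
    combined_var: float
    combined_noise: float
    combined_snr: float  # NaN when combined_noise <= 0


def decompose_covariance(cov: np.ndarray) -> tuple[float, np.ndarray]:
    """Signal (mean off-diagonal covariance) and per-method noise from a covariance."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    iu = np.triu_indices(k, 1)
    signal = float(np.mean(cov[iu]))
    noise = np.diag(cov) - signal
    return signal, noise


class SignalNoiseEstimator(BaseEstimator):
    """Estimate the shared-signal / method-noise decomposition from responses.

    ``fit(X)`` with ``X`` the complete N x k matrix of (pretreatment-
    adjusted) responses computes the sample covariance (denominator n-1)
    and the decomposition. Fitted attributes: ``covariance_``,
    ``signal_var_``, ``noise_vars_``, ``snr_``, ``negative_noise_``,
    ``n_subjects_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValidationError("X must be an N x k matrix with k >= 2 methods")
        if not np.isfinite(X).all():
            raise ValidationError("responses contain non-finite entries")
        n = X.shape[0]
        if n < 5:
            raise InsufficientDataError(f"need at least 5 subjects, got {n}")
        self.covariance_ = np.cov(X, rowvar=False, ddof=1)
        self.signal_var_, self.noise_vars_ = decompose_covariance(self.covariance_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.snr_ = np.where(self.noise_vars_ > 0,
                                 self.signal_var_ / self.noise_vars_, np.nan)
        self.negative_noise_ = tuple(np.flatnonzero(self.noise_vars_ <= 0).tolist())
        self.n_subjects_ = n
        return self


def estimate_signal_noise(panel: ResponsePanel) -> SignalNoiseDecomposition:
    """Decompose a panel's adjusted responses into signal and noise."""
    est = SignalNoiseEstimator().fit(panel.values(adjusted=True))
    return SignalNoiseDecomposition(
        drug=panel.drug, endpoint=panel.endpoint, methods=panel.methods,
        cov_matrix=est.covariance_,
        signal_var=est.signal_var_,
        noise_vars=est.noise_vars_,
        snr=est.snr_,
        n_subjects=est.n_subjects_,
        negative_noise=tuple(panel.methods[i] for i in est.negative_noise_),
    )


def min_variance_weights(cov_matrix: np.ndarray,
                         method_subset: Sequence[str] | Sequence[int],
                         signal_var: float,
                         methods: Sequence[str] = METHODS) -> WeightedAverageSpec:
    """Minimum-variance unit-sum weights over a subset of methods.

    Weights are the row sums of the inverted covariance submatrix,
    normalized to sum to 1 (the normalization leaves the combination's SNR
    unchanged and keeps the weighted response an unbiased signal estimate).
    ``combined_noise`` and ``combined_snr`` use the supplied full-panel
    ``signal_var``.
    """
    cov_matrix = np.asarray(cov_matrix, dtype=float)
    methods = list(methods)
    idx = [methods.index(m) if isinstance(m, str) else int(m) for m in method_subset]
    labels = tuple(methods[i] for i in idx)
    if len(idx) == 0:
        raise ValidationError("method_subset must be non-empty")
    if len(set(idx)) != len(idx):
        raise ValidationError(f"method_subset has duplicates: {labels}")
    sub = cov_matrix[np.ix_(idx, idx)]
    if len(idx) == 1:
        weights = np.array([1.0])
    else:
        try:
            inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError as exc:
            raise SingularMatrixError(
                f"covariance submatrix for {labels} is singular") from exc
        row_sums = inv.sum(axis=1)
        total = row_sums.sum()
        if total == 0 or not np.isfinite(total):
            raise SingularMatrixError(
                f"covariance submatrix for {labels} yields degenerate weights")
        weights = row_sums / total
    combined_var = float(weights @ sub @ weights)
    combined_noise = combined_var - signal_var
    combined_snr = signal_var / combined_noise if combined_noise > 0 else np.nan
    return WeightedAverageSpec(
        methods=labels, weights=weights,
        combined_var=combined_var,
        combined_noise=float(combined_noise),
        combined_snr=float(combined_snr),
    )


class MinimumVarianceCombiner(BaseEstimator, TransformerMixin):
    """Transformer producing the minimum-variance weighted-average response.

    ``fit(X)`` estimates the full-panel signal/noise decomposition from the
    N x k response matrix and the minimum-variance weights over the chosen
    method subset; ``transform(X)`` returns the per-subject combined
    response as an (N, 1) column. Fitted attributes: ``weights_``,
    ``spec_``, ``decomposition_signal_var_``.
    """

    def __init__(self, methods: Sequence[str] = METHODS, subset: Sequence[str] | None = None):
        self.methods = methods
        self.subset = subset

    def fit(self, X, y=None):
        est = SignalNoiseEstimator().fit(X)
        subset = list(self.subset) if self.subset is not None else list(self.methods)
        self.spec_ = min_variance_weights(est.covariance_, subset,
                                          est.signal_var_, methods=self.methods)
        self.weights_ = self.spec_.weights
        self.decomposition_signal_var_ = est.signal_var_
        self._indices = [list(self.methods).index(m) for m in self.spec_.methods]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self._indices] @ self.weights_)[:, None]


def apply_weighted_average(panel: ResponsePanel, spec: WeightedAverageSpec,
                           adjusted: bool = True) -> np.ndarray:
    """Per-subject weighted-average response for a fitted weight spec."""
    missing = [m for m in spec.methods if m not in panel.methods]
    if missing:
        raise ValidationError(f"panel lacks methods {missing} required by the spec")
    idx = [panel.methods.index(m) for m in spec.methods]
    X = panel.values(adjusted=adjusted)
    return X[:, idx] @ spec.weights


def weights_table(specs: Sequence[WeightedAverageSpec]) -> "pd.DataFrame":
    """Tidy (scheme, method, weight) table mirroring a published weights layout."""
    import pandas as pd

    rows = []
    for spec in specs:
        scheme = "+".join(spec.methods)
        for m, w in zip(spec.methods, spec.weights):
            rows.append({"scheme": scheme, "method": m, "weight": float(w)})
    return pd.DataFrame(rows)
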