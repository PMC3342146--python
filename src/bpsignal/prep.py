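"""Response panels: post-minus-pre BP responses and pretreatment adjustment.

The response to therapy is the post-treatment average minus the
pretreatment average, per method (negative = decline). Because higher
pretreatment BP predicts a larger decline and the downstream predictors
should be independent of the pretreatment level, each method's response is
residualized on its own pretreatment value (simple least squares with
intercept) before any further analysis; the column mean is restored after
residualization so the adjusted response keeps its mmHg location. All
covariance and SNR results are invariant to the mean restoration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DegenerateDesignError, EmptyPanelError, ValidationError
from .simulate import METHODS

logger = logging.getLogger(__name__)


@dataclass
class ResponsePanel:
    """Complete-case N x 4 BP responses for one (drug, endpoint).

    Column order is fixed: office, home, amb_day, amb_night.
    """

    drug: str
    endpoint: str
    subject_ids: np.ndarray
    raw: pd.DataFrame
    pretreat: pd.DataFrame
    adjusted: Optional[pd.DataFrame] = None
    adjustment_slopes: Optional[pd.Series] = None
    n_dropped: int = 0

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.raw.columns)

    def values(self, adjusted: bool = True) -> np.ndarray:
        if adjusted:
            if self.adjusted is None:
                raise ValidationError("panel has no adjusted responses; run adjust_pretreatment")
            return self.adjusted.to_numpy(dtype=float)
        return self.raw.to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject_id, method, raw, adjusted, pretreat."""
        frames = []
        for m in self.methods:
            frames.append(pd.DataFrame({
                "subject_id": self.subject_ids,
                "method": m,
                "raw": self.raw[m].to_numpy(),
                "adjusted": (self.adjusted[m].to_numpy()
                             if self.adjusted is not None else np.nan),
                "pretreat": self.pretreat[m].to_numpy(),
            }))
        return pd.concat(frames, ignore_index=True)

    def write(self, csv_path, sidecar_path=None) -> None:
        self.to_long().to_csv(csv_path, index=False)
        if sidecar_path is not None:
            meta = {
                "drug": self.drug,
                "endpoint": self.endpoint,
                "n_subjects": int(self.n_subjects),
                "n_dropped": int(self.n_dropped),
                "adjustment_slopes": (
                    {k: float(v) for k, v in self.adjustment_slopes.items()}
                    if self.adjustment_slopes is not None else None),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")


def read_panel(csv_path, drug: str, endpoint: str) -> ResponsePanel:
    """Rebuild a panel from its long-format CSV."""
    long = pd.read_csv(csv_path)
    raw = long.pivot(index="subject_id", columns="method", values="raw")[list(METHODS)]
    pre = long.pivot(index="subject_id", columns="method", values="pretreat")[list(METHODS)]
    adj = long.pivot(index="subject_id", columns="method", values="adjusted")[list(METHODS)]
    has_adj = not adj.isna().to_numpy().any()
    return ResponsePanel(
        drug=drug, endpoint=endpoint,
        subject_ids=raw.index.to_numpy(),
        raw=raw.reset_index(drop=True),
        pretreat=pre.reset_index(drop=True),
        adjusted=adj.reset_index(drop=True) if has_adj else None,
    )


def compute_responses(cohort: pd.DataFrame, drug: str, endpoint: str) -> ResponsePanel:
    """Build the raw response panel for one drug arm and endpoint.

    Responses are post minus pre, per method. Subjects with any missing
    method (pre or post) are dropped and counted, since the covariance
    stage needs a complete N x 4 matrix.
    """
    arm = cohort.loc[cohort["arm"] == drug]
    pre_cols = [f"pre_{m}_{endpoint}" for m in METHODS]
    post_cols = [f"post_{m}_{endpoint}" for m in METHODS]
    missing = [c for c in pre_cols + post_cols if c not in arm.columns]
    if missing:
        raise ValidationError(f"cohort lacks columns {missing} for endpoint {endpoint!r}")
    complete = arm[pre_cols + post_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d subjects with incomplete %s measurements", n_dropped, endpoint)
    arm = arm.loc[complete]
    if len(arm) == 0:
        raise EmptyPanelError(f"no complete-case subjects for drug={drug!r}, endpoint={endpoint!r}")
    pre = arm[pre_cols].to_numpy(dtype=float)
    post = arm[post_cols].to_numpy(dtype=float)
    return ResponsePanel(
        drug=drug, endpoint=endpoint,
        subject_ids=arm["subject_id"].to_numpy(),
        raw=pd.DataFrame(post - pre, columns=list(METHODS)),
        pretreat=pd.DataFrame(pre, columns=list(METHODS)),
        n_dropped=n_dropped,
    )


class PretreatmentAdjuster(BaseEstimator):
    """Residualize each method's response on its own pretreatment level.

    ``fit(X, pretreat)`` regresses each response column on the matching
    pretreatment column (simple least squares with intercept);
    ``transform(X, pretreat)`` returns residuals with each column's fitted
    training mean restored. Fitted attributes: ``slopes_``, ``intercepts_``,
    ``means_`` (per column).
    """

    def fit(self, X, pretreat):
        X = np.asarray(X, dtype=float)
        P = np.asarray(pretreat, dtype=float)
        if X.shape != P.shape or X.ndim != 2:
            raise ValidationError("responses and pretreatment must be equal-shape 2-D arrays")
        if not (np.isfinite(X).all() and np.isfinite(P).all()):
            raise ValidationError("responses and pretreatment must be finite")
        n, k = X.shape
        slopes = np.empty(k)
        intercepts = np.empty(k)
        for j in range(k):
            x = P[:, j]
            sxx = np.sum((x - x.mean()) ** 2)
            if sxx == 0.0:
                raise DegenerateDesignError(f"pretreatment column {j} is constant")
            slopes[j] = np.sum((x - x.mean()) * (X[:, j] - X[:, j].mean())) / sxx
            intercepts[j] = X[:, j].mean() - slopes[j] * x.mean()
        self.slopes_ = slopes
        self.intercepts_ = intercepts
        self.means_ = X.mean(axis=0)
        self.n_features_in_ = k
        return self

    def transform(self, X, pretreat):
        X = np.asarray(X, dtype=float)
        P = np.asarray(pretreat, dtype=float)
        fitted = self.intercepts_ + self.slopes_ * P
        return X - fitted + self.means_


def adjust_pretreatment(panel: ResponsePanel) -> ResponsePanel:
    """Return a copy of the panel with adjusted responses and slopes filled."""
    adj = PretreatmentAdjuster().fit(panel.raw.to_numpy(), panel.pretreat.to_numpy())
    adjusted = adj.transform(panel.raw.to_numpy(), panel.pretreat.to_numpy())
    return ResponsePanel(
        drug=panel.drug,
        endpoint=panel.endpoint,
        subject_ids=panel.subject_ids,
        raw=panel.raw,
        pretreat=panel.pretreat,
        adjusted=pd.DataFrame(adjusted, columns=list(panel.methods)),
        adjustment_slopes=pd.Series(adj.slopes_, index=list(panel.methods)),
        n_dropped=panel.n_dropped,
    )
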