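"""End-to-end orchestration: simulate -> prep -> predictors -> signal/noise -> power.

Every stage persists its artifact as comma-delimited text or JSON so each
stage is independently inspectable and re-runnable, and a manifest records
the seed, package version and a content hash of every file, making a run
reproducible byte-for-byte from its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .exceptions import PipelineStageError, ValidationError
from .power import PowerSpec, scheme_power_table
from .predictors import backward_eliminate, same_signal_test
from .prep import ResponsePanel, adjust_pretreatment, compute_responses
from .signalnoise import (SignalNoiseDecomposition, estimate_signal_noise,
                          min_variance_weights, weights_table)
from .simulate import (COVARIATES, DRUGS, ENDPOINTS, METHODS, GeneratorConfig,
                       default_config, generate_study, read_cohort, write_cohort)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "prep", "predictors", "signalnoise", "power")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_per_arm: int = 300
    cohort_file: str | None = None      # analyze an existing cohort instead of simulating
    stages: tuple[str, ...] = ALL_STAGES
    drugs: tuple[str, ...] = DRUGS
    method: str = "home"                # response used by the predictor models
    subsets: tuple[tuple[str, ...], ...] = (METHODS, ("office", "home"))
    maf: float = 0.2
    alpha: float = 5e-8
    n_ref: int = 300
    power_ref: float = 0.8
    generator_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if self.cohort_file is None and "simulate" not in self.stages:
            raise ValidationError("either provide cohort_file or include the simulate stage")
        if self.cohort_file is not None and not Path(self.cohort_file).exists():
            raise ValidationError(f"cohort_file does not exist: {self.cohort_file}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown pipeline config fields: {sorted(unknown)}")
        for key in ("stages", "drugs"):
            if key in d:
                d[key] = tuple(d[key])
        if "subsets" in d:
            d["subsets"] = tuple(tuple(s) for s in d["subsets"])
        return cls(**d)


def summarize_responses(panel: ResponsePanel) -> pd.DataFrame:
    """Per-method mean and SD of the raw responses, with a contrast p-value.

    The contrast tests equality of the four method means via a stacked
    model with method indicators and a cluster-robust (by subject) Wald
    test, mirroring a trial-style response summary.
    """
    raw = panel.values(adjusted=False)
    n, m = raw.shape
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    # stacked contrast: method dummies, subject-clustered sandwich
    y = raw.ravel()
    D = np.tile(np.eye(m)[:, 1:], (n, 1))
    exog = np.column_stack([np.ones(n * m), D])
    groups = np.repeat(np.arange(n), m)
    from .predictors import _cluster_robust_ols
    beta, cov = _cluster_robust_ols(y, exog, groups)
    b = beta[1:]
    V = cov[1:, 1:]
    wald = float(b @ np.linalg.pinv(V) @ b)
    p = float(stats.chi2.sf(wald, m - 1))
    out = pd.DataFrame({
        "method": list(panel.methods),
        "mean_response": means,
        "sd_response": sds,
    })
    out["contrast_p"] = p
    return out


def correlation_range(panel: ResponsePanel) -> tuple[float, float]:
    """Min/max inter-method correlation of adjusted responses (diagnostic)."""
    corr = np.corrcoef(panel.values(adjusted=True), rowvar=False)
    iu = np.triu_indices_from(corr, 1)
    return float(corr[iu].min()), float(corr[iu].max())


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages; returns the manifest dict.

    Artifacts per (drug, endpoint): response panel (long CSV + slopes
    JSON), response summary CSV, predictor-model CSV, same-signal JSON,
    signal/noise JSON + weights CSV, power table CSV; plus cohort CSVs and
    a manifest with the seed, version and per-file SHA-256 hashes.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    files: list[Path] = []
    stage = "setup"
    try:
        # --- simulate / load -------------------------------------------
        stage = "simulate"
        cohorts: dict[str, pd.DataFrame] = {}
        if config.cohort_file is not None:
            cohort = read_cohort(config.cohort_file)
            for drug in config.drugs:
                cohorts[drug] = cohort.loc[cohort["arm"] == drug].reset_index(drop=True)
        else:
            for i, drug in enumerate(config.drugs):
                cfgs = {
                    ep: default_config(drug, ep, n_subjects=config.n_per_arm,
                                       seed=config.seed + 1000 * i,
                                       **config.generator_overrides)
                    for ep in ENDPOINTS
                }
                cohorts[drug] = generate_study(cfgs["systolic"], cfgs["diastolic"])
                path = outdir / f"cohort_{drug}.csv"
                write_cohort(cohorts[drug], path)
                files.append(path)
        for drug, ch in cohorts.items():
            counts[f"subjects_{drug}"] = int(len(ch))
            logger.info("cohort %s: %d subjects", drug, len(ch))

        # --- prep ------------------------------------------------------
        stage = "prep"
        panels: dict[tuple[str, str], ResponsePanel] = {}
        if {"prep", "predictors", "signalnoise", "power"} & set(config.stages):
            for drug in config.drugs:
                for ep in ENDPOINTS:
                    panel = adjust_pretreatment(compute_responses(cohorts[drug], drug, ep))
                    panels[(drug, ep)] = panel
                    counts[f"panel_{drug}_{ep}"] = panel.n_subjects
                    counts[f"dropped_{drug}_{ep}"] = panel.n_dropped
                    p_csv = outdir / f"panel_{drug}_{ep}.csv"
                    p_json = outdir / f"panel_{drug}_{ep}.json"
                    panel.write(p_csv, p_json)
                    files += [p_csv, p_json]
                    summary = summarize_responses(panel)
                    s_csv = outdir / f"response_summary_{drug}_{ep}.csv"
                    summary.to_csv(s_csv, index=False, float_format="%.6g")
                    files.append(s_csv)

        # --- predictors ------------------------------------------------
        if "predictors" in config.stages:
            stage = "predictors"
            for drug in config.drugs:
                cov = (cohorts[drug].set_index("subject_id")
                       .loc[panels[(drug, "systolic")].subject_ids, list(COVARIATES)]
                       .reset_index(drop=True))
                res_s, res_d = backward_eliminate(
                    panels[(drug, "systolic")], panels[(drug, "diastolic")],
                    cov, method=config.method)
                tab = pd.concat({"systolic": res_s.table(), "diastolic": res_d.table()},
                                names=["endpoint", "predictor"])
                tab["r_squared"] = [res_s.r_squared if ep == "systolic" else res_d.r_squared
                                    for ep, _ in tab.index]
                t_csv = outdir / f"predictors_{drug}.csv"
                tab.to_csv(t_csv, float_format="%.6g")
                files.append(t_csv)
                for ep in ENDPOINTS:
                    result = same_signal_test(panels[(drug, ep)], cov)
                    ss_json = outdir / f"same_signal_{drug}_{ep}.json"
                    result.write(ss_json)
                    files.append(ss_json)

        # --- signal/noise ----------------------------------------------
        decomps: dict[tuple[str, str], SignalNoiseDecomposition] = {}
        specs: dict[tuple[str, str], list] = {}
        if {"signalnoise", "power"} & set(config.stages):
            stage = "signalnoise"
            for (drug, ep), panel in panels.items():
                dec = estimate_signal_noise(panel)
                decomps[(drug, ep)] = dec
                specs[(drug, ep)] = [
                    min_variance_weights(dec.cov_matrix, subset, dec.signal_var,
                                         methods=dec.methods)
                    for subset in config.subsets
                ]
                d_json = outdir / f"signalnoise_{drug}_{ep}.json"
                dec.write(d_json)
                files.append(d_json)
                w_csv = outdir / f"weights_{drug}_{ep}.csv"
                weights_table(specs[(drug, ep)]).to_csv(w_csv, index=False,
                                                        float_format="%.6g")
                files.append(w_csv)
                lo, hi = correlation_range(panel)
                logger.info("inter-method correlations %s %s: %.2f-%.2f", drug, ep, lo, hi)

        # --- power -----------------------------------------------------
        if "power" in config.stages:
            stage = "power"
            for (drug, ep), dec in decomps.items():
                pspec = PowerSpec(maf=config.maf, alpha=config.alpha,
                                  n_ref=config.n_ref, power_ref=config.power_ref)
                table = scheme_power_table(dec, specs[(drug, ep)], pspec)
                pw_csv = outdir / f"power_{drug}_{ep}.csv"
                table.to_csv(pw_csv, index=False, float_format="%.8g")
                files.append(pw_csv)
    except ValidationError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "counts": counts,
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(files)
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
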