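import numpy as np
import pandas as pd
import pytest

import bpsignal as bp


@pytest.fixture(scope="session")
def atenolol_systolic_5000():
    """One calibrated atenolol systolic cohort, n=5000, with adjusted panel."""
    cfg = bp.default_config("atenolol", "systolic", n_subjects=5000, seed=11)
    cohort = bp.generate_cohort(cfg)
    panel = bp.adjust_pretreatment(bp.compute_responses(cohort, "atenolol", "systolic"))
    covariates = (cohort.set_index("subject_id")
                  .loc[panel.subject_ids, list(bp.COVARIATES)]
                  .reset_index(drop=True))
    return cfg, cohort, panel, covariates


@pytest.fixture(scope="session")
def atenolol_study_5000():
    """Two-endpoint atenolol study, n=5000, panels and covariates."""
    cfg_s = bp.default_config("atenolol", "systolic", n_subjects=5000, seed=13)
    cfg_d = bp.default_config("atenolol", "diastolic", n_subjects=5000, seed=13)
    cohort = bp.generate_study(cfg_s, cfg_d)
    panels = {ep: bp.adjust_pretreatment(bp.compute_responses(cohort, "atenolol", ep))
              for ep in bp.ENDPOINTS}
    covariates = (cohort.set_index("subject_id")
                  .loc[panels["systolic"].subject_ids, list(bp.COVARIATES)]
                  .reset_index(drop=True))
    return (cfg_s, cfg_d), cohort, panels, covariates


def make_panel(raw, pretreat=None, adjusted=None, drug="atenolol", endpoint="systolic"):
    """Hand-built panel for worked examples; columns follow the method order."""
    raw = pd.DataFrame(np.asarray(raw, dtype=float), columns=list(bp.METHODS))
    n = len(raw)
    if pretreat is None:
        pretreat = np.full((n, 4), 150.0)
    pretreat = pd.DataFrame(np.asarray(pretreat, dtype=float), columns=list(bp.METHODS))
    panel = bp.ResponsePanel(
        drug=drug, endpoint=endpoint, subject_ids=np.arange(n),
        raw=raw, pretreat=pretreat,
    )
    if adjusted is not None:
        panel.adjusted = pd.DataFrame(np.asarray(adjusted, dtype=float),
                                      columns=list(bp.METHODS))
    return panel
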