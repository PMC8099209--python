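import numpy as np
import pandas as pd
import pytest

import adforecast as af
from adforecast.panel import SIGNS


def make_panel_df(scores_by_patient, covariates=None):
    """Small panel frame from {patient: {sign: [scores...]}} dicts.

    Scores may contain None for missing; all six signs default to the given
    series when only one is provided.
    """
    rows = []
    for patient, spec in scores_by_patient.items():
        n = max(len(v) for v in spec.values())
        for t in range(n):
            row = {"patient_id": patient, "day": t + 1}
            for sign in SIGNS:
                series = spec.get(sign, spec.get("all"))
                v = series[t] if series is not None and t < len(series) else None
                row[sign] = np.nan if v is None else v
            if covariates:
                for cov, series in covariates.items():
                    row[cov] = series[t]
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients x 60 days with defaults; shared across read-only tests."""
    cfg = af.GeneratorConfig(n_patients=20, n_days=60, seed=7)
    ds, truth = af.generate_cohort(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def fitted_small_model(small_cohort):
    ds, truth = small_cohort
    pairs = af.extract_transition_pairs(ds, "dryness")
    model = af.fit_sign_model(pairs, af.ModelSpec("dryness"))
    return model, pairs, truth
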