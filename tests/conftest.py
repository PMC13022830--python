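"""Shared fixtures.

`recovery_sims` runs the Monte-Carlo parameter-recovery loop once per
session: 200 independent cohorts from the default generator, each pushed
through the stratified-slope, interaction, tract-screening and path-model
estimators (point estimates only; bootstrap machinery is exercised in
dedicated tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vascsynergy import (SimConfig, fit_adjusted_linear, ground_truth,
                         interaction_model, screen_features, simulate_cohort,
                         standardize)
from vascsynergy.pathmodel import PathSpec, fit_path_stratified
from vascsynergy.pipeline import build_cohort

# covariate set for simulation loops: the moderation default minus Aβ
# positivity (whose mixture cut-off is irrelevant to the generating model)
SIM_COVARIATES = ("age", "sex_male", "education", "hypertension",
                  "diabetes", "icv_ml")

N_RECOVERY_REPS = 200


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One default synthetic cohort, fully built (exclusions, Aβ
    positivity, tertiles, standardization)."""
    raw, _ = simulate_cohort(default_config)
    cohort, meta = build_cohort(raw, seed=0)
    return cohort


@pytest.fixture(scope="session")
def truth(default_config):
    return ground_truth(default_config)


def _one_rep(seed: int, spec: PathSpec) -> dict:
    raw, _ = simulate_cohort(SimConfig(seed=seed))
    df = standardize(raw, ["nfl", "ptau181"])
    rep: dict = {"seed": seed}
    for g in range(3):
        est = fit_adjusted_linear(df[df.csvd_grade == g], "nfl_z",
                                  "ptau181_z", SIM_COVARIATES,
                                  standardized=False)
        rep[f"slope_g{g}"] = est.beta
    im = interaction_model(df, covariates=SIM_COVARIATES)
    rep["interaction_est"] = im.est_interaction
    screen = screen_features(df, "tracts_MD", effect="interaction",
                             covariates=SIM_COVARIATES)
    order = screen.sort_values("p").reset_index(drop=True)
    rep["rank_CCG_L"] = int(order.index[order.label == "CCG_L"][0]) + 1
    rep["rank_CGH_L"] = int(order.index[order.label == "CGH_L"][0]) + 1
    fits = fit_path_stratified(df, spec)
    for g in range(3):
        f = fits[str(g)]
        for q in ("b1", "b4", "ie1", "ie3", "ie", "te", "c_prime"):
            rep[f"{q}_g{g}"] = f.quantity(q)
    return rep


@pytest.fixture(scope="session")
def recovery_sims() -> pd.DataFrame:
    spec = PathSpec()
    return pd.DataFrame([_one_rep(1000 + r, spec)
                         for r in range(N_RECOVERY_REPS)])
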