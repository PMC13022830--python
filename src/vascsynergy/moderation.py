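"""Grade-moderated biomarker regressions.

The p-tau181 × CSVD-burden interaction on NfL, per-grade stratified
effects with BCa bootstrap intervals, and between-grade Δβ contrasts.
The same machinery serves the WMHV-tertile and biomarker-swap variants
(focal = Aβ42, outcome = GFAP) — those differ only in column names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .cohort import standardize
from .stats import (BootstrapCI, EffectEstimate, bca_interval, design_matrix,
                    fit_adjusted_linear, ols_fit)

#: covariate set used by the biomarker moderation models
DEFAULT_COVARIATES = ("age", "sex_male", "education", "hypertension",
                      "diabetes", "icv_ml", "abeta_positive")

ORDINAL = "ordinal_0_1_2"
CATEGORICAL = "categorical_dummies"


@dataclass(frozen=True)
class InteractionResult:
    beta_focal: float
    p_focal: float
    est_interaction: float
    p_interaction: float
    coding: str
    n: int
    interaction_terms: tuple[tuple[str, float, float], ...] = ()

    def to_dict(self) -> dict:
        return {"beta_focal": self.beta_focal, "p_focal": self.p_focal,
                "est_interaction": self.est_interaction,
                "p_interaction": self.p_interaction, "coding": self.coding,
                "n": self.n,
                "interaction_terms": [list(t) for t in self.interaction_terms]}


@dataclass(frozen=True)
class StratumEffect:
    stratum: str
    estimate: EffectEstimate | None
    ci: BootstrapCI | None
    significant: bool | None
    flag: str | None = None


@dataclass(frozen=True)
class GroupContrast:
    """Δ = statistic(g2) − statistic(g1); by convention g2 is the
    higher-burden group, so positive Δβ means a stronger effect there."""

    g1: str
    g2: str
    delta: float
    ci: BootstrapCI
    significant: bool

    def to_dict(self) -> dict:
        return {"g1": self.g1, "g2": self.g2, "delta": self.delta,
                "ci": self.ci.to_dict(), "significant": self.significant}


def _zcols(cohort: pd.DataFrame, outcome: str, focal: str) -> pd.DataFrame:
    """Ensure full-sample standardized copies of outcome and focal exist."""
    need = [v for v in (outcome, focal) if f"{v}_z" not in cohort.columns]
    return standardize(cohort, need) if need else cohort


def interaction_model(cohort: pd.DataFrame, outcome: str = "nfl",
                      focal: str = "ptau181", moderator: str = "csvd_grade",
                      covariates: Sequence[str] = DEFAULT_COVARIATES,
                      coding: str = ORDINAL) -> InteractionResult:
    """OLS of standardized outcome on standardized focal, the moderator
    (ordinal 0/1/2 by default, or dummy-coded), their product(s) and
    covariates."""
    levels = np.sort(pd.unique(cohort[moderator].dropna()))
    if len(levels) < 2:
        raise ConfigurationError(
            f"moderator {moderator!r} has a single level; need >= 2")
    df = _zcols(cohort, outcome, focal)
    cols = [f"{outcome}_z", f"{focal}_z", moderator, *covariates]
    sub = df[cols].dropna()
    y = sub[f"{outcome}_z"].to_numpy(dtype=float)
    x = sub[f"{focal}_z"].to_numpy(dtype=float)
    C = [sub[c].to_numpy(dtype=float) for c in covariates]
    m = sub[moderator].to_numpy(dtype=float)
    if coding == ORDINAL:
        X = np.column_stack([np.ones(len(sub)), x, m, x * m, *C])
        beta, se, pval, _ = ols_fit(X, y)
        terms = ((f"{focal}x{moderator}", float(beta[3]), float(pval[3])),)
        est, p_int = float(beta[3]), float(pval[3])
    elif coding == CATEGORICAL:
        dummies = [(m == lev).astype(float) for lev in levels[1:]]
        prods = [x * d for d in dummies]
        X = np.column_stack([np.ones(len(sub)), x, *dummies, *prods, *C])
        beta, se, pval, _ = ols_fit(X, y)
        k = len(dummies)
        terms = tuple((f"{focal}x{moderator}={lev}", float(beta[2 + k + j]),
                       float(pval[2 + k + j]))
                      for j, lev in enumerate(levels[1:]))
        est, p_int = terms[-1][1], terms[-1][2]
    else:
        raise ConfigurationError(f"unknown moderator coding {coding!r}")
    return InteractionResult(beta_focal=float(beta[1]), p_focal=float(pval[1]),
                             est_interaction=est, p_interaction=p_int,
                             coding=coding, n=len(sub),
                             interaction_terms=terms)


def _slope_statistic(n_cov: int):
    """Statistic over an ndarray with columns [y, x, cov...]: the OLS
    coefficient of x.  Lean on purpose — this runs inside the bootstrap."""
    def stat(arr: np.ndarray) -> float:
        X = np.column_stack([np.ones(len(arr)), arr[:, 1:2 + n_cov]])
        beta, _, _, _ = np.linalg.lstsq(X, arr[:, 0], rcond=None)
        return float(beta[1])
    return stat


def _stratum_array(df: pd.DataFrame, outcome_z: str, focal_z: str,
                   covariates: Sequence[str]) -> np.ndarray:
    return df[[outcome_z, focal_z, *covariates]].dropna().to_numpy(dtype=float)


def stratified_effects(cohort: pd.DataFrame, outcome: str = "nfl",
                       focal: str = "ptau181",
                       stratum_var: str = "csvd_grade",
                       covariates: Sequence[str] = DEFAULT_COVARIATES,
                       B: int = 5000, level: float = 0.90,
                       seed: int = 0) -> list[StratumEffect]:
    """Within-stratum standardized-β fits with BCa intervals.

    Outcome and focal are standardized once over the full sample so the
    per-stratum coefficients share a scale; resampling is within-stratum.
    Strata too small to fit are flagged, not dropped."""
    df = _zcols(cohort, outcome, focal)
    oz, fz = f"{outcome}_z", f"{focal}_z"
    out: list[StratumEffect] = []
    n_params = 2 + len(covariates)
    for lev in np.sort(pd.unique(df[stratum_var].dropna())):
        sub = df[df[stratum_var] == lev]
        name = str(lev)
        if len(sub[[oz, fz, *covariates]].dropna()) <= n_params + 5:
            out.append(StratumEffect(stratum=name, estimate=None, ci=None,
                                     significant=None, flag="too_small"))
            continue
        est = fit_adjusted_linear(sub, oz, fz, covariates,
                                  standardized=False, stratum=name)
        arr = _stratum_array(sub, oz, fz, covariates)
        ci = bca_interval(_slope_statistic(len(covariates)), arr, B=B,
                          level=level,
                          seed=np.random.default_rng([seed, int(lev)]))
        out.append(StratumEffect(stratum=name, estimate=est, ci=ci,
                                 significant=ci.excludes_zero()))
    return out


def contrast_groups(cohort: pd.DataFrame, outcome: str, focal: str,
                    stratum_var: str, g1, g2,
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    B: int = 5000, level: float = 0.90,
                    seed: int = 0) -> GroupContrast:
    """Δβ = β(g2) − β(g1) with a BCa interval.

    Each replicate resamples within g1 and g2 independently and refits
    both models; the jackknife runs over the union of both groups."""
    df = _zcols(cohort, outcome, focal)
    oz, fz = f"{outcome}_z", f"{focal}_z"
    parts, labels = [], []
    for g in (g1, g2):
        sub = df[df[stratum_var] == g]
        arr = _stratum_array(sub, oz, fz, covariates)
        if len(arr) <= 2 + len(covariates) + 5:
            raise ConfigurationError(f"stratum {g!r} too small to contrast")
        parts.append(arr)
        labels.append(np.full(len(arr), len(parts) - 1))
    data = np.column_stack([np.concatenate(parts),
                            np.concatenate(labels)[:, None]])
    slope = _slope_statistic(len(covariates))

    def stat(arr: np.ndarray) -> float:
        grp = arr[:, -1]
        return slope(arr[grp == 1]) - slope(arr[grp == 0])

    ci = bca_interval(stat, data, B=B, level=level, strata=data[:, -1],
                      seed=np.random.default_rng([seed, 1]))
    return GroupContrast(g1=str(g1), g2=str(g2), delta=ci.point, ci=ci,
                         significant=ci.excludes_zero())


def moderation_table(strata_effects: list[StratumEffect],
                     contrasts: list[GroupContrast]) -> pd.DataFrame:
    """Tidy table: one row per stratified estimate or contrast."""
    rows = []
    for s in strata_effects:
        if s.estimate is None:
            rows.append({"kind": "stratum", "stratum": s.stratum,
                         "flag": s.flag})
            continue
        rows.append({"kind": "stratum", "stratum": s.stratum,
                     "beta": s.estimate.beta, "p": s.estimate.p_value,
                     "lo": s.ci.lo, "hi": s.ci.hi, "level": s.ci.level,
                     "B": s.ci.B, "significant": s.significant})
    for c in contrasts:
        rows.append({"kind": "contrast", "stratum": f"{c.g2}-{c.g1}",
                     "beta": c.delta, "lo": c.ci.lo, "hi": c.ci.hi,
                     "level": c.ci.level, "B": c.ci.B,
                     "significant": c.significant})
    return pd.DataFrame(rows)
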