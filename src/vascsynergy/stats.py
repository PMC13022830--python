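"""Shared statistical primitives.

Covariate-adjusted linear models with standardized coefficients,
bias-corrected and accelerated (BCa) bootstrap intervals for arbitrary
statistics with optional stratified resampling, Benjamini–Hochberg FDR,
and residualization for display.

The BCa interval uses the bias-correction term
z0 = Φ⁻¹(#{θ*_b < θ̂}/B) and the jackknife acceleration
a = Σ(θ̄(·) − θ(i))³ / [6·(Σ(θ̄(·) − θ(i))²)^{3/2}], mapping the nominal
percentile points α/2 and 1 − α/2 through
Φ(z0 + (z0 + z_α)/(1 − a(z0 + z_α))).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import ConfigurationError


class DegenerateIntervalError(RuntimeError):
    """All bootstrap replicates identical: no interval can be formed."""


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient."""


# --- containers ------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    """A standardized regression coefficient for one focal predictor."""

    beta: float
    se: float
    p_value: float
    n: int
    outcome: str
    predictor: str
    covariates: tuple[str, ...] = ()
    stratum: str | None = None

    def to_dict(self) -> dict:
        return {"beta": self.beta, "se": self.se, "p_value": self.p_value,
                "n": self.n, "outcome": self.outcome,
                "predictor": self.predictor,
                "covariates": list(self.covariates), "stratum": self.stratum}


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    level: float
    B: int
    z0: float
    a: float
    lo: float
    hi: float
    method: str = "bca"  # "bca" or "percentile"
    n_failed: int = 0
    warnings: tuple[str, ...] = ()

    def excludes_zero(self) -> bool:
        return self.lo > 0.0 or self.hi < 0.0

    def to_dict(self) -> dict:
        return {"point": self.point, "level": self.level, "B": self.B,
                "z0": self.z0, "a": self.a, "lo": self.lo, "hi": self.hi,
                "method": self.method, "n_failed": self.n_failed,
                "warnings": list(self.warnings)}


@dataclass(frozen=True)
class FdrResult:
    p_values: np.ndarray
    q_values: np.ndarray
    family: str
    family_size: int


# --- linear modelling ------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if not sd > 0:
        raise ConfigurationError("zero-variance variable cannot be standardized")
    return (x - np.mean(x)) / sd


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.sum(resid**2) < 1e-10 * max(1.0, np.sum(X[:, j] ** 2)):
                bad.append(names[j])
        raise RankDeficientError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}")


def design_matrix(data: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Intercept + the given columns as a float design matrix."""
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(dtype=float) for c in columns])
    return X


def ols_fit(X: np.ndarray, y: np.ndarray):
    """Plain least squares: coefficients, standard errors, two-sided
    t-distribution p-values, residuals."""
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2.0 * sps.t.sf(np.abs(tval), dof)
    return beta, se, pval, resid


def fit_adjusted_linear(data: pd.DataFrame, outcome: str, focal: str,
                        covariates: Sequence[str] = (),
                        standardized: bool = True,
                        stratum: str | None = None) -> EffectEstimate:
    """OLS of `outcome` on `focal` plus covariates.

    When `standardized`, outcome and focal are z-scored over the rows of
    `data` (pass pre-standardized ``*_z`` columns with
    ``standardized=False`` to keep a common full-sample scale across
    strata); covariates enter on their native scale.
    """
    cols = [outcome, focal, *covariates]
    sub = data[cols].dropna()
    n = len(sub)
    if n < len(cols) + 2:
        raise ConfigurationError(
            f"too few complete cases ({n}) for {len(cols)} model columns")
    y = sub[outcome].to_numpy(dtype=float)
    x = sub[focal].to_numpy(dtype=float)
    if standardized:
        y, x = _zscore(y), _zscore(x)
    X = np.column_stack([np.ones(n), x]
                        + [sub[c].to_numpy(dtype=float) for c in covariates])
    _check_rank(X, ["intercept", focal, *covariates])
    beta, se, pval, _ = ols_fit(X, y)
    return EffectEstimate(beta=float(beta[1]), se=float(se[1]),
                          p_value=float(pval[1]), n=n, outcome=outcome,
                          predictor=focal, covariates=tuple(covariates),
                          stratum=stratum)


def multi_ols(X: np.ndarray, Y: np.ndarray):
    """One design, many outcomes: per-outcome coefficients, SEs and
    two-sided p-values (vectorized across the columns of Y)."""
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)                       # p × m
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof          # m
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # p × m
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    pval = 2.0 * sps.t.sf(np.abs(tval), dof)
    return beta, se, pval


def residualize(data: pd.DataFrame, outcome: str,
                covariates: Sequence[str] = ()) -> np.ndarray:
    """Outcome minus its OLS prediction from the covariates alone
    (centered outcome when no covariates are given)."""
    sub = data[[outcome, *covariates]].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub))]
                        + [sub[c].to_numpy(dtype=float) for c in covariates])
    _check_rank(X, ["intercept", *covariates])
    beta, _, _, resid = ols_fit(X, y)
    return resid


# --- BCa bootstrap ---------------------------------------------------------

def _take(data, idx):
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    return np.asarray(data)[idx]


def _strata_indices(data, strata) -> list[np.ndarray]:
    s = np.asarray(strata)
    return [np.nonzero(s == lev)[0] for lev in pd.unique(s)]


def bca_from_replicates(point: float, replicates: np.ndarray,
                        jackknife: np.ndarray, level: float,
                        n_failed: int = 0) -> BootstrapCI:
    """BCa interval from precomputed bootstrap replicates and delete-one
    jackknife values (the resampling loop lives in :func:`bca_interval`)."""
    reps = np.asarray(replicates, dtype=float)
    B = len(reps)
    warnings: list[str] = []
    if np.allclose(reps, reps[0]):
        raise DegenerateIntervalError(
            "all bootstrap replicates identical; zero bootstrap variance")
    prop = float(np.mean(reps < point))
    if prop <= 0.0 or prop >= 1.0:
        prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1))
        warnings.append("bias-correction proportion clipped")
    z0 = float(sps.norm.ppf(prop))
    d = np.mean(jackknife) - np.asarray(jackknife, dtype=float)
    denom = float(np.sum(d**2) ** 1.5)
    alpha = np.array([(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    if denom == 0.0:
        warnings.append("jackknife degenerate; percentile fallback")
        lo, hi = np.quantile(reps, alpha)
        return BootstrapCI(point=float(point), level=level, B=B, z0=z0,
                           a=0.0, lo=float(lo), hi=float(hi),
                           method="percentile", n_failed=n_failed,
                           warnings=tuple(warnings))
    a = float(np.sum(d**3) / (6.0 * denom))
    zalpha = sps.norm.ppf(alpha)
    with np.errstate(divide="ignore"):
        adj = sps.norm.cdf(z0 + (z0 + zalpha) / (1.0 - a * (z0 + zalpha)))
    adj = np.clip(adj, 0.0, 1.0)
    lo, hi = np.quantile(reps, adj)
    return BootstrapCI(point=float(point), level=level, B=B, z0=z0, a=a,
                       lo=float(lo), hi=float(hi), method="bca",
                       n_failed=n_failed, warnings=tuple(warnings))


def bca_interval(statistic: Callable, data, B: int = 5000,
                 level: float = 0.90, strata=None,
                 seed: int | np.random.Generator = 0) -> BootstrapCI:
    """BCa bootstrap interval for ``statistic(data)``.

    Rows are resampled with replacement — independently within each level
    of `strata` when given.  Replicates where the statistic raises or
    returns a non-finite value are rejected and redrawn (at most ``2B``
    draws in total).  The acceleration uses a delete-one jackknife over
    all rows, strata preserved implicitly by row identity.
    """
    if B < 200:
        raise ConfigurationError("B must be at least 200 for BCa intervals")
    if level not in (0.90, 0.95):
        raise ConfigurationError("level must be 0.90 or 0.95")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(data)
    point = float(statistic(data))
    if not np.isfinite(point):
        raise ConfigurationError("statistic is not finite on the full data")

    groups = ([np.arange(n)] if strata is None
              else _strata_indices(data, strata))

    reps = np.empty(B)
    got, drawn, failed = 0, 0, 0
    while got < B:
        if drawn >= 2 * B:
            raise RuntimeError(
                f"too many failed bootstrap replicates ({failed} of {drawn})")
        idx = np.concatenate([g[rng.integers(0, len(g), len(g))]
                              for g in groups])
        drawn += 1
        try:
            val = float(statistic(_take(data, idx)))
        except Exception:
            failed += 1
            continue
        if not np.isfinite(val):
            failed += 1
            continue
        reps[got] = val
        got += 1

    jack = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = float(statistic(_take(data, np.delete(all_idx, i))))
    return bca_from_replicates(point, reps, jack, level, n_failed=failed)


# --- multiple testing ------------------------------------------------------

def bh_fdr(p_values: Iterable[float], family: str = "") -> FdrResult:
    """Benjamini–Hochberg step-up q-values; NaN p-values propagate as NaN."""
    p = np.asarray(list(p_values), dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum() > 0:
        _, qv, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = qv
    return FdrResult(p_values=p, q_values=q, family=family,
                     family_size=int(ok.sum()))
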