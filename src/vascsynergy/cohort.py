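"""Cohort construction: CSVD burden scoring and grading, exclusion
filtering, Gaussian-mixture biomarker positivity cut-off, WMHV tertiles
and variable standardization.

The total CSVD burden score counts four binary MRI features (lacunes,
microbleeds, severe basal-ganglia enlarged perivascular spaces, severe
white-matter hyperintensities), each contributing one point, and maps to
three grades: none (0), mild (1), moderate-to-severe (≥ 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ConfigurationError


class ValidationError(ValueError):
    """Raised when input data violate the cohort schema."""


class CSVDGrade(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


@dataclass(frozen=True)
class CSVDBurden:
    total_score: int
    grade: CSVDGrade


_GRADE_BY_SCORE = {0: CSVDGrade.NONE, 1: CSVDGrade.MILD}


def compute_csvd_burden(features: Sequence[int],
                        participant: str | None = None) -> CSVDBurden:
    """Total CSVD score (0–4) and burden grade from four binary features."""
    who = f" for participant {participant}" if participant else ""
    if len(features) != 4:
        raise ValidationError(f"expected 4 CSVD features{who}, got {len(features)}")
    vals = []
    for f in features:
        if f is None or (isinstance(f, float) and np.isnan(f)) or int(f) not in (0, 1):
            raise ValidationError(f"non-binary or missing CSVD feature{who}: {f!r}")
        vals.append(int(f))
    score = sum(vals)
    grade = _GRADE_BY_SCORE.get(score, CSVDGrade.MODERATE_SEVERE)
    return CSVDBurden(total_score=score, grade=grade)


def grade_from_score(score: int) -> CSVDGrade:
    if score < 0 or score > 4:
        raise ValidationError(f"CSVD score must lie in 0..4, got {score}")
    return _GRADE_BY_SCORE.get(int(score), CSVDGrade.MODERATE_SEVERE)


# --- exclusions ------------------------------------------------------------

@dataclass
class ExclusionLog:
    """Per-rule removal counts; rules are applied as one conjunctive pass,
    each removed row attributed to the first rule it violates."""

    input_n: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    remaining_n: int = 0

    def to_dict(self) -> dict:
        return {"input_n": self.input_n, "removed": dict(self.removed),
                "remaining_n": self.remaining_n}


def apply_exclusions(cohort: pd.DataFrame,
                     nfl_threshold: float = 179.0,
                     nfl_column: str = "nfl",
                     require_complete: Iterable[str] = (),
                     ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove rows with NfL strictly above `nfl_threshold` (pg/ml) or with
    missing values in `require_complete`; row order is preserved."""
    if nfl_threshold <= 0:
        raise ConfigurationError("nfl_threshold must be positive")
    log = ExclusionLog(input_n=len(cohort))
    drop = pd.Series(False, index=cohort.index)
    if nfl_column in cohort.columns:
        hit = cohort[nfl_column] > nfl_threshold
        log.removed["nfl_above_threshold"] = int(hit.sum())
        drop |= hit
    for col in require_complete:
        if col not in cohort.columns:
            raise ValidationError(f"required column {col!r} absent from cohort")
        hit = cohort[col].isna() & ~drop
        log.removed[f"missing_{col}"] = int(hit.sum())
        drop |= hit
    out = cohort.loc[~drop].copy()
    log.remaining_n = len(out)
    return out, log


# --- Gaussian-mixture biomarker cut-off ------------------------------------

@dataclass(frozen=True)
class MixtureCutoff:
    """Two-component Gaussian mixture fit with the equal-posterior
    cut-off between the component means."""

    cutoff: float
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    positivity_side: str  # "at_or_above" or "below"
    converged: bool
    loglik: float
    n_iter: int

    def classify(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.cutoff if self.positivity_side == "at_or_above"
                else v < self.cutoff).astype(int)

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "means": list(self.means),
                "sds": list(self.sds), "weights": list(self.weights),
                "positivity_side": self.positivity_side,
                "converged": self.converged, "loglik": self.loglik,
                "n_iter": self.n_iter}


def _em_univariate_2gmm(x: np.ndarray, mu: np.ndarray, sd: np.ndarray,
                        w: np.ndarray, tol: float, max_iter: int,
                        var_floor: float):
    """EM for a univariate two-component Gaussian mixture.

    Returns (mu, sd, w, loglik_trace, converged).  The log-likelihood is
    asserted non-decreasing (up to round-off) at every iteration.
    """
    trace = []
    converged = False
    for _ in range(max_iter):
        logpdf = norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        ll = float(lse.sum())
        if trace:
            assert ll >= trace[-1] - 1e-8 * abs(trace[-1]) - 1e-10, \
                "EM log-likelihood decreased"
            if abs(ll - trace[-1]) <= tol * (abs(trace[-1]) + 1.0):
                trace.append(ll)
                converged = True
                break
        trace.append(ll)
        resp = np.exp(logpdf - lse[:, None])
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, var_floor))
    return mu, sd, w, trace, converged


def _equal_posterior_cutoff(mu, sd, w) -> float:
    """Point between the component means where posterior responsibilities
    are equal, i.e. w1·φ1(x) = w2·φ2(x), solved on a fine grid + bisection."""
    from scipy.optimize import brentq
    lo, hi = sorted(mu)
    if np.isclose(lo, hi):
        return float(lo)

    def diff(x):
        return (np.log(w[0]) + norm.logpdf(x, mu[0], sd[0])
                - np.log(w[1]) - norm.logpdf(x, mu[1], sd[1]))

    grid = np.linspace(lo, hi, 512)
    vals = diff(grid)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        # no interior crossing (extreme weight imbalance): midpoint fallback
        return float((lo + hi) / 2.0)
    i = idx[0]
    return float(brentq(diff, grid[i], grid[i + 1]))


def fit_abeta_cutoff(values: np.ndarray,
                     n_components: int = 2,
                     restarts: int = 10,
                     tol: float = 1e-8,
                     max_iter: int = 500,
                     seed: int = 0,
                     positivity_side: str = "at_or_above",
                     ) -> MixtureCutoff:
    """Fit a two-component Gaussian mixture to biomarker concentrations and
    derive the equal-posterior positivity cut-off.

    EM with k-means-style initialization, best of `restarts` runs by
    log-likelihood, variance floor 1e-4 × data variance.
    """
    if n_components != 2:
        raise ConfigurationError("only two-component mixtures are supported")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20 or np.any(x <= 0):
        raise ValidationError(
            "need at least 20 finite positive biomarker values")
    rng = np.random.default_rng(seed)
    var_floor = 1e-4 * float(np.var(x))
    best = None
    for r in range(restarts):
        if r == 0:
            # k-means-style split at the median
            med = np.median(x)
            mu = np.array([x[x <= med].mean(), x[x > med].mean()])
        else:
            mu = np.sort(rng.choice(x, size=2, replace=False))
        sd = np.full(2, max(np.std(x) / 2.0, np.sqrt(var_floor)))
        w = np.array([0.5, 0.5])
        mu, sd, w, trace, conv = _em_univariate_2gmm(
            x, mu.astype(float), sd, w, tol, max_iter, var_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (mu, sd, w, trace, conv)
    mu, sd, w, trace, conv = best
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    cutoff = _equal_posterior_cutoff(mu, sd, w)
    return MixtureCutoff(cutoff=cutoff, means=(float(mu[0]), float(mu[1])),
                         sds=(float(sd[0]), float(sd[1])),
                         weights=(float(w[0]), float(w[1])),
                         positivity_side=positivity_side,
                         converged=bool(conv), loglik=float(trace[-1]),
                         n_iter=len(trace))


# --- WMHV tertiles ---------------------------------------------------------

TERTILE_LABELS = ("low", "mid", "high")


def assign_tertiles(values: np.ndarray) -> np.ndarray:
    """Rank-based thirds of WMH volume; sizes differ by at most one, with
    remainders allocated to the lowest tertile(s); ties broken by stable
    input order."""
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValidationError("WMHV values must be finite and non-negative")
    if len(np.unique(v)) < 3:
        raise ValidationError("need at least 3 distinct values for tertiles")
    n = len(v)
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for lab, size in zip(TERTILE_LABELS, sizes):
        labels[order[start:start + size]] = lab
        start += size
    return labels


# --- standardization -------------------------------------------------------

def standardize(cohort: pd.DataFrame, variables: Iterable[str],
                scope: str = "full_sample",
                stratum_var: str | None = None) -> pd.DataFrame:
    """Append z-scored copies (``<var>_z``) of the given variables.

    ``scope='full_sample'`` uses one mean/SD for everyone (stratified
    coefficients stay on a common scale); ``scope='within_stratum'``
    standardizes inside each level of `stratum_var`.  SDs use the n−1
    denominator.  Original columns are preserved.
    """
    if scope not in ("full_sample", "within_stratum"):
        raise ConfigurationError(f"unknown standardization scope {scope!r}")
    out = cohort.copy()
    for var in variables:
        x = out[var].astype(float)
        if scope == "full_sample":
            sd = x.std(ddof=1)
            if not sd > 0:
                raise ValidationError(f"zero variance in variable {var!r}")
            out[f"{var}_z"] = (x - x.mean()) / sd
        else:
            if stratum_var is None:
                raise ConfigurationError(
                    "within_stratum scope requires stratum_var")
            def z(s):
                sd = s.std(ddof=1)
                if not sd > 0:
                    raise ValidationError(
                        f"zero variance in variable {var!r} within a stratum")
                return (s - s.mean()) / sd
            out[f"{var}_z"] = out.groupby(stratum_var)[var].transform(z)
    out.attrs["standardization_scope"] = scope
    return out
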