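"""Recursive three-equation path model with indirect-effect decomposition.

The model links plasma p-tau181 (exposure) to cognition through plasma
NfL and a white-matter imaging marker:

    NfL     = b1·ptau                       (+ covariates)
    imaging = b2·NfL + b4·ptau              (+ covariates)
    cog     = b3·imaging + b5·NfL + c′·ptau (+ covariates)

Indirect effects: IE1 = b1·b2·b3 (chain through both mediators),
IE2 = b1·b5 (through NfL), IE3 = b3·b4 (through the imaging marker);
IE = IE1 + IE2 + IE3 and TE = c′ + IE.  For a recursive system with
uncorrelated errors, equation-by-equation least squares coincides with
full-information maximum likelihood, so each equation is fitted by OLS
on standardized role variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .cohort import standardize
from .stats import BootstrapCI, bca_from_replicates, ols_fit

#: covariate presets: the analysis text names age/sex/education; the
#: figure annotation lists the fuller vascular set.  Default: methods_text.
COVARIATE_PRESETS = {
    "methods_text": ("age", "sex_male", "education"),
    "figure_legend": ("age", "sex_male", "education", "hypertension",
                      "diabetes", "icv_ml", "abeta_positive"),
}

QUANTITIES = ("b1", "b2", "b3", "b4", "b5", "c_prime",
              "ie1", "ie2", "ie3", "ie", "te")


@dataclass(frozen=True)
class PathSpec:
    exposure: str = "ptau181"
    mediator1: str = "nfl"
    mediator2: str = "CCG_L_MD"
    outcome: str = "MMSE"
    covariates: tuple[str, ...] = COVARIATE_PRESETS["methods_text"]

    def roles(self) -> tuple[str, str, str, str]:
        r = (self.exposure, self.mediator1, self.mediator2, self.outcome)
        if len(set(r)) != 4:
            raise ConfigurationError("path roles must be four distinct variables")
        return r


@dataclass(frozen=True)
class PathFit:
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    c_prime: float
    ie1: float
    ie2: float
    ie3: float
    ie: float
    te: float
    n: int
    stratum: str | None = None

    def quantity(self, name: str) -> float:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {q: getattr(self, q) for q in QUANTITIES} | {
            "n": self.n, "stratum": self.stratum}


@dataclass(frozen=True)
class PathContrast:
    quantity: str
    g1: str
    g2: str
    delta: float
    ci: BootstrapCI
    significant: bool
    ci_secondary: BootstrapCI | None = None

    def to_dict(self) -> dict:
        d = {"quantity": self.quantity, "g1": self.g1, "g2": self.g2,
             "delta": self.delta, "ci": self.ci.to_dict(),
             "significant": self.significant}
        if self.ci_secondary is not None:
            d["ci_secondary"] = self.ci_secondary.to_dict()
        return d


def _path_coefficients(arr: np.ndarray, n_cov: int) -> np.ndarray:
    """Six path coefficients from an ndarray with columns
    [ptau, nfl, imaging, cog, cov...]; three sequential OLS fits."""
    n = len(arr)
    ones = np.ones((n, 1))
    cov = arr[:, 4:4 + n_cov]
    ptau, nfl, img, cog = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    b1 = np.linalg.lstsq(np.hstack([ones, ptau[:, None], cov]), nfl,
                         rcond=None)[0][1]
    eq2 = np.linalg.lstsq(np.hstack([ones, nfl[:, None], ptau[:, None], cov]),
                          img, rcond=None)[0]
    b2, b4 = eq2[1], eq2[2]
    eq3 = np.linalg.lstsq(
        np.hstack([ones, img[:, None], nfl[:, None], ptau[:, None], cov]),
        cog, rcond=None)[0]
    b3, b5, cp = eq3[1], eq3[2], eq3[3]
    return np.array([b1, b2, b3, b4, b5, cp])


def _derive(coefs: np.ndarray) -> np.ndarray:
    """[b1..b5, c'] -> full quantity vector in QUANTITIES order."""
    b1, b2, b3, b4, b5, cp = coefs
    ie1, ie2, ie3 = b1 * b2 * b3, b1 * b5, b3 * b4
    ie = ie1 + ie2 + ie3
    return np.array([b1, b2, b3, b4, b5, cp, ie1, ie2, ie3, ie, cp + ie])


def _role_array(df: pd.DataFrame, spec: PathSpec) -> np.ndarray:
    exp, m1, m2, out = spec.roles()
    cols = [f"{v}_z" for v in (exp, m1, m2, out)] + list(spec.covariates)
    return df[cols].dropna().to_numpy(dtype=float)


def fit_path(data: pd.DataFrame, spec: PathSpec,
             standardized: bool = True,
             stratum: str | None = None) -> PathFit:
    """Fit the three path equations on standardized role variables.

    With ``standardized=True`` the four roles are z-scored over the rows
    of `data`; with ``standardized=False`` pre-standardized ``*_z``
    columns must already be present (a common full-sample scale across
    strata).  The identity TE = c′ + IE1 + IE2 + IE3 holds exactly by
    construction and is asserted on every fit.
    """
    df = standardize(data, spec.roles()) if standardized else data
    arr = _role_array(df, spec)
    if len(arr) < 30:
        raise ConfigurationError(
            f"path model needs >= 30 complete cases, got {len(arr)}")
    q = _derive(_path_coefficients(arr, len(spec.covariates)))
    fit = PathFit(*(float(v) for v in q), n=len(arr), stratum=stratum)
    assert abs(fit.te - (fit.c_prime + fit.ie1 + fit.ie2 + fit.ie3)) < 1e-12
    return fit


def fit_path_stratified(cohort: pd.DataFrame, spec: PathSpec,
                        stratum_var: str = "csvd_grade",
                        ) -> dict[str, PathFit]:
    """Per-stratum path fits on a common full-sample standardization."""
    df = standardize(cohort, spec.roles())
    out: dict[str, PathFit] = {}
    for lev in np.sort(pd.unique(df[stratum_var].dropna())):
        sub = df[df[stratum_var] == lev]
        out[str(lev)] = fit_path(sub, spec, standardized=False,
                                 stratum=str(lev))
    return out


def contrast_path(cohort: pd.DataFrame, spec: PathSpec, g1, g2,
                  quantities: Sequence[str] = QUANTITIES,
                  stratum_var: str = "csvd_grade",
                  B: int = 5000, level: float = 0.90, seed: int = 0,
                  secondary_level: float | None = None,
                  ) -> list[PathContrast]:
    """Between-stratum differences Δ = quantity(g2) − quantity(g1) for path
    coefficients and indirect effects, each with a BCa interval.

    Every bootstrap replicate resamples rows independently within each
    stratum (the groups are disjoint participants), refits both path
    models and records all quantity differences; the jackknife for the
    acceleration deletes one row of the union at a time.
    """
    unknown = [q for q in quantities if q not in QUANTITIES]
    if unknown:
        raise ConfigurationError(f"unknown path quantities: {unknown}")
    df = standardize(cohort, spec.roles())
    n_cov = len(spec.covariates)
    arrs = []
    for g in (g1, g2):
        arr = _role_array(df[df[stratum_var] == g], spec)
        if len(arr) < 30:
            raise ConfigurationError(f"stratum {g!r} too small for path model")
        arrs.append(arr)
    n1, n2 = len(arrs[0]), len(arrs[1])
    data = np.vstack(arrs)

    def deltas(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        return (_derive(_path_coefficients(a2, n_cov))
                - _derive(_path_coefficients(a1, n_cov)))

    point = deltas(arrs[0], arrs[1])
    rng = np.random.default_rng([int(seed) % (2**31), 2])
    reps = np.empty((B, len(QUANTITIES)))
    got, drawn = 0, 0
    while got < B:
        if drawn >= 2 * B:
            raise RuntimeError("too many failed bootstrap replicates")
        drawn += 1
        i1 = rng.integers(0, n1, n1)
        i2 = rng.integers(0, n2, n2)
        try:
            val = deltas(arrs[0][i1], arrs[1][i2])
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(val)):
            continue
        reps[got] = val
        got += 1

    jack = np.empty((n1 + n2, len(QUANTITIES)))
    for i in range(n1 + n2):
        if i < n1:
            jack[i] = deltas(np.delete(arrs[0], i, axis=0), arrs[1])
        else:
            jack[i] = deltas(arrs[0], np.delete(arrs[1], i - n1, axis=0))

    out = []
    for q in quantities:
        j = QUANTITIES.index(q)
        ci = bca_from_replicates(float(point[j]), reps[:, j], jack[:, j],
                                 level, n_failed=drawn - got)
        ci2 = (bca_from_replicates(float(point[j]), reps[:, j], jack[:, j],
                                   secondary_level)
               if secondary_level is not None else None)
        out.append(PathContrast(quantity=q, g1=str(g1), g2=str(g2),
                                delta=float(point[j]), ci=ci,
                                significant=ci.excludes_zero(),
                                ci_secondary=ci2))
    return out
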