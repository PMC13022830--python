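"""Mass-univariate screening of p-tau181 effects over imaging features.

One interaction (or main-effect) regression per family member — 48 white
matter tracts per DTI metric, or 124 grey-matter regions — with
Benjamini–Hochberg FDR applied within each (family × effect) set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._labels import GM_FAST_REGIONS, GM_FIRST_REGIONS, JHU_TRACTS
from .config import ConfigurationError
from .cohort import standardize
from .stats import bh_fdr, multi_ols

#: covariate set used for the imaging screens (ICV included for volumes)
DEFAULT_COVARIATES = ("age", "sex_male", "education", "hypertension",
                      "diabetes", "icv_ml", "abeta_positive")


@dataclass(frozen=True)
class FeatureFamily:
    name: str
    members: tuple[str, ...]   # cohort column names
    labels: tuple[str, ...]    # display labels
    units: str

    def __post_init__(self):
        if len(self.members) != len(self.labels):
            raise ConfigurationError("members and labels must align")


_FAMILY_SIZES = {"tracts_FA": 48, "tracts_MD": 48, "tracts_MO": 48,
                 "gm_regions": 124, "gm_first": 14}


def feature_family(name: str) -> FeatureFamily:
    """Construct one of the analysis feature families by name."""
    if name.startswith("tracts_"):
        metric = name.split("_", 1)[1]
        if metric not in ("FA", "MD", "MO"):
            raise ConfigurationError(f"unknown family {name!r}")
        units = {"FA": "unitless", "MD": "1e-3 mm^2/s", "MO": "unitless"}[metric]
        return FeatureFamily(name=name,
                             members=tuple(f"{t}_{metric}" for t in JHU_TRACTS),
                             labels=JHU_TRACTS, units=units)
    if name == "gm_regions":
        regions = GM_FAST_REGIONS + GM_FIRST_REGIONS
        return FeatureFamily(name=name,
                             members=tuple(f"{r}_ml" for r in regions),
                             labels=regions, units="ml")
    if name == "gm_first":
        return FeatureFamily(name=name,
                             members=tuple(f"{r}_ml" for r in GM_FIRST_REGIONS),
                             labels=GM_FIRST_REGIONS, units="ml")
    raise ConfigurationError(f"unknown family {name!r}")


def screen_features(cohort: pd.DataFrame, family: FeatureFamily | str,
                    effect: str = "interaction",
                    focal: str = "ptau181", moderator: str = "csvd_grade",
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Feature-wise standardized regressions with family-wise BH-FDR.

    Every member is z-scored and regressed on standardized `focal`, the
    ordinal moderator, their product and the covariates; `effect` selects
    whether the focal main effect or the interaction term is screened.
    Returns a table (label, beta, p, q, significant) sorted by q then
    label.
    """
    if effect not in ("main", "interaction"):
        raise ConfigurationError(f"effect must be 'main' or 'interaction'")
    fam = feature_family(family) if isinstance(family, str) else family
    missing = [m for m in fam.members if m not in cohort.columns]
    if missing:
        raise ConfigurationError(
            f"family {fam.name!r} members absent from cohort: {missing}")
    df = cohort if f"{focal}_z" in cohort.columns else standardize(cohort, [focal])
    cols = [f"{focal}_z", moderator, *covariates, *fam.members]
    sub = df[cols].dropna()
    x = sub[f"{focal}_z"].to_numpy(dtype=float)
    m = sub[moderator].to_numpy(dtype=float)
    C = [sub[c].to_numpy(dtype=float) for c in covariates]
    X = np.column_stack([np.ones(len(sub)), x, m, x * m, *C])
    Y = sub[list(fam.members)].to_numpy(dtype=float)
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    beta, se, pval = multi_ols(X, Y)
    row = 1 if effect == "main" else 3
    fdr = bh_fdr(pval[row], family=f"{fam.name}_{effect}")
    out = pd.DataFrame({"label": fam.labels, "beta": beta[row],
                        "p": pval[row], "q": fdr.q_values})
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["q", "label"], kind="stable").reset_index(drop=True)


def head_size_adjust(volumes: pd.DataFrame | np.ndarray,
                     scaling_factor: np.ndarray):
    """Scale native-space volumes by the per-participant head-size factor.

    Returns the adjusted volumes with ``attrs['head_size_adjusted']`` set
    (when a DataFrame) so downstream models can drop ICV from the
    covariates for pre-scaled volumes."""
    f = np.asarray(scaling_factor, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ConfigurationError("scaling factors must be finite and positive")
    if isinstance(volumes, pd.DataFrame):
        out = volumes.mul(f, axis=0)
        out.attrs["head_size_adjusted"] = True
        return out
    return np.asarray(volumes, dtype=float) * f[:, None] if np.ndim(volumes) == 2 \
        else np.asarray(volumes, dtype=float) * f
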