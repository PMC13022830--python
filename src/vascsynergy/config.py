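"""Simulation and pipeline configuration.

``SimConfig`` holds every parameter of the synthetic cohort generator:
cohort composition (three CSVD burden grades), per-grade covariate
distributions, log-normal plasma biomarker parameters, the grade-specific
standardized slopes of NfL on p-tau181, planted tract-level effects, and
the per-grade path-model coefficients that generate cognition.

``GroundTruth`` exposes the realized generating parameters — including the
derived conditional p-tau → imaging path coefficient b4 and the implied
indirect/total effects — so recovery tests can compare estimates against
truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

N_GRADES = 3
GRADE_NAMES = ("none", "mild", "moderate_severe")


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


def _tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != N_GRADES:
        raise ConfigurationError(f"expected 3 per-grade values, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class CovariateDistributions:
    """Per-grade covariate moments and prevalences (grades 0, I, II)."""

    age_mean: tuple[float, ...] = (65.73, 67.06, 73.06)
    age_sd: tuple[float, ...] = (8.74, 9.24, 7.92)
    education_mean: tuple[float, ...] = (11.88, 11.35, 10.66)
    education_sd: tuple[float, ...] = (4.74, 4.40, 4.64)
    icv_mean: tuple[float, ...] = (2664.73, 2640.76, 2594.77)   # ml
    icv_sd: tuple[float, ...] = (268.09, 262.91, 267.74)
    wmhv_mean: tuple[float, ...] = (6.04, 8.41, 19.20)          # ml, right-skewed
    wmhv_sd: tuple[float, ...] = (6.96, 9.43, 19.03)
    male_prev: tuple[float, ...] = (0.34, 0.36, 0.49)
    hypertension_prev: tuple[float, ...] = (0.28, 0.28, 0.54)
    diabetes_prev: tuple[float, ...] = (0.10, 0.097, 0.26)

    def validate(self) -> None:
        for name in ("age_sd", "education_sd", "icv_sd", "wmhv_sd"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ConfigurationError(f"{name} must be positive")
        for name in ("male_prev", "hypertension_prev", "diabetes_prev"):
            if any(not 0.0 <= v <= 1.0 for v in getattr(self, name)):
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class BiomarkerParams:
    """Log-normal biomarker distributions, parameterized by per-grade
    arithmetic mean/SD on the measured pg/ml scale.

    NfL is not listed here: it is generated by the structural model
    (grade-specific slope on standardized p-tau181 plus covariates and
    noise) with per-grade means and a common within-grade SD.
    """

    ptau181_mean: tuple[float, ...] = (2.47, 2.41, 2.86)
    ptau181_sd: tuple[float, ...] = (1.76, 1.57, 1.79)
    abeta42_mean: tuple[float, ...] = (6.61, 6.48, 6.33)
    abeta42_sd: tuple[float, ...] = (1.95, 1.78, 2.13)
    abeta40_mean: tuple[float, ...] = (70.20, 77.02, 84.50)
    abeta40_sd: tuple[float, ...] = (44.30, 40.59, 44.28)
    gfap_mean: tuple[float, ...] = (104.09, 112.51, 118.32)
    gfap_sd: tuple[float, ...] = (67.80, 93.11, 91.02)
    nfl_mean: tuple[float, ...] = (17.72, 16.58, 23.17)
    nfl_sd: float = 15.74  # common within-grade SD, keeps slopes on scale

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x <= 0 for x in vals):
                raise ConfigurationError(f"{f.name} must be positive")


@dataclass(frozen=True)
class TractEffect:
    """Marginal standardized effects of p-tau181 on one tract metric:
    ``main`` at grade 0 plus ``interaction`` per burden-grade step."""

    main: float = 0.0
    interaction: float = 0.0


@dataclass(frozen=True)
class PathParams:
    """Per-grade generating path coefficients (standardized scale).

    b1 (p-tau → NfL) is taken from ``SimConfig.ptau_nfl_slopes``.  b4
    (p-tau → imaging, conditional on NfL) is derived from the mediator
    tract's marginal effect: b4_g = marginal_g − b2_g · b1_g, so the
    mass-univariate marginal interaction and the path-model contrast are
    generated by one coherent process.
    """

    b2: tuple[float, ...] = (0.18, 0.18, 0.18)      # NfL → imaging
    b3: tuple[float, ...] = (-0.05, -0.08, -0.12)   # imaging → cognition
    b5: tuple[float, ...] = (-0.05, -0.05, -0.21)   # NfL → cognition
    c_prime: tuple[float, ...] = (-0.02, -0.25, -0.12)  # p-tau → cognition

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _tuple3(getattr(self, f.name))


def _default_tract_effects() -> dict[str, TractEffect]:
    # Interactions planted only in the two left cingulum MD members;
    # a few further main effects echo the marginal p-tau associations.
    return {
        "CCG_L_MD": TractEffect(main=0.02, interaction=0.16),
        "CGH_L_MD": TractEffect(main=0.02, interaction=0.15),
        "FX_ST_L_MD": TractEffect(main=0.17),
        "FX_ST_R_MD": TractEffect(main=0.17),
        "FX_ST_L_FA": TractEffect(main=-0.15),
        "FX_ST_R_FA": TractEffect(main=-0.15),
        "PTR_L_MD": TractEffect(main=0.15),
        "PTR_R_MD": TractEffect(main=0.15),
    }


def _default_gm_effects() -> dict[str, float]:
    # Modest main effects on medial temporal volumes; none survive FDR
    # at the default sample size, mirroring a weak grey-matter signal.
    return {
        "Hippocampus_L_ml": -0.21,
        "Hippocampus_R_ml": -0.21,
        "Amygdala_L_ml": -0.16,
        "Amygdala_R_ml": -0.17,
        "FIRST_Hippocampus_R_ml": -0.23,
        "FIRST_Hippocampus_L_ml": -0.21,
    }


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort."""

    group_sizes: tuple[int, ...] = (144, 103, 128)
    csvd2_score_split: tuple[int, ...] = (70, 41, 17)  # scores 2 / 3 / 4
    covariate_distributions: CovariateDistributions = field(
        default_factory=CovariateDistributions)
    biomarker_params: BiomarkerParams = field(default_factory=BiomarkerParams)
    ptau_nfl_slopes: tuple[float, ...] = (0.06, 0.08, 0.30)
    tract_effects: dict[str, TractEffect] = field(
        default_factory=_default_tract_effects)
    gm_effects: dict[str, float] = field(default_factory=_default_gm_effects)
    path_params: PathParams = field(default_factory=PathParams)
    mediator_tract: str = "CCG_L_MD"
    # residual SDs on the standardized/latent scale
    noise_sd_nfl: float = 1.0
    noise_sd_tract: float = 1.0
    noise_sd_cognition: float = 1.0
    covariate_effect_age_nfl: float = 0.15
    covariate_effect_age_tract: float = 0.20
    covariate_effect_edu_cognition: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) != N_GRADES or any(n < 0 for n in self.group_sizes):
            raise ConfigurationError("group_sizes must be 3 non-negative counts")
        if len(self.csvd2_score_split) != 3 or any(n < 0 for n in self.csvd2_score_split):
            raise ConfigurationError("csvd2_score_split must be 3 non-negative counts")
        if sum(self.csvd2_score_split) != self.group_sizes[2]:
            raise ConfigurationError(
                "csvd2_score_split must sum to the grade-II group size "
                f"({sum(self.csvd2_score_split)} != {self.group_sizes[2]})")
        _tuple3(self.ptau_nfl_slopes)
        for name in ("noise_sd_nfl", "noise_sd_tract", "noise_sd_cognition"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        self.covariate_distributions.validate()
        self.biomarker_params.validate()
        self.path_params.validate()
        if self.mediator_tract not in self.tract_effects:
            raise ConfigurationError(
                f"mediator tract {self.mediator_tract!r} has no tract_effects entry")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tract_effects"] = {k: dataclasses.asdict(v)
                              for k, v in self.tract_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "covariate_distributions" in d:
            d["covariate_distributions"] = CovariateDistributions(
                **{k: tuple(v) for k, v in d["covariate_distributions"].items()})
        if "biomarker_params" in d:
            bp = dict(d["biomarker_params"])
            bp = {k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                  for k, v in bp.items()}
            d["biomarker_params"] = BiomarkerParams(**bp)
        if "path_params" in d:
            d["path_params"] = PathParams(
                **{k: tuple(v) for k, v in d["path_params"].items()})
        if "tract_effects" in d:
            d["tract_effects"] = {k: TractEffect(**v)
                                  for k, v in d["tract_effects"].items()}
        for k in ("group_sizes", "csvd2_score_split", "ptau_nfl_slopes"):
            if k in d:
                d[k] = tuple(d[k])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_yaml(cls, s: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(s) or {})

    def hash(self) -> str:
        """Stable short hash identifying the configuration."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass(frozen=True)
class GroundTruth:
    """Realized generating parameters and the implied mediation effects."""

    b1: tuple[float, ...]
    b2: tuple[float, ...]
    b3: tuple[float, ...]
    b4: tuple[float, ...]
    b5: tuple[float, ...]
    c_prime: tuple[float, ...]
    tract_effects: dict[str, TractEffect]
    ie1: tuple[float, ...] = ()
    ie2: tuple[float, ...] = ()
    ie3: tuple[float, ...] = ()
    ie: tuple[float, ...] = ()
    te: tuple[float, ...] = ()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tract_effects"] = {k: dataclasses.asdict(v)
                              for k, v in self.tract_effects.items()}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GroundTruth":
        d = dict(d)
        d["tract_effects"] = {k: TractEffect(**v)
                              for k, v in d["tract_effects"].items()}
        for k in ("b1", "b2", "b3", "b4", "b5", "c_prime",
                  "ie1", "ie2", "ie3", "ie", "te"):
            d[k] = tuple(d[k])
        return cls(**d)


def ground_truth(config: SimConfig) -> GroundTruth:
    """Exact generating parameters and derived IE/TE; seed-independent.

    b4_g = marginal_g − b2_g · b1_g with marginal_g = main + interaction·g
    for the mediator tract; IE1 = b1·b2·b3, IE2 = b1·b5, IE3 = b3·b4,
    IE = IE1 + IE2 + IE3, TE = c′ + IE (exact by construction).
    """
    config.validate()
    b1 = config.ptau_nfl_slopes
    pp = config.path_params
    med = config.tract_effects[config.mediator_tract]
    marginal = tuple(med.main + med.interaction * g for g in range(N_GRADES))
    b4 = tuple(marginal[g] - pp.b2[g] * b1[g] for g in range(N_GRADES))
    ie1 = tuple(b1[g] * pp.b2[g] * pp.b3[g] for g in range(N_GRADES))
    ie2 = tuple(b1[g] * pp.b5[g] for g in range(N_GRADES))
    ie3 = tuple(pp.b3[g] * b4[g] for g in range(N_GRADES))
    ie = tuple(ie1[g] + ie2[g] + ie3[g] for g in range(N_GRADES))
    te = tuple(pp.c_prime[g] + ie[g] for g in range(N_GRADES))
    return GroundTruth(b1=b1, b2=pp.b2, b3=pp.b3, b4=b4, b5=pp.b5,
                       c_prime=pp.c_prime, tract_effects=dict(config.tract_effects),
                       ie1=ie1, ie2=ie2, ie3=ie3, ie=ie, te=te)
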