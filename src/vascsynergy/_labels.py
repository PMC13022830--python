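"""Label lists for the imaging feature families.

White-matter tracts follow the 48-label JHU ICBM-DTI-81 atlas convention
(midline structures unsuffixed, lateralized structures with ``_L``/``_R``).
Grey-matter labels are a synthetic stand-in for a 110-region tissue-type
parcellation (96 bilateral cortical + 14 subcortical) plus the 14
subcortical structures of a model-based segmentation; the counts match the
families used in the analyses (48 tracts, 110 + 14 = 124 regions).
"""

from __future__ import annotations

# 48 JHU ICBM-DTI-81 white-matter tract labels.
JHU_TRACTS: tuple[str, ...] = (
    "MCP",      # middle cerebellar peduncle
    "PCT",      # pontine crossing tract
    "GCC",      # genu of corpus callosum
    "BCC",      # body of corpus callosum
    "SCC",      # splenium of corpus callosum
    "FX",       # fornix (column and body)
    "CST_R", "CST_L",      # corticospinal tract
    "ML_R", "ML_L",        # medial lemniscus
    "ICP_R", "ICP_L",      # inferior cerebellar peduncle
    "SCP_R", "SCP_L",      # superior cerebellar peduncle
    "CP_R", "CP_L",        # cerebral peduncle
    "ALIC_R", "ALIC_L",    # anterior limb of internal capsule
    "PLIC_R", "PLIC_L",    # posterior limb of internal capsule
    "RLIC_R", "RLIC_L",    # retrolenticular part of internal capsule
    "ACR_R", "ACR_L",      # anterior corona radiata
    "SCR_R", "SCR_L",      # superior corona radiata
    "PCR_R", "PCR_L",      # posterior corona radiata
    "PTR_R", "PTR_L",      # posterior thalamic radiation
    "SS_R", "SS_L",        # sagittal stratum
    "EC_R", "EC_L",        # external capsule
    "CCG_R", "CCG_L",      # cingulum (cingulate gyrus part)
    "CGH_R", "CGH_L",      # cingulum (hippocampal part)
    "FX_ST_R", "FX_ST_L",  # fornix (cres) / stria terminalis
    "SLF_R", "SLF_L",      # superior longitudinal fasciculus
    "SFO_R", "SFO_L",      # superior fronto-occipital fasciculus
    "UNC_R", "UNC_L",      # uncinate fasciculus
    "TAP_R", "TAP_L",      # tapetum
)

assert len(JHU_TRACTS) == 48

DTI_METRICS: tuple[str, ...] = ("FA", "MD", "MO")

_CORTICAL_48: tuple[str, ...] = (
    "FrontalPole", "InsularCortex", "SuperiorFrontalGyrus", "MiddleFrontalGyrus",
    "InferiorFrontalGyrusParsTriangularis", "InferiorFrontalGyrusParsOpercularis",
    "PrecentralGyrus", "TemporalPole", "SuperiorTemporalGyrusAnterior",
    "SuperiorTemporalGyrusPosterior", "MiddleTemporalGyrusAnterior",
    "MiddleTemporalGyrusPosterior", "MiddleTemporalGyrusTemporooccipital",
    "InferiorTemporalGyrusAnterior", "InferiorTemporalGyrusPosterior",
    "InferiorTemporalGyrusTemporooccipital", "PostcentralGyrus",
    "SuperiorParietalLobule", "SupramarginalGyrusAnterior",
    "SupramarginalGyrusPosterior", "AngularGyrus", "LateralOccipitalCortexSuperior",
    "LateralOccipitalCortexInferior", "IntracalcarineCortex", "FrontalMedialCortex",
    "JuxtapositionalLobuleCortex", "SubcallosalCortex", "ParacingulateGyrus",
    "CingulateGyrusAnterior", "CingulateGyrusPosterior", "PrecuneousCortex",
    "CunealCortex", "FrontalOrbitalCortex", "ParahippocampalGyrusAnterior",
    "ParahippocampalGyrusPosterior", "LingualGyrus", "TemporalFusiformCortexAnterior",
    "TemporalFusiformCortexPosterior", "TemporalOccipitalFusiformCortex",
    "OccipitalFusiformGyrus", "FrontalOperculumCortex", "CentralOpercularCortex",
    "ParietalOperculumCortex", "PlanumPolare", "HeschlsGyrus", "PlanumTemporale",
    "SupracalcarineCortex", "OccipitalPole",
)

_SUBCORTICAL_7: tuple[str, ...] = (
    "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens",
)

# 110 tissue-type-segmentation regions: 96 bilateral cortical + 14 subcortical.
GM_FAST_REGIONS: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _CORTICAL_48 for side in ("L", "R")
) + tuple(f"{name}_{side}" for name in _SUBCORTICAL_7 for side in ("L", "R"))

# 14 model-based subcortical segmentations.
GM_FIRST_REGIONS: tuple[str, ...] = tuple(
    f"FIRST_{name}_{side}" for name in _SUBCORTICAL_7 for side in ("L", "R")
)

assert len(GM_FAST_REGIONS) == 110
assert len(GM_FIRST_REGIONS) == 14


def tract_columns(metric: str) -> list[str]:
    """Column names for one DTI metric over all 48 tracts, e.g. ``CCG_L_MD``."""
    if metric not in DTI_METRICS:
        raise ValueError(f"unknown DTI metric {metric!r}; expected one of {DTI_METRICS}")
    return [f"{t}_{metric}" for t in JHU_TRACTS]


def gm_columns() -> list[str]:
    """Column names for all 124 grey-matter region volumes (ml)."""
    return [f"{r}_ml" for r in GM_FAST_REGIONS + GM_FIRST_REGIONS]
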