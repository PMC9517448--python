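"""Catalog of the study's path-model topologies and effect utilities.

The catalog covers eight cancer x sex strata (gastric, lung and
colorectal by sex; breast and cervical in women only), each in two
stages: the pre-analysis hypothesis model (both latent factors acting on
the screening rate, all six resource indicators) and the final model
actually reported, whose topology is transcribed from the published path
diagrams.  Models are shipped as plain-text mini-syntax files and parsed
on demand.

The module also carries the published standardized solution per stratum
(used as ground truth by the synthetic generator) and the published fit
statistics per stratum (chi-square, df, and the index battery), plus
standardized total-effect and effect-ratio utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import linalg

from .sem import FitResult, ModelError, ModelSpec, ParameterSet, parse_model

__all__ = [
    "STRATA",
    "StudyModelKey",
    "available_keys",
    "model_text",
    "load_model",
    "initial_model",
    "final_model",
    "STANDARDIZED_ESTIMATES",
    "PUBLISHED_FIT_STATISTICS",
    "total_effect",
    "total_effect_from_params",
    "effect_ratio",
]

#: the eight analyzed strata, in reporting order
STRATA: tuple[tuple[str, str], ...] = (
    ("gastric", "male"),
    ("gastric", "female"),
    ("lung", "male"),
    ("lung", "female"),
    ("colorectal", "male"),
    ("colorectal", "female"),
    ("breast", "female"),
    ("cervical", "female"),
)

_STAGES = ("initial", "final")


@dataclass(frozen=True)
class StudyModelKey:
    cancer: str
    sex: str
    stage: str

    def __post_init__(self) -> None:
        if (self.cancer, self.sex) not in STRATA:
            raise ModelError(
                f"unknown stratum {self.cancer!r} x {self.sex!r}; "
                f"known: {sorted(STRATA)}"
            )
        if self.stage not in _STAGES:
            raise ModelError(f"stage must be one of {_STAGES}, got {self.stage!r}")

    @property
    def name(self) -> str:
        return f"{self.cancer}_{self.sex}_{self.stage}"

    @classmethod
    def from_name(cls, name: str) -> "StudyModelKey":
        parts = name.split("_")
        if len(parts) != 3:
            raise ModelError(
                f"model key {name!r} is not of the form cancer_sex_stage"
            )
        return cls(*parts)


def available_keys() -> list[str]:
    return [
        f"{cancer}_{sex}_{stage}"
        for cancer, sex in STRATA
        for stage in _STAGES
    ]


def model_text(key: StudyModelKey | str) -> str:
    """Raw mini-syntax text of a catalog model."""
    name = key if isinstance(key, str) else key.name
    if name not in available_keys():
        raise ModelError(
            f"unknown model key {name!r}; available: {available_keys()}"
        )
    ref = resources.files("screensem").joinpath("models").joinpath(f"{name}.txt")
    return ref.read_text(encoding="utf-8")


def load_model(key: StudyModelKey | str) -> ModelSpec:
    return parse_model(model_text(key))


def initial_model(key: StudyModelKey) -> ModelSpec:
    if key.stage != "initial":
        raise ModelError(f"{key.name} is not an initial-stage key")
    return load_model(key)


def final_model(key: StudyModelKey) -> ModelSpec:
    if key.stage != "final":
        raise ModelError(f"{key.name} is not a final-stage key")
    return load_model(key)


# --------------------------------------------------------------------------
# published standardized solutions (final models, per stratum)
# --------------------------------------------------------------------------

#: standardized loadings and path coefficients of the reported final
#: models; keys are (cancer, sex).  Loadings keyed (latent, indicator),
#: paths keyed (outcome, predictor).
STANDARDIZED_ESTIMATES: dict[tuple[str, str], dict] = {
    ("gastric", "male"): {
        "loadings": {
            ("resources", "phns"): 0.88,
            ("resources", "public_health_expense"): 0.62,
            ("resources", "general_revenue"): 0.87,
            ("interventions", "recall"): 0.80,
            ("interventions", "call"): 0.55,
            ("interventions", "upper_limit"): -0.90,
        },
        "paths": {
            ("rate", "interventions"): 0.53,
            ("rate", "household_income"): 0.27,
            ("interventions", "resources"): 0.62,
            ("resources", "aging_rate"): 0.73,
        },
    },
    ("gastric", "female"): {
        "loadings": {
            ("resources", "phns"): 0.79,
            ("resources", "public_health_expense"): 0.72,
            ("resources", "general_revenue"): 0.96,
            ("interventions", "recall"): 0.66,
            ("interventions", "call"): 0.35,
            ("interventions", "upper_limit"): -0.77,
        },
        "paths": {
            ("rate", "interventions"): 0.60,
            ("rate", "household_income"): 0.34,
            ("interventions", "resources"): 0.67,
            ("resources", "aging_rate"): 0.82,
        },
    },
    ("lung", "male"): {
        "loadings": {
            ("resources", "phns"): 0.82,
            ("resources", "public_health_expense"): 0.68,
            ("resources", "general_revenue"): 0.91,
            ("interventions", "recall"): 0.60,
            ("interventions", "call"): 0.80,
            ("interventions", "charge_free"): 0.38,
        },
        "paths": {
            ("rate", "interventions"): 0.81,
            ("rate", "aging_rate"): -0.31,
            ("interventions", "resources"): 0.48,
            ("resources", "aging_rate"): 0.75,
        },
    },
    ("lung", "female"): {
        "loadings": {
            ("resources", "phns"): 0.78,
            ("resources", "public_health_expense"): 0.67,
            ("resources", "general_revenue"): 0.94,
            ("interventions", "recall"): 0.59,
            ("interventions", "call"): 0.80,
            ("interventions", "charge_free"): 0.41,
        },
        "paths": {
            ("rate", "interventions"): 0.69,
            ("rate", "household_income"): 0.24,
            ("interventions", "resources"): 0.41,
            ("resources", "aging_rate"): 0.84,
        },
    },
    ("colorectal", "male"): {
        "loadings": {
            ("resources", "phns"): 0.80,
            ("resources", "public_health_expense"): 0.73,
            ("resources", "general_revenue"): 0.95,
            ("interventions", "recall"): 0.74,
            ("interventions", "call"): 0.73,
        },
        "paths": {
            ("rate", "resources"): 0.58,
            ("rate", "household_income"): 0.51,
            ("rate", "aging_rate"): -0.40,
            ("interventions", "resources"): 0.48,
            ("resources", "aging_rate"): 0.74,
        },
    },
    ("colorectal", "female"): {
        "loadings": {
            ("resources", "phns"): 0.79,
            ("resources", "public_health_expense"): 0.72,
            ("resources", "general_revenue"): 0.97,
            ("interventions", "recall"): 0.74,
            ("interventions", "call"): 0.74,
        },
        "paths": {
            ("rate", "household_income"): 0.41,
            ("interventions", "resources"): 0.434,
            ("resources", "aging_rate"): 0.821,
        },
    },
    ("breast", "female"): {
        "loadings": {
            ("resources", "phns"): 0.80,
            ("resources", "public_health_expense"): 0.72,
            ("resources", "general_revenue"): 0.95,
            ("interventions", "recall"): 0.60,
            ("interventions", "call"): 0.54,
            ("interventions", "upper_limit"): -0.47,
        },
        "paths": {
            ("rate", "interventions"): 1.14,
            ("rate", "household_income"): 0.38,
            ("rate", "aging_rate"): -0.70,
            ("interventions", "resources"): 0.78,
            ("resources", "aging_rate"): 0.83,
        },
    },
    ("cervical", "female"): {
        "loadings": {
            ("resources", "phns"): 0.83,
            ("resources", "public_health_expense"): 0.67,
            ("resources", "general_revenue"): 0.91,
            ("interventions", "recall"): 0.53,
            ("interventions", "call"): 0.61,
            ("interventions", "upper_limit"): -0.43,
        },
        "paths": {
            ("rate", "interventions"): 1.23,
            ("rate", "aging_rate"): -0.93,
            ("interventions", "resources"): 0.77,
            ("resources", "aging_rate"): 0.85,
        },
    },
}

#: fit statistics printed alongside the final path diagrams (the diagram
#: captions are internally consistent with chi-square, df and n = 47 and
#: are treated as authoritative where the summary table disagrees)
PUBLISHED_FIT_STATISTICS: dict[tuple[str, str], dict[str, float]] = {
    ("gastric", "male"): dict(
        chi_square=28.66, df=22, p_value=0.155, gfi=0.872, agfi=0.738,
        pgfi=0.426, srmr=0.09, cfi=0.96, rmsea=0.080),
    ("gastric", "female"): dict(
        chi_square=29.82, df=22, p_value=0.123, gfi=0.892, agfi=0.780,
        pgfi=0.436, srmr=0.083, cfi=0.96, rmsea=0.087),
    ("lung", "male"): dict(
        chi_square=13.77, df=17, p_value=0.683, gfi=0.943, agfi=0.878,
        pgfi=0.445, srmr=0.070, cfi=1.00, rmsea=0.000),
    ("lung", "female"): dict(
        chi_square=34.438, df=24, p_value=0.077, gfi=0.887, agfi=0.789,
        pgfi=0.473, srmr=0.093, cfi=0.94, rmsea=0.096),
    ("colorectal", "male"): dict(
        chi_square=29.362, df=16, p_value=0.022, gfi=0.874, agfi=0.717,
        pgfi=0.388, srmr=0.108, cfi=0.911, rmsea=0.133),
    ("colorectal", "female"): dict(
        chi_square=35.111, df=18, p_value=0.009, gfi=0.876, agfi=0.753,
        pgfi=0.438, srmr=0.110, cfi=0.898, rmsea=0.142),
    ("breast", "female"): dict(
        chi_square=30.03, df=21, p_value=0.091, gfi=0.930, agfi=0.850,
        pgfi=0.434, srmr=0.080, cfi=0.954, rmsea=0.096),
    ("cervical", "female"): dict(
        chi_square=34.798, df=15, p_value=0.003, gfi=0.909, agfi=0.782,
        pgfi=0.379, srmr=0.095, cfi=0.896, rmsea=0.168),
}


# --------------------------------------------------------------------------
# effect decomposition
# --------------------------------------------------------------------------


def _standardized_coefficient_matrix(
    spec: ModelSpec, params: ParameterSet
) -> tuple[np.ndarray, dict[str, int]]:
    idx = {v: i for i, v in enumerate(spec.all_vars)}
    t = len(spec.all_vars)
    A = np.zeros((t, t))
    for latent, indicators in spec.latents:
        for ind in indicators:
            A[idx[ind], idx[latent]] = params.loadings[(latent, ind)]
    for outcome, predictor in spec.regressions:
        A[idx[outcome], idx[predictor]] = params.paths[(outcome, predictor)]
    return A, idx


def total_effect_from_params(
    spec: ModelSpec, params: ParameterSet, source: str, target: str
) -> float:
    """Sum over all directed paths source -> ... -> target of the product
    of (standardized) coefficients along each path: the (target, source)
    entry of (I - A)^-1 - I.  Zero when no path exists."""
    if source not in spec.all_vars or target not in spec.all_vars:
        raise ModelError(f"unknown variable in ({source!r}, {target!r})")
    A, idx = _standardized_coefficient_matrix(spec, params)
    t = A.shape[0]
    total = linalg.solve(np.eye(t) - A, np.eye(t)) - np.eye(t)
    return float(total[idx[target], idx[source]])


def total_effect(result: FitResult, source: str, target: str) -> float:
    """Standardized total effect (direct plus all indirect paths) from a
    fitted model."""
    return total_effect_from_params(result.spec, result.standardized, source, target)


def _lookup_standardized(result: FitResult, path: tuple[str, str]) -> float:
    outcome, predictor = path
    if (outcome, predictor) in result.standardized.paths:
        return result.standardized.paths[(outcome, predictor)]
    if (outcome, predictor) in result.standardized.loadings:
        return result.standardized.loadings[(outcome, predictor)]
    raise ModelError(f"no coefficient {outcome!r} <- {predictor!r} in the model")


def effect_ratio(
    result: FitResult, path_a: tuple[str, str], path_b: tuple[str, str]
) -> float:
    """Ratio of two standardized coefficients, e.g. the intervention
    effect on the screening rate relative to the income effect."""
    a = _lookup_standardized(result, path_a)
    b = _lookup_standardized(result, path_b)
    if b == 0:
        raise ModelError(f"coefficient {path_b} is zero: ratio undefined")
    return a / b
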