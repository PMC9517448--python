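"""Synthetic prefecture tables with the statistical structure the
analysis assumes.

The study's raw inputs are open administrative statistics that are not
redistributed here; this module generates stand-in tables whose latent
structure is known exactly, so every pipeline stage can be exercised and
its recovery quantified.  Generation proceeds in three layers:

1. *Latent layer* — multivariate-normal scores drawn from the implied
   covariance of a path model at chosen standardized coefficients
   (defaults: the published final-model solutions).
2. *Placement layer* — each score is mapped onto a realistic raw scale
   through a monotone inverse Box-Cox placement anchored at the published
   per-variable medians and interquartile ranges, inducing the right
   skew that the preprocessing stage must undo.  Percentage variables
   with mass near 100 use the complementary ("headroom") placement so the
   [0, 100] support is respected without hard truncation.
3. *Count layer* — an eligible population is drawn per prefecture and
   screening participants are sampled binomially at the placed rate, so
   the screening-rate arithmetic runs on genuine counts.

Variables listed as degenerate are replaced by near-point-mass draws to
emulate intervention indicators adopted (or not) almost everywhere —
these must be caught and excluded by the normality screen.

A single seed is expanded into one substream per variable, so adding a
variable to the schema never perturbs previously generated columns.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special

from .data_model import (
    FEMALE_ONLY_CANCERS,
    MODEL_VARIABLES,
    PrefectureRecord,
    RegionTable,
)
from .sem import (
    ModelError,
    ModelSpec,
    ParameterSet,
    fit,
    implied_covariance,
    param_names,
    standardized_standard_errors,
)
from .study_models import STANDARDIZED_ESTIMATES, load_model

__all__ = [
    "SimulationConfig",
    "standardized_truth",
    "default_config",
    "simulate_scores",
    "simulate_table",
    "recovery_experiment",
    "DEFAULT_RESIDUAL_CORRELATION",
    "DEFAULT_EXOGENOUS_CORRELATIONS",
    "DEFAULT_DEGENERATES",
]

#: residual-error correlation assumed for the hypothesized residual
#: pairs (call-recall, call-upper_limit, revenue-expense); the published
#: solution does not print these values
DEFAULT_RESIDUAL_CORRELATION = 0.2

#: correlations among exogenous observed covariates; rural prefectures
#: are older and poorer, so aging rate and household income co-vary
#: negatively
DEFAULT_EXOGENOUS_CORRELATIONS = {("aging_rate", "household_income"): -0.3}

#: intervention indicators with a dominant point mass, per cancer type:
#: after-hours / extra-region / out-of-evidence / modality-extension
#: everywhere, charge-free except for lung, upper-limit for lung and
#: colorectal
_COMMON_DEGENERATES = [
    "after_hours",
    "extra_region",
    "out_of_evidence",
    "modality_ext",
]
DEFAULT_DEGENERATES: dict[str, list[str]] = {
    "gastric": _COMMON_DEGENERATES + ["charge_free"],
    "lung": _COMMON_DEGENERATES + ["upper_limit"],
    "colorectal": _COMMON_DEGENERATES + ["charge_free", "upper_limit"],
    "breast": _COMMON_DEGENERATES + ["charge_free"],
    "cervical": _COMMON_DEGENERATES + ["charge_free"],
}

# --------------------------------------------------------------------------
# raw-scale placement: median, (q1, q3), transform
# --------------------------------------------------------------------------
# mode "boxcox": x = invboxcox(t_med + t_scale * z, lam) — right-skewed,
#   support (0, inf), exactly normalized back by the Box-Cox stage.
# mode "headroom": same placement applied to (100 - x) — left-skewed
#   percentage with mass near 100, support (-inf, 100).
# mode "affine": x = med + scale * z.
# Quartiles are mapped through the transform, so median and IQR are
# matched exactly in every mode.


@dataclass(frozen=True)
class _Placement:
    median: float
    q1: float
    q3: float
    mode: str = "boxcox"
    lam: float = 0.5


_RESOURCE_PLACEMENTS: dict[str, _Placement] = {
    "public_health_expense": _Placement(20.6, 17.5, 22.9),
    "general_revenue": _Placement(246.9, 218.3, 266.7),
    "nurses": _Placement(10.3, 8.6, 11.6),
    "phns": _Placement(0.5, 0.4, 0.6),
    "hospitals": _Placement(0.9, 0.8, 1.0),
    "physicians": _Placement(2.4, 2.2, 2.8),
    "aging_rate": _Placement(25.5, 24.3, 26.6, mode="affine"),
    "household_income": _Placement(5.2, 4.9, 5.7),
}

#: per-cancer placements of intervention shares (shares are per cancer
#: type, not per sex)
_INTERVENTION_PLACEMENTS: dict[str, dict[str, _Placement]] = {
    "gastric": {
        "call": _Placement(80.0, 71.6, 90.0, mode="headroom"),
        "recall": _Placement(31.4, 22.1, 52.1, lam=0.25),
        "charge_free": _Placement(7.0, 3.0, 20.5, lam=0.0),
        "after_hours": _Placement(87.0, 80.0, 94.0, mode="headroom"),
        "extra_region": _Placement(1.7, 0.4, 5.0, lam=0.0),
        "modality_ext": _Placement(15.1, 7.0, 27.8, lam=0.25),
        "out_of_evidence": _Placement(90.5, 83.7, 97.0, mode="headroom"),
        "upper_limit": _Placement(28.6, 13.5, 52.9, lam=0.25),
    },
    "lung": {
        "call": _Placement(79.7, 69.1, 90.0, mode="headroom"),
        "recall": _Placement(28.0, 18.7, 44.9, lam=0.25),
        "charge_free": _Placement(28.0, 19.3, 45.9),
        "after_hours": _Placement(86.4, 73.7, 92.1, mode="headroom"),
        "extra_region": _Placement(1.7, 0.4, 5.0, lam=0.0),
        "modality_ext": _Placement(12.5, 4.5, 20.6, lam=0.25),
        "out_of_evidence": _Placement(90.5, 83.7, 97.0, mode="headroom"),
        "upper_limit": _Placement(13.3, 3.5, 28.8, lam=0.25),
    },
    "colorectal": {
        "call": _Placement(81.5, 74.2, 92.2, mode="headroom"),
        "recall": _Placement(42.1, 28.2, 52.8, lam=0.25),
        "charge_free": _Placement(11.1, 5.1, 24.5, lam=0.0),
        "after_hours": _Placement(87.0, 77.6, 93.1, mode="headroom"),
        "extra_region": _Placement(1.5, 0.4, 5.2, lam=0.0),
        "modality_ext": _Placement(1.7, 0.4, 7.4, lam=0.0),
        "out_of_evidence": _Placement(90.5, 83.7, 97.0, mode="headroom"),
        "upper_limit": _Placement(7.3, 2.0, 18.0, lam=0.0),
    },
    "breast": {
        "call": _Placement(81.5, 69.5, 88.4, mode="headroom"),
        "recall": _Placement(44.0, 33.3, 55.1, lam=0.25),
        "charge_free": _Placement(6.3, 0.9, 16.5, lam=0.0),
        "after_hours": _Placement(81.8, 62.9, 90.5, mode="headroom"),
        "extra_region": _Placement(3.1, 0.6, 7.3, lam=0.0),
        "modality_ext": _Placement(80.0, 50.1, 94.7, mode="headroom"),
        "out_of_evidence": _Placement(90.5, 83.7, 97.0, mode="headroom"),
        "upper_limit": _Placement(52.0, 30.2, 67.7, lam=0.25),
    },
    "cervical": {
        "call": _Placement(81.0, 72.7, 90.0, mode="headroom"),
        "recall": _Placement(44.8, 34.5, 55.6, lam=0.25),
        "charge_free": _Placement(8.0, 3.2, 20.0, lam=0.0),
        "after_hours": _Placement(76.0, 57.4, 89.5, mode="headroom"),
        "extra_region": _Placement(1.7, 0.4, 5.8, lam=0.0),
        "modality_ext": _Placement(11.1, 7.5, 23.8, lam=0.25),
        "out_of_evidence": _Placement(90.5, 83.7, 97.0, mode="headroom"),
        "upper_limit": _Placement(29.6, 12.2, 52.0, lam=0.25),
    },
}

#: screening-rate placement (percent) per (cancer, sex)
_RATE_PLACEMENTS: dict[tuple[str, str], _Placement] = {
    ("gastric", "male"): _Placement(9.3, 6.8, 11.5, mode="affine"),
    ("gastric", "female"): _Placement(7.4, 5.6, 9.4, mode="affine"),
    ("lung", "male"): _Placement(23.2, 13.5, 28.9, mode="affine"),
    ("lung", "female"): _Placement(21.2, 12.8, 27.0, mode="affine"),
    ("colorectal", "male"): _Placement(20.3, 17.6, 27.8, mode="affine"),
    ("colorectal", "female"): _Placement(21.2, 17.0, 26.6, mode="affine"),
    ("breast", "female"): _Placement(24.2, 20.6, 28.9, mode="affine"),
    ("cervical", "female"): _Placement(26.3, 23.1, 30.3, mode="affine"),
}

#: point-mass anchors for degenerate variables: (modal value, spread
#: direction); 70% of prefectures sit exactly at the mode
_DEGENERATE_ANCHORS: dict[str, tuple[float, float]] = {
    "out_of_evidence": (100.0, -10.0),
    "after_hours": (100.0, -15.0),
    "extra_region": (0.0, +5.0),
    "modality_ext": (0.0, +10.0),
    "charge_free": (0.0, +8.0),
    "upper_limit": (0.0, +12.0),
}
_DEGENERATE_MODAL_SHARE = 0.7


def _inv_boxcox(t: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.exp(t)
    return special.inv_boxcox(np.clip(t, -1.0 / lam + 1e-9, None), lam) if lam > 0 \
        else special.inv_boxcox(np.clip(t, None, -1.0 / lam - 1e-9), lam)


def _place(z: np.ndarray, pl: _Placement, percentage: bool) -> np.ndarray:
    """Monotone map from standard-normal scores to the raw scale matching
    the placement's median and IQR exactly."""
    from scipy.special import boxcox as _bc

    if pl.mode == "affine":
        x = pl.median + (pl.q3 - pl.q1) / 1.349 * z
    elif pl.mode == "boxcox":
        tq = _bc(np.array([pl.q1, pl.median, pl.q3], dtype=float), pl.lam)
        x = _inv_boxcox(tq[1] + (tq[2] - tq[0]) / 1.349 * z, pl.lam)
    elif pl.mode == "headroom":
        h = np.array([100.0 - pl.q3, 100.0 - pl.median, 100.0 - pl.q1])
        tq = _bc(h, pl.lam)
        x = 100.0 - _inv_boxcox(tq[1] + (tq[2] - tq[0]) / 1.349 * (-z), pl.lam)
    else:  # pragma: no cover
        raise ValueError(f"unknown placement mode {pl.mode!r}")
    if percentage:
        x = np.clip(x, 0.0, 100.0)
    return x


@dataclass
class SimulationConfig:
    """Fully determines one synthetic stratum table."""

    spec: ModelSpec
    true_params: ParameterSet  # standardized metric, marker loadings included
    cancer: str = "gastric"
    sex: str = "male"
    n: int = 47
    seed: int = 0
    skew_map: dict[str, float] = field(default_factory=dict)
    degenerate_vars: list[str] = field(default_factory=list)
    count_scale: tuple[int, int] = (50_000, 500_000)

    def __post_init__(self) -> None:
        if self.cancer in FEMALE_ONLY_CANCERS and self.sex != "female":
            raise ModelError(f"{self.cancer} must be simulated with sex='female'")
        sigma = implied_covariance(self.spec, self.true_params, marker_fixed=False)
        try:
            linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ModelError(
                "implied covariance of the true parameters is not "
                "positive-definite"
            ) from exc


def standardized_truth(
    spec: ModelSpec,
    loadings: dict[tuple[str, str], float],
    paths: dict[tuple[str, str], float],
    exogenous_correlations: dict[tuple[str, str], float] | None = None,
    residual_correlation: float = DEFAULT_RESIDUAL_CORRELATION,
) -> ParameterSet:
    """Complete a standardized coefficient set into a full parameterization.

    Given standardized loadings (marker included) and path coefficients,
    residual variances are solved in topological order so that every
    variable has unit implied variance; the hypothesized residual pairs
    get covariance ``r * sqrt(theta_a * theta_b)``.  Residual-covariance
    pairs must be terminal indicators (no outgoing edges), which holds
    for every catalog model.
    """
    exo_corr = dict(exogenous_correlations or {})
    ps = ParameterSet()
    ps.loadings = dict(loadings)
    ps.paths = dict(paths)

    heads: dict[str, list[tuple[str, float]]] = {v: [] for v in spec.all_vars}
    for latent, indicators in spec.latents:
        for ind in indicators:
            heads[ind].append((latent, loadings[(latent, ind)]))
    for outcome, predictor in spec.regressions:
        heads[outcome].append((predictor, paths[(outcome, predictor)]))

    order = _topological_order(spec)
    processed: list[str] = []
    V: dict[tuple[str, str], float] = {}

    def cov(a: str, b: str) -> float:
        return V[(a, b)] if (a, b) in V else V[(b, a)]

    for v in order:
        preds = heads[v]
        if not preds:  # exogenous: unit variance, specified correlations
            for u in processed:
                key = (v, u) if (v, u) in exo_corr else (u, v)
                V[(v, u)] = exo_corr.get(key, 0.0)
            V[(v, v)] = 1.0
            ps.variances[v] = 1.0
        else:
            for u in processed:
                V[(v, u)] = sum(b * cov(q, u) for q, b in preds)
            explained = sum(
                b1 * b2 * cov(q1, q2) for q1, b1 in preds for q2, b2 in preds
            )
            psi = 1.0 - explained
            if psi <= 0:
                raise ModelError(
                    f"standardized coefficients leave variable {v!r} with "
                    f"non-positive residual variance ({psi:.3f})"
                )
            V[(v, v)] = 1.0
            ps.variances[v] = psi
        processed.append(v)

    for a, b in spec.residual_covariances:
        if heads[a] == [] or heads[b] == []:
            raise ModelError(f"residual pair ({a}, {b}) involves an exogenous variable")
        ps.covariances[(a, b) if a <= b else (b, a)] = (
            residual_correlation * np.sqrt(ps.variances[a] * ps.variances[b])
        )
    exo_obs = spec.exogenous_observed
    for i in range(len(exo_obs)):
        for j in range(i + 1, len(exo_obs)):
            a, b = exo_obs[i], exo_obs[j]
            key = (a, b) if a <= b else (b, a)
            r = exo_corr.get((a, b), exo_corr.get((b, a), 0.0))
            ps.covariances[key] = r
    return ps


def _topological_order(spec: ModelSpec) -> list[str]:
    succ: dict[str, list[str]] = {v: [] for v in spec.all_vars}
    indeg = {v: 0 for v in spec.all_vars}
    for head, tail in spec.directed_edges:
        succ[tail].append(head)
        indeg[head] += 1
    order, queue = [], sorted(v for v, d in indeg.items() if d == 0)
    while queue:
        v = queue.pop(0)
        order.append(v)
        for w in succ[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return order


def default_config(
    cancer: str, sex: str, seed: int = 0, n: int = 47
) -> SimulationConfig:
    """Study-condition defaults for one stratum: the final-model topology
    at the published standardized solution, realistic skew on every
    policy/financial variable, and the degenerate intervention set that
    the normality screen must exclude."""
    spec = load_model(f"{cancer}_{sex}_final")
    est = STANDARDIZED_ESTIMATES[(cancer, sex)]
    truth = standardized_truth(
        spec,
        est["loadings"],
        est["paths"],
        exogenous_correlations=DEFAULT_EXOGENOUS_CORRELATIONS,
    )
    return SimulationConfig(
        spec=spec,
        true_params=truth,
        cancer=cancer,
        sex=sex,
        n=n,
        seed=seed,
        degenerate_vars=list(DEFAULT_DEGENERATES[cancer]),
    )


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def simulate_scores(
    spec: ModelSpec, true_params: ParameterSet, n: int, seed: int
) -> pd.DataFrame:
    """n rows of multivariate-normal scores for the model's observed
    variables, drawn from the implied covariance of the truth.

    Each variable consumes its own substream; the Cholesky mixing is
    lower-triangular in the spec's variable order, so appending a new
    variable leaves existing columns untouched.
    """
    sigma = implied_covariance(spec, true_params, marker_fixed=False)
    L = linalg.cholesky(sigma, lower=True)
    Z = np.column_stack(
        [_substream(seed, f"score:{v}").standard_normal(n) for v in spec.observed]
    )
    return pd.DataFrame(Z @ L.T, columns=list(spec.observed))


def simulate_table(config: SimulationConfig) -> RegionTable:
    """Generate a full prefecture table for one stratum.

    Model variables are placed from their latent scores; schema variables
    outside the model get independent scores; degenerate variables are
    overwritten with point-mass draws; counts are synthesized so the
    recomputed screening rate reproduces the placed rate up to binomial
    noise.
    """
    cfg = config
    scores = simulate_scores(cfg.spec, cfg.true_params, cfg.n, cfg.seed)
    placements = dict(_RESOURCE_PLACEMENTS)
    placements.update(_INTERVENTION_PLACEMENTS[cfg.cancer])
    placements["rate"] = _RATE_PLACEMENTS[(cfg.cancer, cfg.sex)]

    columns: dict[str, np.ndarray] = {}
    for name in MODEL_VARIABLES:
        if name in scores.columns:
            z = scores[name].to_numpy()
        else:
            z = _substream(cfg.seed, f"score:{name}").standard_normal(cfg.n)
        pl = placements[name]
        if name in cfg.skew_map:
            pl = _Placement(pl.median, pl.q1, pl.q3, "boxcox", cfg.skew_map[name])
        percentage = name == "rate" or MODEL_VARIABLES[name].endswith("_pct")
        columns[name] = _place(z, pl, percentage)

    for name in cfg.degenerate_vars:
        mode_value, spread = _DEGENERATE_ANCHORS[name]
        rng = _substream(cfg.seed, f"degenerate:{name}")
        u = rng.uniform(size=cfg.n)
        tail = mode_value + np.abs(rng.normal(size=cfg.n)) * spread * np.sign(spread) \
            if spread > 0 else mode_value - np.abs(rng.normal(size=cfg.n)) * abs(spread)
        vals = np.where(u < _DEGENERATE_MODAL_SHARE, mode_value, tail)
        columns[name] = np.clip(vals, 0.0, 100.0)

    rate_pct = np.clip(columns["rate"], 0.1, 80.0)
    rng_counts = _substream(cfg.seed, "counts")
    eligible = rng_counts.integers(cfg.count_scale[0], cfg.count_scale[1], size=cfg.n)
    screened = rng_counts.binomial(eligible, rate_pct / 100.0)
    total = 2 * eligible
    employed = (11 * eligible) // 10
    primary = eligible - total + employed  # reconstructs eligible exactly

    records = []
    for i in range(cfg.n):
        records.append(
            PrefectureRecord(
                prefecture_id=f"P{i + 1:02d}",
                cancer=cfg.cancer,
                sex=cfg.sex,
                screened=int(screened[i]),
                total_population=int(total[i]),
                employed=int(employed[i]),
                primary_industry_workers=int(primary[i]),
                call_pct=float(columns["call"][i]),
                recall_pct=float(columns["recall"][i]),
                charge_free_pct=float(columns["charge_free"][i]),
                after_hours_pct=float(columns["after_hours"][i]),
                extra_region_pct=float(columns["extra_region"][i]),
                modality_ext_pct=float(columns["modality_ext"][i]),
                out_of_evidence_pct=float(columns["out_of_evidence"][i]),
                upper_limit_pct=float(columns["upper_limit"][i]),
                public_health_expense=float(columns["public_health_expense"][i]),
                general_revenue=float(columns["general_revenue"][i]),
                nurses=float(columns["nurses"][i]),
                phns=float(columns["phns"][i]),
                hospitals=float(columns["hospitals"][i]),
                physicians=float(columns["physicians"][i]),
                aging_rate=float(columns["aging_rate"][i]),
                household_income=float(columns["household_income"][i]),
            )
        )
    return RegionTable(records)


def recovery_experiment(
    spec: ModelSpec,
    true_params: ParameterSet,
    n: int,
    reps: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo parameter recovery for the standardized solution.

    Each replicate draws ``n`` multivariate-normal observations from the
    truth's implied covariance and refits the model; the table reports,
    per free parameter, the standardized truth, mean estimate, bias,
    RMSE and the coverage of nominal delta-method 95% intervals.
    Non-convergent replicates are excluded and counted in the
    ``n_excluded`` attribute (``df.attrs``).
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    keys = param_names(spec)
    truth_vec = np.array([true_params.get(k) for k in keys])
    sigma = implied_covariance(spec, true_params, marker_fixed=False)
    L = linalg.cholesky(sigma, lower=True)
    seeds = np.random.SeedSequence(seed).spawn(reps)
    estimates, covered = [], []
    excluded = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        X = rng.standard_normal((n, len(spec.observed))) @ L.T
        try:
            result = fit(spec, X, names=list(spec.observed))
        except ModelError:
            excluded += 1
            continue
        if not result.converged:
            excluded += 1
            continue
        std = result.standardized
        est = np.array([std.get(k) for k in keys])
        if not np.all(np.isfinite(est)):
            excluded += 1
            continue
        estimates.append(est)
        try:
            se = standardized_standard_errors(result)
            se_vec = np.array([se[k] for k in keys])
            cov_row = np.where(
                se_vec > 1e-8,  # structurally constant std. params have no interval
                np.abs(est - truth_vec) <= 1.959963984540054 * se_vec,
                np.nan,
            )
            covered.append(cov_row)
        except ModelError:
            covered.append(np.full(len(keys), np.nan))
    if not estimates:
        raise ModelError("no replicate converged")
    E = np.vstack(estimates)
    C = np.vstack(covered).astype(float)
    from .sem import format_param

    df = pd.DataFrame(
        {
            "parameter": [format_param(k) for k in keys],
            "truth": truth_vec,
            "mean_estimate": E.mean(axis=0),
            "bias": E.mean(axis=0) - truth_vec,
            "rmse": np.sqrt(((E - truth_vec) ** 2).mean(axis=0)),
            "coverage_95": _nanmean_columns(C),
        }
    )
    df.attrs["n_converged"] = len(estimates)
    df.attrs["n_excluded"] = excluded
    df.attrs["n"] = n
    return df


def _nanmean_columns(C: np.ndarray) -> np.ndarray:
    """Column means ignoring NaN; all-NaN columns (parameters without a
    defined interval) yield NaN without warning."""
    out = np.full(C.shape[1], np.nan)
    for j in range(C.shape[1]):
        col = C[:, j]
        good = np.isfinite(col)
        if good.any():
            out[j] = col[good].mean()
    return out
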