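"""End-to-end study runner: ingest, preprocess, fit, index, report.

One run covers any subset of the eight cancer x sex strata.  Per stratum
the stages are: read (or simulate) the prefecture table; screen and
transform every model variable (Box-Cox + standardization, exclusions
with reasons); prune screened-out indicators from the model topology;
fit by maximum likelihood; compute the fit-index battery and the
four-criterion acceptance verdict; tabulate the standardized solution.
A failure in one stratum is recorded and does not abort the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .data_model import RegionTable, read_region_table
from .fit_indices import FitIndexReport, index_report
from .preprocess import prepare_analysis_table
from .sem import FitResult, ModelError, ModelSpec, fit, format_param, param_names
from .study_models import STRATA, load_model
from .synthetic import default_config, simulate_table

logger = logging.getLogger("screensem")

__all__ = ["StudyConfig", "StratumResult", "StudyReport", "run_study", "prune_spec"]


@dataclass
class StudyConfig:
    """Configuration of one study run.

    ``data_paths`` maps (cancer, sex) to a stratum CSV; strata without a
    path are simulated from the catalog truth at ``n`` units with
    ``seed``.  ``stage`` selects the catalog topology to fit.
    """

    strata: list[tuple[str, str]] = field(default_factory=lambda: list(STRATA))
    data_paths: dict[tuple[str, str], Path] = field(default_factory=dict)
    stage: str = "final"
    output_dir: Path | None = None
    seed: int = 0
    n: int = 47
    verbosity: str = "info"


@dataclass
class StratumResult:
    cancer: str
    sex: str
    error: str | None = None
    kept: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    fit_result: FitResult | None = None
    indices: FitIndexReport | None = None

    @property
    def accepted(self) -> bool | None:
        return None if self.indices is None else self.indices.accepted

    def standardized_table(self) -> pd.DataFrame | None:
        """Standardized estimates shaped like the published solution
        table: one row per loading/path with estimate and p-value."""
        if self.fit_result is None:
            return None
        res = self.fit_result
        rows = []
        for key in param_names(res.spec):
            if key[0] not in ("loading", "path"):
                continue
            rows.append(
                {
                    "parameter": format_param(key),
                    "standardized_estimate": round(res.standardized.get(key), 2),
                    "p_value": round(res.p_values.get(key, float("nan")), 4),
                }
            )
        # markers: standardized value shown, no p-value (loading fixed)
        for latent, indicators in res.spec.latents:
            rows.insert(
                0,
                {
                    "parameter": f"{latent} =~ {indicators[0]} (marker)",
                    "standardized_estimate": round(
                        res.standardized.loadings[(latent, indicators[0])], 2
                    ),
                    "p_value": float("nan"),
                },
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "cancer": self.cancer,
            "sex": self.sex,
            "error": self.error,
            "kept_variables": self.kept,
            "dropped_variables": [
                {"variable": v, "reason": r} for v, r in self.dropped
            ],
        }
        if self.fit_result is not None:
            out["fit"] = self.fit_result.to_dict()
        if self.indices is not None:
            out["fit_indices"] = self.indices.to_dict()
            out["accepted"] = self.indices.accepted
        return out


@dataclass
class StudyReport:
    results: list[StratumResult]
    config: StudyConfig

    def to_dict(self) -> dict:
        return {
            "metadata": {
                "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "seed": self.config.seed,
                "stage": self.config.stage,
                "n": self.config.n,
            },
            "strata": [r.to_dict() for r in self.results],
        }

    def write(self, output_dir: str | Path) -> Path:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        path = output_dir / "study_report.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        for r in self.results:
            table = r.standardized_table()
            if table is not None:
                table.to_csv(
                    output_dir / f"standardized_{r.cancer}_{r.sex}.csv", index=False
                )
        return path


def prune_spec(spec: ModelSpec, kept: list[str]) -> ModelSpec:
    """Restrict a topology to the variables that survived screening.

    Screened-out indicators are removed from their latent; regressions
    and residual covariances touching a removed variable are dropped.  A
    latent left with fewer than two indicators, or a missing outcome
    variable, makes the stratum unmodelable.
    """
    kept_set = set(kept)
    missing = [v for v in spec.observed if v not in kept_set]
    if not missing:
        return spec
    new_latents = []
    for latent, indicators in spec.latents:
        remaining = tuple(i for i in indicators if i in kept_set)
        if len(remaining) < 2:
            raise ModelError(
                f"latent {latent!r} has {len(remaining)} indicator(s) left "
                f"after screening (removed: {sorted(set(indicators) - kept_set)})"
            )
        new_latents.append((latent, remaining))
    lat_names = {name for name, _ in spec.latents}
    new_regressions = tuple(
        (o, p)
        for o, p in spec.regressions
        if (o in kept_set or o in lat_names) and (p in kept_set or p in lat_names)
    )
    new_covs = tuple(
        (a, b)
        for a, b in spec.residual_covariances
        if a in kept_set and b in kept_set
    )
    return ModelSpec(
        observed=tuple(v for v in spec.observed if v in kept_set),
        latents=tuple(new_latents),
        regressions=new_regressions,
        residual_covariances=new_covs,
        exogenous_free=spec.exogenous_free,
    )


def run_stratum(
    cancer: str,
    sex: str,
    table: RegionTable,
    spec: ModelSpec,
) -> StratumResult:
    result = StratumResult(cancer=cancer, sex=sex)
    try:
        groups = {latent: list(inds) for latent, inds in spec.latents}
        matrix, kept, dropped = prepare_analysis_table(
            table, list(spec.observed), required_groups=groups
        )
        result.kept, result.dropped = kept, dropped
        model = prune_spec(spec, kept)
        if "rate" not in model.observed:
            raise ModelError("screening rate failed the normality screen")
        frame = pd.DataFrame(matrix, columns=kept)
        fitted = fit(model, frame)
        result.fit_result = fitted
        result.indices = index_report(fitted)
        logger.info(
            "%s/%s: chi2=%.2f df=%d accepted=%s",
            cancer, sex, fitted.chi_square, fitted.df,
            result.indices.accepted,
        )
    except Exception as exc:  # per-stratum isolation
        logger.warning("%s/%s failed: %s", cancer, sex, exc)
        result.error = str(exc)
    return result


def run_study(config: StudyConfig) -> StudyReport:
    """Run every configured stratum; errors are isolated per stratum."""
    results = []
    for cancer, sex in config.strata:
        try:
            spec = load_model(f"{cancer}_{sex}_{config.stage}")
        except ModelError as exc:
            results.append(StratumResult(cancer=cancer, sex=sex, error=str(exc)))
            continue
        try:
            if (cancer, sex) in config.data_paths:
                table = read_region_table(
                    config.data_paths[(cancer, sex)], cancer=cancer, sex=sex
                )
            else:
                table = simulate_table(
                    default_config(cancer, sex, seed=config.seed, n=config.n)
                )
        except Exception as exc:
            results.append(StratumResult(cancer=cancer, sex=sex, error=str(exc)))
            continue
        results.append(run_stratum(cancer, sex, table, spec))
    report = StudyReport(results=results, config=config)
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
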