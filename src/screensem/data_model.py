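"""Prefecture-level study tables for municipality-based cancer screening.

The unit of analysis is the prefecture (47 areal units in Japan).  Each
record carries, for one cancer type and sex stratum, the raw counts needed
for the screening rate, the eight intervention-adoption percentages (share
of municipalities implementing a given screening intervention), the
medical/financial resource indicators, and two demographic covariates.

Screening is municipality-based: employees are customarily screened by
their employer's insurer, so the eligible pool is the total population
minus the employed plus primary-industry workers (who are self-employed
and therefore fall back on municipal screening)::

    eligible = total_population - employed + primary_industry_workers
    rate     = screened / eligible
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CANCERS",
    "SEXES",
    "SCHEMA_COLUMNS",
    "MODEL_VARIABLES",
    "SchemaError",
    "ValidationError",
    "DataAnomalyWarning",
    "PrefectureRecord",
    "MunicipalRecord",
    "RegionTable",
    "eligible_population",
    "screening_rate",
    "intervention_share",
    "aggregate_municipalities",
    "read_region_table",
    "write_region_table",
]

CANCERS = ("gastric", "lung", "colorectal", "breast", "cervical")
SEXES = ("male", "female", "combined")

#: cancers screened in women only; their records must carry sex="female"
FEMALE_ONLY_CANCERS = frozenset({"breast", "cervical"})

_COUNT_FIELDS = ("screened", "total_population", "employed", "primary_industry_workers")
_PCT_FIELDS = (
    "call_pct",
    "recall_pct",
    "charge_free_pct",
    "after_hours_pct",
    "extra_region_pct",
    "modality_ext_pct",
    "out_of_evidence_pct",
    "upper_limit_pct",
)
_RESOURCE_FIELDS = (
    "public_health_expense",  # 10^3 yen per capita
    "general_revenue",        # 10^3 yen per capita
    "nurses",                 # per 10^3 people
    "phns",                   # public health nurses per 10^3 people
    "hospitals",              # per 10^3 people
    "physicians",             # per 10^3 people
)
_OTHER_FIELDS = ("aging_rate", "household_income")

SCHEMA_COLUMNS = (
    ("prefecture_id", "cancer", "sex")
    + _COUNT_FIELDS
    + _PCT_FIELDS
    + _RESOURCE_FIELDS
    + _OTHER_FIELDS
)

#: model-variable name -> table column (computed columns handled separately)
MODEL_VARIABLES = {
    "rate": "rate",
    "call": "call_pct",
    "recall": "recall_pct",
    "charge_free": "charge_free_pct",
    "after_hours": "after_hours_pct",
    "extra_region": "extra_region_pct",
    "modality_ext": "modality_ext_pct",
    "out_of_evidence": "out_of_evidence_pct",
    "upper_limit": "upper_limit_pct",
    "public_health_expense": "public_health_expense",
    "general_revenue": "general_revenue",
    "nurses": "nurses",
    "phns": "phns",
    "hospitals": "hospitals",
    "physicians": "physicians",
    "aging_rate": "aging_rate",
    "household_income": "household_income",
}


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """A record violates a field-level invariant."""


class DataAnomalyWarning(UserWarning):
    """Non-fatal data oddity, e.g. more screened persons than eligible."""


def eligible_population(
    total_population: int, employed: int, primary_industry_workers: int
) -> int:
    """Population eligible for municipality-based screening.

    Employees are screened through their employer's insurer and leave the
    municipal pool; primary-industry workers (counted among the employed)
    are self-employed and re-enter it.
    """
    if total_population < 0 or employed < 0 or primary_industry_workers < 0:
        raise ValidationError("counts must be non-negative")
    if employed > total_population:
        raise ValidationError(
            f"employed ({employed}) exceeds total population ({total_population})"
        )
    result = total_population - employed + primary_industry_workers
    if result < 0:  # unreachable given the checks above; kept as a guard
        raise ValidationError("eligible population is negative")
    return result


def screening_rate(screened: int, eligible: int) -> float:
    """Screening uptake as a proportion of the eligible population.

    ``screened > eligible`` is flagged with :class:`DataAnomalyWarning`
    but still computed: municipal registries occasionally record more
    participants than the derived denominator.
    """
    if eligible <= 0:
        raise ValidationError("eligible population must be positive for a rate")
    if screened < 0:
        raise ValidationError("screened count must be non-negative")
    if screened > eligible:
        warnings.warn(
            f"screened ({screened}) exceeds eligible ({eligible}); rate > 1",
            DataAnomalyWarning,
            stacklevel=2,
        )
    return screened / eligible


def intervention_share(municipal_flags: Sequence[bool]) -> float:
    """Percentage of municipalities implementing an intervention (0-100)."""
    flags = list(municipal_flags)
    if not flags:
        raise ValidationError("cannot compute a share of zero municipalities")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


@dataclass
class PrefectureRecord:
    """One prefecture's counts, intervention shares and covariates
    for a single cancer type and sex stratum."""

    prefecture_id: str
    cancer: str
    sex: str
    screened: int
    total_population: int
    employed: int
    primary_industry_workers: int
    call_pct: float
    recall_pct: float
    charge_free_pct: float
    after_hours_pct: float
    extra_region_pct: float
    modality_ext_pct: float
    out_of_evidence_pct: float
    upper_limit_pct: float
    public_health_expense: float
    general_revenue: float
    nurses: float
    phns: float
    hospitals: float
    physicians: float
    aging_rate: float
    household_income: float

    def __post_init__(self) -> None:
        if self.cancer not in CANCERS:
            raise ValidationError(f"unknown cancer {self.cancer!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.cancer in FEMALE_ONLY_CANCERS and self.sex != "female":
            raise ValidationError(
                f"{self.cancer} screening records must have sex='female'"
            )
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{self.prefecture_id}: {name} is negative ({v})")
        if self.employed > self.total_population:
            raise ValidationError(
                f"{self.prefecture_id}: employed exceeds total population"
            )
        for name in _PCT_FIELDS + ("aging_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{self.prefecture_id}: {name} = {v} outside [0, 100]"
                )

    @property
    def eligible(self) -> int:
        return eligible_population(
            self.total_population, self.employed, self.primary_industry_workers
        )

    @property
    def rate(self) -> float:
        return screening_rate(self.screened, self.eligible)


@dataclass
class MunicipalRecord:
    """One municipality's raw inputs prior to prefecture aggregation.

    Intervention fields are booleans (does this municipality implement the
    intervention); resource fields are absolute numerators (total expense
    in 10^3 yen, head counts) so that per-capita and per-1000 indicators
    can be recomputed from summed numerators and denominators.
    """

    prefecture_id: str
    municipality_id: str
    cancer: str
    sex: str
    screened: int
    total_population: int
    employed: int
    primary_industry_workers: int
    call: bool
    recall: bool
    charge_free: bool
    after_hours: bool
    extra_region: bool
    modality_ext: bool
    out_of_evidence: bool
    upper_limit: bool
    health_expense_total: float  # 10^3 yen, absolute
    general_revenue_total: float  # 10^3 yen, absolute
    nurses_count: float
    phns_count: float
    hospitals_count: float
    physicians_count: float
    population_65plus: int
    household_income: float  # 10^3 yen, municipal mean


def aggregate_municipalities(
    municipal_rows: Sequence[MunicipalRecord],
) -> PrefectureRecord:
    """Combine municipal rows of one prefecture into a prefecture record.

    Counts are summed; intervention shares are the percentage of
    municipalities with the flag set; per-capita / per-1000 indicators are
    recomputed from summed numerators over the summed population; household
    income is the population-weighted mean.
    """
    rows = list(municipal_rows)
    if not rows:
        raise ValidationError("no municipal rows to aggregate")
    first = rows[0]
    for r in rows[1:]:
        if (r.prefecture_id, r.cancer, r.sex) != (
            first.prefecture_id,
            first.cancer,
            first.sex,
        ):
            raise ValidationError(
                "municipal rows mix prefectures or strata: "
                f"{(r.prefecture_id, r.cancer, r.sex)} vs "
                f"{(first.prefecture_id, first.cancer, first.sex)}"
            )
    pop = sum(r.total_population for r in rows)
    if pop <= 0:
        raise ValidationError("aggregated population is zero")
    share = lambda name: intervention_share([getattr(r, name) for r in rows])
    return PrefectureRecord(
        prefecture_id=first.prefecture_id,
        cancer=first.cancer,
        sex=first.sex,
        screened=sum(r.screened for r in rows),
        total_population=pop,
        employed=sum(r.employed for r in rows),
        primary_industry_workers=sum(r.primary_industry_workers for r in rows),
        call_pct=share("call"),
        recall_pct=share("recall"),
        charge_free_pct=share("charge_free"),
        after_hours_pct=share("after_hours"),
        extra_region_pct=share("extra_region"),
        modality_ext_pct=share("modality_ext"),
        out_of_evidence_pct=share("out_of_evidence"),
        upper_limit_pct=share("upper_limit"),
        public_health_expense=sum(r.health_expense_total for r in rows) / pop,
        general_revenue=sum(r.general_revenue_total for r in rows) / pop,
        nurses=1000.0 * sum(r.nurses_count for r in rows) / pop,
        phns=1000.0 * sum(r.phns_count for r in rows) / pop,
        hospitals=1000.0 * sum(r.hospitals_count for r in rows) / pop,
        physicians=1000.0 * sum(r.physicians_count for r in rows) / pop,
        aging_rate=100.0 * sum(r.population_65plus for r in rows) / pop,
        household_income=sum(r.household_income * r.total_population for r in rows)
        / pop,
    )


@dataclass
class RegionTable:
    """Ordered prefecture records for a single cancer x sex stratum."""

    records: list[PrefectureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("a region table needs at least one record")
        ids = [r.prefecture_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate prefecture_ids: {dupes}")
        strata = {(r.cancer, r.sex) for r in self.records}
        if len(strata) > 1:
            raise ValidationError(f"records mix strata: {sorted(strata)}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def cancer(self) -> str:
        return self.records[0].cancer

    @property
    def sex(self) -> str:
        return self.records[0].sex

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame with the schema columns plus derived
        ``eligible`` and ``rate`` (as a percentage) columns."""
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
        df["eligible"] = [r.eligible for r in self.records]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataAnomalyWarning)
            df["rate"] = [100.0 * r.rate for r in self.records]
        return df

    def variable(self, name: str) -> pd.Series:
        """Model-variable column by its short analysis name."""
        if name not in MODEL_VARIABLES:
            raise KeyError(f"unknown model variable {name!r}")
        df = self.to_frame()
        return df[MODEL_VARIABLES[name]].rename(name)

    def variables(self, names: Iterable[str]) -> pd.DataFrame:
        return pd.concat([self.variable(n) for n in names], axis=1)


def read_region_table(
    path: str | Path, cancer: str | None = None, sex: str | None = None
) -> RegionTable:
    """Read a stratum table from CSV, validating every row.

    The file may be a single-stratum file or a combined long-format file;
    in the latter case ``cancer`` and ``sex`` select the stratum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if cancer is not None:
        df = df[df["cancer"] == cancer]
    if sex is not None:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValidationError(
            f"{path.name}: no rows for stratum cancer={cancer!r}, sex={sex!r}"
        )
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PrefectureRecord(
                    prefecture_id=str(row["prefecture_id"]),
                    cancer=str(row["cancer"]),
                    sex=str(row["sex"]),
                    **{
                        f: int(row[f]) for f in _COUNT_FIELDS
                    },
                    **{
                        f: float(row[f])
                        for f in _PCT_FIELDS + _RESOURCE_FIELDS + _OTHER_FIELDS
                    },
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name}, row {idx}: {exc}") from exc
    return RegionTable(records)


def write_region_table(table: RegionTable, path: str | Path) -> Path:
    """Write a stratum table as UTF-8 comma-separated CSV (schema columns
    only; derived columns are recomputed on read)."""
    path = Path(path)
    rows = [dataclasses.asdict(r) for r in table.records]
    pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)).to_csv(path, index=False)
    return path
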