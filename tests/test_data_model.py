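"""Schema, screening-rate arithmetic and municipal aggregation."""

import dataclasses

import numpy as np
import pytest

from screensem.data_model import (
    DataAnomalyWarning,
    MunicipalRecord,
    PrefectureRecord,
    RegionTable,
    SchemaError,
    ValidationError,
    aggregate_municipalities,
    eligible_population,
    intervention_share,
    read_region_table,
    screening_rate,
    write_region_table,
)


def make_record(**overrides):
    base = dict(
        prefecture_id="P01",
        cancer="gastric",
        sex="male",
        screened=7_000,
        total_population=1_000_000,
        employed=500_000,
        primary_industry_workers=50_000,
        call_pct=80.0,
        recall_pct=30.0,
        charge_free_pct=7.0,
        after_hours_pct=87.0,
        extra_region_pct=2.0,
        modality_ext_pct=15.0,
        out_of_evidence_pct=90.0,
        upper_limit_pct=28.0,
        public_health_expense=20.6,
        general_revenue=246.9,
        nurses=10.3,
        phns=0.5,
        hospitals=0.9,
        physicians=2.4,
        aging_rate=25.5,
        household_income=5.2,
    )
    base.update(overrides)
    return PrefectureRecord(**base)


class TestEligiblePopulation:
    def test_no_employment(self):
        assert eligible_population(1000, 0, 0) == 1000

    def test_direct_arithmetic(self):
        assert eligible_population(1000, 400, 100) == 700

    def test_matches_independent_oneliner(self, rng):
        formula = lambda t, e, p: t - e + p
        for _ in range(20):
            t = int(rng.integers(1_000, 2_000_000))
            e = int(rng.integers(0, t))
            p = int(rng.integers(0, e + 1))
            assert eligible_population(t, e, p) == formula(t, e, p)

    def test_linear_in_primary_workers(self):
        assert (
            eligible_population(1000, 400, 101)
            - eligible_population(1000, 400, 100)
            == 1
        )

    def test_employed_exceeding_population_rejected(self):
        with pytest.raises(ValidationError):
            eligible_population(1000, 1001, 0)


class TestScreeningRate:
    def test_nobody_screened(self):
        assert screening_rate(0, 700) == 0.0

    def test_direct_ratio(self):
        assert screening_rate(70, 700) == pytest.approx(0.10)

    def test_zero_eligible_is_error(self):
        with pytest.raises(ValidationError):
            screening_rate(10, 0)

    def test_overcount_warns_but_computes(self):
        with pytest.warns(DataAnomalyWarning):
            assert screening_rate(800, 700) == pytest.approx(800 / 700)

    def test_binomial_sampling_recovers_target(self, rng):
        eligible = 100_000
        target = 0.093
        screened = rng.binomial(eligible, target)
        rate = screening_rate(int(screened), eligible)
        # 5 sigma binomial band
        assert abs(rate - target) < 5 * np.sqrt(target * (1 - target) / eligible)

    def test_never_exceeds_one_when_bounded(self):
        assert screening_rate(700, 700) <= 1.0


class TestInterventionShare:
    def test_all_true(self):
        assert intervention_share([True] * 5) == 100.0

    def test_half(self):
        assert intervention_share([True, False, False, True]) == 50.0

    def test_matches_mean_oracle(self, rng):
        for _ in range(1000):
            flags = rng.uniform(size=int(rng.integers(1, 30))) < 0.5
            assert intervention_share(list(flags)) == pytest.approx(
                100.0 * np.mean(flags)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            intervention_share([])


class TestRecordValidation:
    def test_percentage_bound(self):
        with pytest.raises(ValidationError, match="call_pct"):
            make_record(call_pct=130.0)

    def test_negative_count(self):
        with pytest.raises(ValidationError):
            make_record(screened=-1)

    def test_breast_must_be_female(self):
        with pytest.raises(ValidationError):
            make_record(cancer="breast", sex="male")

    def test_duplicate_prefecture_ids(self):
        with pytest.raises(ValidationError, match="duplicate"):
            RegionTable([make_record(), make_record()])


class TestRoundTrip:
    def test_writer_reader_identity(self, tmp_path):
        table = RegionTable(
            [make_record(prefecture_id=f"P{i:02d}") for i in range(3)]
        )
        path = write_region_table(table, tmp_path / "t.csv")
        back = read_region_table(path, cancer="gastric", sex="male")
        assert back.n == 3
        for a, b in zip(table.records, back.records):
            assert dataclasses.asdict(a) == pytest.approx(dataclasses.asdict(b))

    def test_generator_output_validates(self, gastric_male_table, tmp_path):
        path = write_region_table(gastric_male_table, tmp_path / "g.csv")
        back = read_region_table(path, cancer="gastric", sex="male")
        assert back.n == 47

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("prefecture_id,cancer,sex\nP01,gastric,male\n")
        with pytest.raises(SchemaError, match="screened"):
            read_region_table(p)

    def test_out_of_range_row_reported(self, tmp_path):
        table = RegionTable([make_record()])
        path = write_region_table(table, tmp_path / "t.csv")
        text = path.read_text().replace("80.0", "130.0")
        path.write_text(text)
        with pytest.raises(ValidationError, match="call_pct"):
            read_region_table(path)


def make_municipality(i, **overrides):
    base = dict(
        prefecture_id="P01",
        municipality_id=f"M{i:02d}",
        cancer="gastric",
        sex="male",
        screened=30,
        total_population=10_000,
        employed=5_000,
        primary_industry_workers=500,
        call=True,
        recall=False,
        charge_free=False,
        after_hours=True,
        extra_region=False,
        modality_ext=False,
        out_of_evidence=True,
        upper_limit=False,
        health_expense_total=206_000.0,
        general_revenue_total=2_469_000.0,
        nurses_count=103.0,
        phns_count=5.0,
        hospitals_count=9.0,
        physicians_count=24.0,
        population_65plus=2_550,
        household_income=5.2,
    )
    base.update(overrides)
    return MunicipalRecord(**base)


class TestAggregation:
    def test_single_municipality_identity(self):
        agg = aggregate_municipalities([make_municipality(1)])
        assert agg.screened == 30
        assert agg.public_health_expense == pytest.approx(20.6)
        assert agg.phns == pytest.approx(0.5)
        assert agg.aging_rate == pytest.approx(25.5)
        assert agg.call_pct == 100.0
        assert agg.recall_pct == 0.0

    def test_counts_additive(self):
        rows = [
            make_municipality(1, screened=30),
            make_municipality(2, screened=70),
        ]
        assert aggregate_municipalities(rows).screened == 100

    def test_order_invariance(self):
        rows = [make_municipality(i, screened=10 * i) for i in range(1, 5)]
        a = aggregate_municipalities(rows)
        b = aggregate_municipalities(rows[::-1])
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_rate_equals_weighted_mean_of_municipal_rates(self):
        rows = [
            make_municipality(1, screened=300, total_population=20_000,
                              employed=10_000, primary_industry_workers=1_000),
            make_municipality(2, screened=50, total_population=8_000,
                              employed=4_000, primary_industry_workers=200),
        ]
        agg = aggregate_municipalities(rows)
        eligibles = [
            eligible_population(r.total_population, r.employed,
                                r.primary_industry_workers)
            for r in rows
        ]
        rates = [r.screened / e for r, e in zip(rows, eligibles)]
        weighted = np.average(rates, weights=eligibles)
        assert agg.rate == pytest.approx(weighted)

    def test_mixed_prefectures_rejected(self):
        with pytest.raises(ValidationError, match="mix"):
            aggregate_municipalities(
                [make_municipality(1), make_municipality(2, prefecture_id="P02")]
            )
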