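import numpy as np
import pandas as pd
import pytest

from ecosir.data_io import Dataset, RunConfig
from ecosir.errors import DataError
from ecosir.standardization import (
    annual_sir,
    build_cells,
    expected_counts,
    person_time,
    reference_rates,
)
from ecosir.synthetic_data import SimulationSpec, simulate_dataset


def _births(rows):
    return pd.DataFrame(rows, columns=["municipality_id", "birth_year", "n_births"])


class TestPersonTime:
    def test_birth_in_final_year_contributes_age_zero_only(self):
        pt = person_time(_births([("A", 2005, 1)]), study_end_year=2005)
        assert len(pt) == 1
        assert pt.iloc[0]["age_class"] == "0"
        assert pt.iloc[0]["person_years"] == 1

    def test_fully_observed_birth_contributes_15_person_years(self):
        pt = person_time(_births([("A", 1990, 1)]), study_end_year=2005)
        assert pt["person_years"].sum() == 15
        assert sorted(pt["age_class"].astype(int)) == list(range(15))

    def test_matches_exhaustive_enumeration(self, rng):
        """Total person-years equal brute-force iteration over every
        (birth, age) pair."""
        rows = [
            (f"M{rng.integers(5)}", int(rng.integers(1990, 2000)), int(rng.integers(0, 50)))
            for _ in range(60)
        ]
        end = 2003
        pt = person_time(_births(rows), end)
        brute = 0
        for _, year, n in rows:
            for a in range(15):
                if year + a <= end:
                    brute += n
        assert pt["person_years"].sum() == brute

    def test_no_person_time_past_study_end(self):
        pt = person_time(_births([("A", 2000, 7)]), study_end_year=2004)
        assert pt["age_class"].astype(int).max() == 4

    def test_grouped_aml_scheme_aggregates(self):
        pt = person_time(
            _births([("A", 1990, 2)]), study_end_year=2010, age_scheme="grouped_aml"
        )
        got = pt.set_index("age_class")["person_years"].to_dict()
        assert got == {"<1": 2, "1-4": 8, "5-9": 10, "10-14": 10}

    def test_age_range_restriction(self):
        pt = person_time(
            _births([("A", 1990, 3)]), study_end_year=2010, age_range=(7, 14)
        )
        assert pt["person_years"].sum() == 3 * 8
        assert pt["age_class"].astype(int).min() == 7


class TestReferenceRates:
    def test_rate_is_cases_over_person_years(self):
        pt = person_time(_births([("A", 1990, 1000)]), 2010)
        cases = pd.DataFrame(
            {
                "municipality_id": ["A"] * 10,
                "birth_year": [1990] * 10,
                "age_at_diagnosis": [3] * 10,
                "subtype": ["BCP_ALL"] * 10,
            }
        )
        rates = reference_rates(cases, pt)
        assert rates["3"] == pytest.approx(10 / 1000)
        assert rates["7"] == 0.0

    def test_cases_without_person_time_is_data_error(self):
        pt = person_time(_births([("A", 2004, 10)]), 2005)  # ages 0-1 only
        cases = pd.DataFrame(
            {
                "municipality_id": ["A"],
                "birth_year": [2004],
                "age_at_diagnosis": [9],
                "subtype": ["AML"],
            }
        )
        with pytest.raises(DataError):
            reference_rates(cases, pt)

    def test_outcome_filter(self):
        births = _births([("A", 1990, 100)])
        pt = person_time(births, 2010)
        pt_grouped = person_time(births, 2010, age_scheme="grouped_aml")
        cases = pd.DataFrame(
            {
                "municipality_id": ["A", "A"],
                "birth_year": [1990, 1990],
                "age_at_diagnosis": [2, 2],
                "subtype": ["AML", "BCP_ALL"],
            }
        )
        assert reference_rates(cases, pt_grouped, "AML", "grouped_aml")[
            "1-4"
        ] == pytest.approx(1 / 400)
        assert reference_rates(cases, pt, "ALL")["2"] == pytest.approx(1 / 100)
        assert reference_rates(cases, pt, "AL")["2"] == pytest.approx(2 / 100)

    def test_scheme_mismatch_rejected(self):
        from ecosir.errors import UsageError

        pt = person_time(_births([("A", 1990, 100)]), 2010)  # one-year classes
        cases = pd.DataFrame(
            {
                "municipality_id": ["A"],
                "birth_year": [1990],
                "age_at_diagnosis": [2],
                "subtype": ["AML"],
            }
        )
        with pytest.raises(UsageError, match="age scheme"):
            reference_rates(cases, pt, "AML", "grouped_aml")


class TestExpectedCounts:
    def test_zero_rates_give_zero_expectation(self):
        pt = person_time(_births([("A", 1990, 50)]), 2010)
        rates = pd.Series(0.0, index=[str(a) for a in range(15)])
        exp = expected_counts(pt, rates)
        assert (exp["expected"] == 0).all()

    def test_matches_independent_summation(self, rng):
        rows = [
            (f"M{i % 4}", int(1990 + i % 6), int(rng.integers(1, 80)))
            for i in range(40)
        ]
        end = 2001
        pt = person_time(_births(rows), end)
        rates = pd.Series(
            rng.uniform(0, 1e-3, 15), index=[str(a) for a in range(15)]
        )
        exp = expected_counts(pt, rates)
        # oracle: direct double loop over births and ages
        brute: dict[str, float] = {}
        for mid, year, n in rows:
            for a in range(15):
                if year + a <= end:
                    brute[mid] = brute.get(mid, 0.0) + n * rates[str(a)]
        got = exp.groupby("municipality_id")["expected"].sum().to_dict()
        assert got == pytest.approx(brute)

    def test_single_municipality_absorbs_national_total(self):
        births = _births([("ONLY", 1990, 500)])
        pt = person_time(births, 2010)
        cases = pd.DataFrame(
            {
                "municipality_id": ["ONLY"] * 7,
                "birth_year": [1990] * 7,
                "age_at_diagnosis": [1, 1, 2, 3, 5, 8, 13],
                "subtype": ["BCP_ALL"] * 7,
            }
        )
        rates = reference_rates(cases, pt)
        exp = expected_counts(pt, rates)
        assert exp["expected"].sum() == pytest.approx(7.0)


class TestConservation:
    @pytest.mark.parametrize("outcome", ["AL", "ALL", "AML"])
    def test_sum_expected_equals_sum_observed(self, desk_dataset, desk_spec, outcome):
        """Internal standardization conserves totals per outcome."""
        cfg = desk_spec.run_config(outcome=outcome)
        cells = build_cells(desk_dataset, cfg)
        n_cases = desk_dataset.cases["subtype"].isin(
            {"AL": set(["AL", "ALL", "BCP_ALL", "AML"]), "ALL": {"ALL", "BCP_ALL"}, "AML": {"AML"}}[outcome]
        ).sum()
        assert cells["observed"].sum() == n_cases
        assert cells["expected"].sum() == pytest.approx(n_cases, rel=1e-9)


class TestAnnualSir:
    def test_homogeneous_rates_give_sirs_near_one(self, desk_dataset, desk_spec):
        table = annual_sir(desk_dataset, desk_spec.run_config())
        assert len(table) == 10
        # pooled internal rates: birth-year SIRs scatter around 1
        assert table["SIR"].mean() == pytest.approx(1.0, abs=0.15)

    def test_planted_hot_year_is_recovered(self):
        """Doubling the rate in one birth year doubles that year's SIR."""
        spec = SimulationSpec(seed=7, n_municipalities=800, mean_births=150.0)
        ds, _ = simulate_dataset(spec)
        hot = 1994
        extra = ds.cases[ds.cases["birth_year"] == hot]
        ds_hot = Dataset(
            ds.municipalities,
            ds.censuses,
            ds.births,
            pd.concat([ds.cases, extra], ignore_index=True),
        )
        table = annual_sir(ds_hot, spec.run_config()).set_index("birth_year")
        others = table.drop(index=hot)
        # the hot year roughly doubles relative to the others
        assert table.loc[hot, "SIR"] > 1.5 * others["SIR"].mean()
        assert table.loc[hot, "ci_low"] > 1.0

    def test_year_without_cases_has_sir_zero_and_no_ci(self):
        births = _births([("A", 1990, 500), ("A", 1991, 500)])
        cases = pd.DataFrame(
            {
                "municipality_id": ["A"],
                "birth_year": [1990],
                "age_at_diagnosis": [2],
                "subtype": ["BCP_ALL"],
            }
        )
        mun = pd.DataFrame(
            {
                "municipality_id": ["A"],
                "area_km2": [10.0],
                "urban_unit_class": ["other_uu"],
                "uv_class": ["low"],
                "deprivation_class": ["Q1_Q4"],
                "population_size_class": ["uu_le_100k"],
            }
        )
        ds = Dataset(mun, pd.DataFrame(columns=["municipality_id", "census_year", "crop_type", "crop_area_km2"]), births, cases)
        cfg = RunConfig(
            birth_years=(1990, 1991),
            study_end_year=2005,
            census_period_map={1988: (1990, 1991)},
        )
        table = annual_sir(ds, cfg).set_index("birth_year")
        assert table.loc[1991, "observed"] == 0
        assert table.loc[1991, "SIR"] == 0.0
        assert np.isnan(table.loc[1991, "ci_low"])


class TestBuildCells:
    def test_cells_cover_every_municipality_period(self, tiny_dataset, tiny_config):
        cells = build_cells(tiny_dataset, tiny_config)
        assert len(cells) == 6
        assert cells["observed"].sum() == 1
        assert cells["expected"].sum() == pytest.approx(1.0, rel=1e-12)
        # B has births only in period 1
        b2 = cells.query("municipality_id == 'B' and birth_period == '1993-1995'")
        assert b2["expected"].iloc[0] == 0.0

    def test_observed_without_person_time_raises(self, tiny_dataset, tiny_config):
        broken = tiny_dataset.copy()
        broken.cases.loc[0, "municipality_id"] = "B"
        broken.cases.loc[0, "birth_year"] = 1993  # B has no births in 1993-1995
        with pytest.raises(DataError, match="B/1993-1995"):
            build_cells(broken, tiny_config)
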