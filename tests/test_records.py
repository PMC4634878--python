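"""Record reading, cleaning, deduplication, and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from countyrisk.records import (
    Armed,
    Race,
    SchemaError,
    DataConsistencyError,
    ShootingRecord,
    aggregate_counts,
    clean_records,
    deduplicate,
    read_census,
    read_covariates,
    read_records,
    COVARIATE_COLUMNS,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadRecords:
    def test_empty_data_section(self, tmp_path):
        p = _write(tmp_path, "r.csv", "name,year,race,armed,fips\n")
        assert read_records(p) == []

    def test_enum_mapping_and_fips_padding(self, tmp_path):
        p = _write(
            tmp_path, "r.csv",
            "name,year,race,armed,fips,age\n"
            "John Doe,2012,black,yes,1001,34\n"
            "A B,2013,Hispanic,unarmed,06037,\n"
            "C D,2014,martian,maybe,,19\n",
        )
        recs = read_records(p)
        assert recs[0].race is Race.B and recs[0].armed is Armed.ARMED
        assert recs[0].county_fips == "01001"
        assert recs[1].race is Race.H and recs[1].armed is Armed.UNARMED
        # unparseable fields degrade to UNKNOWN/missing, never dropped
        assert recs[2].race is Race.UNKNOWN and recs[2].armed is Armed.UNKNOWN
        assert recs[2].county_fips is None and len(recs) == 3

    def test_out_of_window_year_retained_at_read_time(self, tmp_path):
        p = _write(tmp_path, "r.csv", "name,year,race,armed,fips\nX Y,2010,white,no,01001\n")
        recs = read_records(p)
        assert len(recs) == 1 and recs[0].year == 2010

    def test_year_from_date_column(self, tmp_path):
        p = _write(tmp_path, "r.csv", "name,date,race,armed,fips\nX Y,2013-05-17,w,armed,01001\n")
        assert read_records(p)[0].year == 2013

    def test_missing_required_column_names_it(self, tmp_path):
        p = _write(tmp_path, "r.csv", "name,year,armed,fips\nX,2012,yes,01001\n")
        with pytest.raises(SchemaError, match="race"):
            read_records(p)

    def test_state_county_lookup(self, tmp_path):
        p = _write(tmp_path, "r.csv", "name,year,race,armed,state,county\nX Y,2012,b,yes,FL,Dade\n")
        lookup = pd.DataFrame({"state": ["FL"], "county": ["Dade"], "fips": ["12086"]})
        assert read_records(p, county_lookup=lookup)[0].county_fips == "12086"


class TestCleanRecords:
    def _valid(self, **kw):
        base = dict(victim_name="A B", year=2012, race=Race.B,
                    armed=Armed.UNARMED, county_fips="01001", age=30)
        base.update(kw)
        return ShootingRecord(**base)

    def test_year_window(self):
        kept, report = clean_records([self._valid(year=2010), self._valid(year=2015)])
        assert kept == [] and report.year_out_of_range == 2

    def test_rule_counters_and_retention(self):
        records = [
            self._valid(),
            self._valid(race=Race.OTHER),
            self._valid(armed=Armed.UNKNOWN),
            self._valid(county_fips=None),
        ]
        kept, report = clean_records(records)
        assert kept == [records[0]]
        assert (report.race_excluded, report.armed_unknown, report.missing_county) == (1, 1, 1)
        assert report.n_input == 4 and report.n_kept == 1 and report.n_dropped == 3

    def test_valid_record_unchanged(self):
        rec = self._valid()
        kept, _ = clean_records([rec])
        assert kept[0] is rec


class TestDeduplicate:
    def _rec(self, name, year=2012, age=30, race=Race.B, fips="01001"):
        return ShootingRecord(victim_name=name, year=year, race=race,
                              armed=Armed.UNARMED, county_fips=fips, age=age)

    def test_exact_normalized_name_same_place_year(self):
        kept, dropped = deduplicate([self._rec("John Doe"), self._rec("john  doe")])
        assert len(kept) == 1 and dropped == 1

    def test_spelling_variation_with_matching_attributes(self):
        kept, dropped = deduplicate([self._rec("Jon Doe"), self._rec("John Doe")])
        assert len(kept) == 1 and dropped == 1
        assert kept[0].victim_name == "Jon Doe"  # first occurrence wins

    def test_same_name_different_year_and_county_kept(self):
        a = self._rec("John Doe", year=2012, fips="01001")
        b = self._rec("John Doe", year=2013, fips="02002")
        kept, dropped = deduplicate([a, b])
        assert len(kept) == 2 and dropped == 0

    def test_distant_names_not_fuzzy_collapsed(self):
        kept, _ = deduplicate([self._rec("John Doe"), self._rec("Maria Gonzalez")])
        assert len(kept) == 2

    @given(st.lists(st.sampled_from(["Jon Doe", "John Doe", "Maria Li", "J Doe"]),
                    max_size=8))
    def test_idempotent(self, names):
        records = [self._rec(n) for n in names]
        once, _ = deduplicate(records)
        twice, dropped_again = deduplicate(once)
        assert dropped_again == 0 and twice == once


class TestAggregateCounts:
    census = pd.DataFrame({
        "fips": ["12086", "06037"],
        "N_B": [400_000, 800_000], "N_H": [1_500_000, 4_700_000],
        "N_W": [380_000, 2_700_000],
    })

    def _rec(self, fips, race=Race.B, armed=Armed.UNARMED):
        return ShootingRecord(victim_name="X", year=2012, race=race,
                              armed=armed, county_fips=fips, age=30)

    def test_counting(self):
        result = aggregate_counts([self._rec("12086")] * 3, self.census)
        row = result.counts.iloc[0]
        assert row["S_BU"] == 3
        assert row[["S_BA", "S_HU", "S_HA", "S_WU", "S_WA"]].sum() == 0
        assert row["N_B"] == 400_000

    def test_uncovered_county_reported_not_aggregated(self):
        result = aggregate_counts([self._rec("99999"), self._rec("12086")], self.census)
        assert result.uncovered == {"99999": 1}
        assert list(result.counts["fips"]) == ["12086"]

    def test_empty_records(self):
        assert aggregate_counts([], self.census).counts.empty

    def test_count_exceeding_population_raises(self):
        census = pd.DataFrame({"fips": ["12086"], "N_B": [2], "N_H": [10], "N_W": [10]})
        with pytest.raises(DataConsistencyError, match="12086"):
            aggregate_counts([self._rec("12086")] * 3, census)

    def test_round_trip_conservation(self):
        records = [self._rec("12086", r, a)
                   for r in (Race.B, Race.H, Race.W)
                   for a in (Armed.ARMED, Armed.UNARMED)
                   for _ in range(2)]
        cleaned, _ = clean_records(records)
        result = aggregate_counts(cleaned, self.census)
        S_total = result.counts.filter(like="S_").to_numpy().sum()
        assert S_total == len(records)


class TestCovariateIO:
    def test_census_roundtrip(self, tmp_path):
        p = _write(tmp_path, "c.csv",
                   "fips,pop_black,pop_hispanic,pop_white\n1001,10,20,30\n")
        df = read_census(p)
        assert df.loc[0, "fips"] == "01001" and df.loc[0, "N_H"] == 20

    def test_covariates_missing_cells_become_nan(self, tmp_path):
        header = "fips," + ",".join(COVARIATE_COLUMNS)
        p = _write(tmp_path, "cov.csv",
                   header + "\n01001,50000,12.5,41000,0.45,1.1,,3.2,1.0,2.0\n")
        df = read_covariates(p)
        assert np.isnan(df.loc[0, "assault_rate_W"])
        assert df.loc[0, "gini"] == 0.45

    def test_gini_bounds_enforced(self, tmp_path):
        header = "fips," + ",".join(COVARIATE_COLUMNS)
        p = _write(tmp_path, "cov.csv",
                   header + "\n01001,50000,12.5,41000,1.45,1.1,2.0,3.2,1.0,2.0\n")
        with pytest.raises(DataConsistencyError):
            read_covariates(p)
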