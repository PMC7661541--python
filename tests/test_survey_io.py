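import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from birdrisk import (
    MissingTraitError,
    RiskModelConfig,
    Season,
    SpeciesTrait,
    SurveySchemaError,
    Zone,
    aggregate_profiles,
    assign_season,
    read_survey,
    read_traits,
)

from conftest import make_record

HEADER = "species,family,order,unit,date,zone,count,height_m,group_size,crossed_runway\n"


def write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "survey.csv"
    path.write_text(header + "".join(r + "\n" for r in rows), encoding="utf-8")
    return path


class TestReadSurvey:
    def test_valid_rows_pass_through(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "tree sparrow,passeridae,passeriformes,A01,2019-04-15,A,10,12.0,5,false",
                "ruddy shelduck,anatidae,anseriformes,C03,2019-05-01,C,40,60,40,true",
                "common kestrel,falconidae,falconiformes,B02,2019-11-20,B,1,80,1,0",
            ],
        )
        result = read_survey(path)
        assert len(result.records) == 3
        assert not result.rejected
        assert result.records[0].zone is Zone.A
        assert result.records[1].crossed_runway is True
        assert result.records[2].date == dt.date(2019, 11, 20)

    def test_unknown_zone_rejected_with_reason(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "tree sparrow,passeridae,passeriformes,A01,2019-04-15,D,10,12.0,5,false",
                "tree sparrow,passeridae,passeriformes,A01,2019-04-15,A,10,12.0,5,false",
            ],
        )
        result = read_survey(path)
        assert len(result.records) == 1
        assert len(result.rejected) == 1
        assert result.rejected[0].row_number == 1
        assert "zone" in result.rejected[0].reason.lower()

    def test_unparseable_number_and_date_rejected_row_level(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "x,f,o,A01,2019-04-15,A,ten,12.0,5,false",
                "x,f,o,A01,April,A,10,12.0,5,false",
            ],
        )
        result = read_survey(path)
        assert result.records == []
        assert [r.row_number for r in result.rejected] == [1, 2]

    def test_header_only_file_yields_empty_list(self, tmp_path):
        result = read_survey(write_csv(tmp_path, []))
        assert result.records == [] and result.rejected == []

    def test_missing_column_is_hard_error_naming_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,family,order,unit,date,zone,count\n", encoding="utf-8")
        with pytest.raises(SurveySchemaError, match="height_m"):
            read_survey(path)

    def test_schema_remapping(self, tmp_path):
        path = write_csv(
            tmp_path,
            ["tree sparrow,passeridae,passeriformes,A01,2019-04-15,A,10,12.0,5,false"],
            header="sp,family,order,unit,date,zone,count,height_m,group_size,crossed_runway\n",
        )
        result = read_survey(path, schema={"species_name": "sp"})
        assert result.records[0].species_name == "tree sparrow"


class TestReadTraits:
    def test_reads_and_flags(self, tmp_path):
        path = tmp_path / "traits.csv"
        path.write_text(
            "species,mass_g,is_raptor\ntree sparrow,20,false\nsteppe eagle,2800,true\n",
            encoding="utf-8",
        )
        traits = read_traits(path)
        assert [t.is_raptor for t in traits] == [False, True]

    def test_duplicate_species_rejected(self, tmp_path):
        path = tmp_path / "traits.csv"
        path.write_text(
            "species,mass_g,is_raptor\nx,20,false\nx,25,false\n", encoding="utf-8"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_traits(path)


@pytest.mark.parametrize(
    "date,expected",
    [
        (dt.date(2019, 4, 15), Season.spring),
        (dt.date(2019, 12, 1), Season.winter),
        (dt.date(2019, 8, 31), Season.summer),
        (dt.date(2019, 2, 28), Season.winter),
        (dt.date(2019, 9, 1), Season.autumn),
    ],
)
def test_assign_season_default_scheme(date, expected):
    assert assign_season(date) is expected


class TestAggregateProfiles:
    def test_aggregation_over_two_records(self, sparrow_trait):
        records = [
            make_record(count=5, group_size=2, zone=Zone.B, flight_height_m=10,
                        date=dt.date(2019, 4, 1)),
            make_record(count=10, group_size=7, zone=Zone.C, flight_height_m=30,
                        date=dt.date(2019, 12, 5), crossed_runway=True),
        ]
        (profile,) = aggregate_profiles(records, [sparrow_trait])
        assert profile.total_count == 15
        assert profile.total_biomass_g == 15 * 20.0
        assert profile.max_cluster_size == 7
        assert profile.nearest_zone is Zone.B  # recorded in B and C only
        assert profile.runway_crossings == 1
        assert profile.seasons_present == frozenset({Season.spring, Season.winter})

    def test_max_cluster_over_three_records(self, sparrow_trait):
        records = [make_record(count=50, group_size=g) for g in (2, 40, 7)]
        (profile,) = aggregate_profiles(records, [sparrow_trait])
        assert profile.max_cluster_size == 40

    def test_missing_trait_raises_listing_species(self, sparrow_trait):
        records = [make_record(), make_record(species_name="unknown bird")]
        with pytest.raises(MissingTraitError, match="unknown bird"):
            aggregate_profiles(records, [sparrow_trait])

    def test_weighted_median_height(self, sparrow_trait):
        # heights 10 (weight 1) and 50 (weight 9): weighted median is 50
        records = [
            make_record(count=1, group_size=1, flight_height_m=10.0),
            make_record(count=9, group_size=9, flight_height_m=50.0),
        ]
        (profile,) = aggregate_profiles(records, [sparrow_trait])
        assert profile.representative_flight_height_m == 50.0

    def test_mean_height_option(self, sparrow_trait):
        records = [
            make_record(count=1, group_size=1, flight_height_m=10.0),
            make_record(count=3, group_size=3, flight_height_m=50.0),
        ]
        config = RiskModelConfig(height_statistic="mean")
        (profile,) = aggregate_profiles(records, [sparrow_trait], config)
        assert profile.representative_flight_height_m == pytest.approx(40.0)

    def test_permutation_invariance_and_count_conservation(self, sparrow_trait):
        records = [
            make_record(count=c, group_size=min(c, 5), zone=z, flight_height_m=h)
            for c, z, h in [(3, Zone.C, 5), (8, Zone.A, 45), (2, Zone.B, 90)]
        ]
        forward = aggregate_profiles(records, [sparrow_trait])
        backward = aggregate_profiles(records[::-1], [sparrow_trait])
        assert forward == backward
        assert forward[0].total_count == sum(r.count for r in records)

    @settings(deadline=None, max_examples=50)
    @given(zones=st.lists(st.sampled_from(list(Zone)), min_size=1, max_size=8))
    def test_record_in_zone_a_forces_nearest_zone_a(self, zones):
        trait = SpeciesTrait(species_name="tree sparrow", mean_body_mass_g=20.0)
        records = [make_record(zone=z) for z in zones] + [make_record(zone=Zone.A)]
        (profile,) = aggregate_profiles(records, [trait])
        assert profile.nearest_zone is Zone.A
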