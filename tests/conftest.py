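import datetime as dt

import pytest

from birdrisk import SpeciesProfile, SpeciesTrait, SurveyRecord, Zone


def make_record(**overrides) -> SurveyRecord:
    base = dict(
        species_name="tree sparrow",
        family="passeridae",
        order="passeriformes",
        survey_unit_id="A01",
        date=dt.date(2019, 4, 15),
        zone=Zone.A,
        count=10,
        flight_height_m=12.0,
        group_size=5,
        crossed_runway=False,
    )
    base.update(overrides)
    return SurveyRecord(**base)


def make_profile(**overrides) -> SpeciesProfile:
    base = dict(
        species_name="tree sparrow",
        family="passeridae",
        order="passeriformes",
        total_count=100,
        total_biomass_g=2000.0,
        representative_flight_height_m=12.0,
        max_cluster_size=30,
        nearest_zone=Zone.A,
        is_raptor=False,
        runway_crossings=0,
        seasons_present=frozenset(),
    )
    base.update(overrides)
    return SpeciesProfile(**base)


@pytest.fixture
def sparrow_trait() -> SpeciesTrait:
    return SpeciesTrait(species_name="tree sparrow", mean_body_mass_g=20.0)
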