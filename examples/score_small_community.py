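"""Score a hand-built three-species community.

Builds survey records for a flocking sparrow, a heavy shelduck and a
kestrel, aggregates them, assigns the five risk factors and prints each
species' likelihood/severity scores and danger level.
"""

import datetime as dt

from birdrisk import (
    SpeciesTrait,
    SurveyRecord,
    Zone,
    aggregate_profiles,
    score_community,
)

records = [
    # tree sparrows: abundant, flocking, low over the airfield
    SurveyRecord("tree sparrow", "passeridae", "passeriformes", "A01",
                 dt.date(2019, 4, 10), Zone.A, count=120, flight_height_m=12,
                 group_size=60),
    SurveyRecord("tree sparrow", "passeridae", "passeriformes", "A02",
                 dt.date(2019, 10, 3), Zone.A, count=80, flight_height_m=8,
                 group_size=40),
    # ruddy shelducks: heavy waterfowl at approach height in the outer belt
    SurveyRecord("ruddy shelduck", "anatidae", "anseriformes", "C04",
                 dt.date(2019, 5, 2), Zone.C, count=35, flight_height_m=45,
                 group_size=35),
    # a kestrel hunting over the runway, seen crossing it repeatedly
    SurveyRecord("common kestrel", "falconidae", "falconiformes", "A01",
                 dt.date(2019, 6, 21), Zone.A, count=1, flight_height_m=40,
                 group_size=1, crossed_runway=True),
    SurveyRecord("common kestrel", "falconidae", "falconiformes", "A01",
                 dt.date(2019, 7, 5), Zone.A, count=1, flight_height_m=35,
                 group_size=1, crossed_runway=True),
    SurveyRecord("common kestrel", "falconidae", "falconiformes", "A03",
                 dt.date(2019, 8, 12), Zone.A, count=1, flight_height_m=50,
                 group_size=1, crossed_runway=True),
]

traits = [
    SpeciesTrait("tree sparrow", mean_body_mass_g=20),
    SpeciesTrait("ruddy shelduck", mean_body_mass_g=1300),
    SpeciesTrait("common kestrel", mean_body_mass_g=200, is_raptor=True),
]

profiles = aggregate_profiles(records, traits)
factors, scores = score_community(profiles)

for profile in profiles:
    f, s = factors[profile.species_name], scores[profile.species_name]
    print(f"{profile.species_name:16s} "
          f"cn={f.comparative_number:.2f} cw={f.comparative_weight:.2f} "
          f"h={f.flight_height_coeff} c={f.cluster_coeff} a={f.activity_coeff} "
          f"L={s.likelihood:5.1f} ({s.likelihood_band.value:9s}) "
          f"S={s.severity:5.1f} ({s.severity_band.value:9s}) "
          f"level {s.base_level}->{s.adjusted_level} {s.adjustments_applied}")

print()
print("Likelihood bands combine flock size, flight height and activity zone;")
print("severity bands combine relative abundance and biomass. The kestrel's")
print("level is raised by the raptor rule and its >=3 runway crossings.")
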