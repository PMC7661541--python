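"""Cross-check a classification against a historical strike-record list.

Scores a simulated community, takes its level-3 (high danger) species and
compares them - by species name, then by family - with a small synthetic
strike-record list, printing the overlap fractions.
"""

from birdrisk import (
    CommunitySpec,
    StrikeRecord,
    StrikeRecordList,
    aggregate_profiles,
    overlap,
    score_community,
    simulate,
)

community, records = simulate(CommunitySpec(n_species=60, seed=3))
profiles = aggregate_profiles(records, community.traits)
_, scores = score_community(profiles)
high_danger = [p for p in profiles if scores[p.species_name].adjusted_level == 3]
print(f"{len(high_danger)} of {len(profiles)} species classified high danger")

# synthetic strike list: two of the high-danger species by name, plus some
# family-level entries covering common hazard families
strikes = StrikeRecordList(entries=[
    StrikeRecord(family=high_danger[0].family, species_name=high_danger[0].species_name),
    StrikeRecord(family="anatidae"),
    StrikeRecord(family="accipitridae"),
    StrikeRecord(family="columbidae"),
    StrikeRecord(family="passeridae"),
])

result = overlap(high_danger, strikes)
print(f"species-level matches: {result.species_matches}")
print(f"family-level matches:  {result.family_matches}")
print(f"species fraction {result.species_fraction:.2f}, "
      f"family fraction {result.family_fraction:.2f}")
print("\nA high joint fraction means the species the model flags are the")
print("ones (or relatives of the ones) that historically struck aircraft.")
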