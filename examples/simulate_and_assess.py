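"""Simulate a year of airport surveys and assess the whole community.

Generates a 118-species synthetic community surveyed monthly at 39 units
(468 unit-visits), runs the full scoring pipeline and prints the danger
level breakdown and the per-season species counts at each level.
"""

from birdrisk import (
    CommunitySpec,
    Season,
    aggregate_profiles,
    build_report,
    score_community,
    simulate,
)

community, records = simulate(CommunitySpec(n_species=118, seed=7))
profiles = aggregate_profiles(records, community.traits)
factors, scores = score_community(profiles)
report = build_report(profiles, factors, scores)

print(f"{len(records)} survey records, {len(profiles)} species")
for level in (3, 2, 1):
    print(f"level {level}: {report.level_counts[level]:3d} species "
          f"({report.level_percentages[level]}%)")

print("\nspecies present per season, by danger level:")
print(f"{'':8s}" + "".join(f"{s.value:>8s}" for s in Season))
for level in (3, 2, 1):
    row = "".join(
        f"{report.seasonal_counts[(season, level)]:8d}" for season in Season
    )
    print(f"level {level} {row}")

print("\nLevel-3 species are the ones a wildlife hazard manager would target")
print("first; the seasonal table shows when each danger class is present.")
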