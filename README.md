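# birdrisk

Birdstrike risk scoring for airport wildlife hazard management.

Collisions between aircraft and birds cluster around take-off and landing,
and the hazard is very unevenly distributed across the bird community: a
flock of heavy waterfowl at approach height over the airfield is a
different problem from a solitary lark high above the outer buffer. Many
airports, however, have no usable historical strike database to calibrate
a statistical risk model. `birdrisk` implements a survey-driven
alternative: everything it needs comes from standard line-transect /
point-count bird surveys of the airport (zone A), a 4 km belt around it
(zone B) and a 4–8 km belt (zone C), plus a species trait table (mean body
mass, raptor flag).

## The model

For each species *i*, five factors are assigned from the survey aggregate:

- **comparative number** `cn_i = N_i / max_j N_j` — total individuals
  relative to the most abundant species;
- **comparative weight** `cw_i = B_i / max_j B_j` — total biomass
  (`N_i × mean mass`) relative to the heaviest species total;
- **flight-height coefficient** `f` — a step function peaking at 1 in the
  30–50 m band (critical take-off/landing height ≈ 40 m), 0.5 in the
  5–30 m and 50–100 m bands, 0.1 below 5 m or above 100 m (upper bounds
  inclusive);
- **cluster coefficient** `c` — 0 for groups of 1–2, 0.2 for 3–19,
  0.5 for 20–99, 1 for ≥ 100;
- **activity coefficient** `a` — 0.9 / 0.6 / 0.3 for nearest recorded
  zone A / B / C.

These combine into two 0–100 scores,

```
likelihood = (c + f + a) × 100 / 3
severity   = (cn + cw)   × 100 / 2
```

each rated into five ordinal bands (likelihood thresholds 15/30/50/70;
severity 4/7/14/40). A validated-monotone 5×5 matrix maps the band pair to
a danger level — 1 (low), 2 (moderate) or 3 (high) — and two rules can each
raise the level by one, capped at 3: the species is a raptor, or it was
seen crossing/overflying the runway at least three times.

The package also ships a synthetic survey generator (39 units × 12 monthly
visits = 468 unit-visits over a guild-structured community) used for
end-to-end testing, a reporting module (level shares, per-season species
counts, CSV/JSON reports with the configuration embedded), and a
cross-check of the high-danger list against a historical strike-record
table at species and family level.

## Worked example

```
python examples/score_small_community.py
```

```
common kestrel   cn=0.01 cw=0.01 h=1.0 c=0.0 a=0.9 L= 63.3 (high     ) S=  1.4 (very_low ) level 2->3 ['raptor', 'runway_crossing']
ruddy shelduck   cn=0.17 cw=1.00 h=1.0 c=0.5 a=0.3 L= 60.0 (high     ) S= 58.8 (very_high) level 3->3 []
tree sparrow     cn=1.00 cw=0.09 h=0.5 c=0.5 a=0.9 L= 63.3 (high     ) S= 54.4 (very_high) level 3->3 []
```

The sparrow flock dominates abundance (`cn=1.00`) and the shelducks
dominate biomass (`cw=1.00`), so both land in the very-high severity band
and classify as high danger. The kestrel is light and solitary (severity
band very low, base level 2) but hunts at critical height over the runway:
the raptor rule and its three observed runway crossings raise it to
level 3 — exactly the under-weighting the adjustment rules exist to fix.

Other entry points: `examples/simulate_and_assess.py` (full synthetic
pipeline with seasonal breakdown), `examples/strike_record_crosscheck.py`
(validation against strike records), and the `birdrisk` CLI with
`assess`, `simulate` and `crosscheck` subcommands.

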