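# Methods

## Scoring pipeline

The unit of analysis is the species-by-survey-period aggregate
(`SpeciesProfile`). Survey records are validated row by row (unknown
zones, unparseable dates/numbers are rejected with row numbers and
reasons; a missing column aborts the read) and collapsed per species:

- `total_count` — raw sum of sighting counts. No survey-effort
  normalization is applied: the comparative factors are ratios over the
  same survey design, so a constant effort factor cancels. This assumes
  the whole community was surveyed with the same protocol.
- `total_biomass_g` — `total_count × mean individual body mass` from the
  trait table. The trait table is the single source of masses; a missing
  species is a hard error rather than an imputation.
- `representative_flight_height_m` — count-weighted median of sighting
  heights (lower median on ties). The median is robust to single extreme
  sightings; a count-weighted mean is available via
  `height_statistic="mean"`.
- `max_cluster_size` — maximum observed group size (risk-conservative: a
  species that can flock in hundreds is hazardous even if it usually does
  not); a quantile of observed group sizes is available via
  `cluster_statistic`.
- `nearest_zone` — minimum over recorded zones in the order A < B < C.
- `seasons_present` — seasons of its records under a configurable
  month-to-season scheme (default Mar–May spring, Jun–Aug summer, Sep–Nov
  autumn, Dec–Feb winter).

Classification is annual: one level per species per surveyed year, with
seasonal *presence* reported alongside rather than per-season re-scoring.
Re-scoring by season would change the comparative factors' denominators
with the thinnest data and make levels incommensurable across seasons.

## Factor scale

The two comparative factors are kept as fractions in [0, 1] and the ×100
scaling is applied exactly once, inside the severity formula. Applying
×100 both in the factor definitions and in the severity combination (as a
literal reading of the printed formulas would) puts severity on a 0–10,000
scale, which no 0–100 severity band table can rate; the single-scaling
reading is the only one consistent with the band thresholds.

`comparative_weight` reads "weight of all birds of a single species" as
*total observed biomass* over the survey period; a per-individual-mass
variant is available (`weight_basis="individual_mass"`) for communities
where totals are dominated by effort artefacts.

## Step coefficients and bands

The flight-height and cluster tables are implemented exactly as printed,
with upper-inclusive boundaries (H = 50 → 1, H = 100 → 0.5, N = 20 → 0.5,
N = 3 → 0.2). The printed cluster table does not assign N = 100
("N > 100" vs "100 > N ≥ 20"); the gap is closed upward (N ≥ 100 → 1),
the risk-conservative choice. Both lookups are tested against
independently transcribed if-chains over exhaustive integer grids.

Score bands are continuous half-open intervals `[lo, hi)` with the top
band closed at 100. The published integer ranges ("0–14", "15–29") leave
non-integer scores such as 14.5 unassigned; the half-open reading assigns
every score in [0, 100] and agrees with the printed ranges at every
integer.

## The risk matrix

The original matrix cell assignments exist only as a figure, so the 5×5
matrix is a **required, validated configuration with a shipped
reconstruction**: level = 3 where the two band ordinals (1–5 each) sum to
≥ 8, level = 2 for sums 5–7, level = 1 otherwise. This is the simplest
rule that is monotone along both axes and pins both extreme corners to
the extreme levels. Any user matrix must be 5×5 over {1,2,3} and monotone
non-decreasing in both band directions; reports embed the matrix actually
used so a classification is always auditable.

The two adjustment rules stack (a raptor with ≥ 3 runway crossings gains
two levels) and are capped at level 3; each applied rule is named in the
output. The crossing rule triggers at ≥ 3 observed crossings (the source
wording alternates between "three times" and "more than three times");
the threshold is configurable. "Raptor" is a trait-table flag rather than
a taxonomic rule, since raptor status is an input judgement, not
derivable from the survey.

## Reporting

Level percentages are rounded half-up to one decimal. Note one known
discrepancy with the published narrative this package's structure follows:
20 of 118 species is 16.949…%, which rounds to 16.9%, while the narrative
prints 17.0%. The package reports the correctly rounded value.

## Synthetic data

The generator emulates a year of monthly surveys at 39 transect/point
units (7 in zone A, 20 in B, 12 in C; 468 unit-visits). A community
(default 118 species) is drawn from four guilds — songbird, waterfowl,
raptor, terrestrial (default shares 0.65/0.15/0.08/0.12) — with
guild-specific lognormal flight heights (medians 8/45/60/2.5 m),
log-uniform latent maximal cluster sizes (up to ~100 for songbirds, ~200
for waterfowl, ≤ 3 for raptors), lognormal body masses clipped to
10 g–12 kg (waterfowl shifted heavier), a lognormal per-species abundance
multiplier driving encounter rates and per-sighting counts, random zone
occupancy (core-zone probabilities 0.15/0.35/0.5 for A/B/C, with outward
extensions), and four seasonal-presence patterns (residents, passage
migrants, summer and winter visitors). These defaults were fixed once to
give a realistic low-danger-dominated community at the emulated scale;
no level split is asserted anywhere.

Group sizes are drawn per sighting between 1 and the species' latent
maximum, hitting the maximum with probability 0.3; in addition, one
"characteristic flock" record per present season is guaranteed in each
species' nearest zone whenever that season is surveyed there — the
monthly protocol is assumed intensive enough to register every regular
species at its typical aggregation in its core area. This guarantee is
what makes the latent nearest zone exactly recoverable and the latent
cluster band recoverable at high accuracy through the pipeline; it is a
statement about the simulated protocol's completeness, not about real
surveys, which suffer detection error the generator deliberately omits
(along with movement ecology and weather). Passing recovery tests
therefore show the *pipeline* preserves the latent structure the surveys
contain, not that real surveys contain it.

Two extreme species can be planted: a maximal-risk one whose records are
constructed after the rest of the community so that it provably dominates
both total count and total biomass (zone A, 40 m, flocks of 150, runway
crossings every visit), and a minimal-risk one (one solitary 10 g bird at
200 m in zone C). Under any monotone matrix with the default bands they
must classify at levels 3 and 1; this is the end-to-end sanity check used
in place of an unavailable real survey table.

## Numerical and degenerate-input choices

- Coefficient-set membership in the likelihood formula is checked with an
  absolute tolerance of 1e-9 (the sets are exact decimals).
- A community whose counts (or biomass totals) are all zero is a hard
  error: comparative factors are undefined without a maximum.
- Weighted medians with all-zero weights fall back to the unweighted
  median; a zero-count sighting still marks presence, zone and season.
- Ties for the community maximum leave every tied species at factor 1.
- Name matching in the cross-check is case-folded and
  whitespace-collapsed, with an optional synonym map applied after
  normalization; family matches are only counted for species not already
  matched by name, so the two match sets are disjoint.

## Problem sizes

The test suite simulates communities of 20–118 species; the acceptance
script runs 20 independent 118-species survey years (~3 s total) plus
exhaustive lookups over integer grids (0–200 m heights, 1–200 cluster
sizes) and a 10,001-point band scan. These sizes fully exercise every
code path while keeping the whole suite under ten seconds.

## Known limitations

- The shipped matrix is a reconstruction; classifications near band
  boundaries can differ from the original instrument's.
- Annual classification hides within-year turnover beyond the seasonal
  presence table.
- No detectability or effort correction: comparative factors inherit any
  detection bias present in the survey data.
- The strike-record cross-check is name-based; without a synonym table,
  vernacular mismatches ("pigeons" vs "rock pigeon") fall through to the
  family level.
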