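"""Synthetic bird communities and survey tables.

Emulates a year-long airport bird survey: 39 transect/point-count units
split over three zones (7 in the flight area A, 20 in the 4 km belt B,
12 in the 4-8 km belt C), each visited monthly, i.e. 468 unit-visits per
default year. Species are drawn from four broad guilds (songbird,
waterfowl, raptor, terrestrial) with guild-specific flight heights and
group-size scales, lognormal body masses and abundances, random zone
occupancy, and seasonal presence patterns (residents, passage migrants,
summer and winter visitors).

The generator returns the latent per-species truth (typical flight height,
maximal cluster size, nearest occupied zone, seasons) alongside the trait
table, so recovery of the latent structure through the aggregation and
scoring pipeline can be tested. Species are reliably detectable in their
nearest zone: at least one record per present season is guaranteed there
whenever the simulated months cover that season, mimicking a survey design
with enough monthly effort to register every regular species in its core
area. Two extreme species can be planted for end-to-end checks: a
maximal-risk one (most abundant, heaviest total biomass, 40 m flight
height, clusters above 100, zone A, frequent runway crossings) and a
minimal-risk one (a single solitary, light, high-flying zone-C sighting).

Detection error, movement ecology and weather are deliberately absent;
abundance differences show up only through encounter rates, group sizes
and per-sighting counts.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .models import Season, SpeciesTrait, SurveyRecord, Zone
from .risk_factors import cluster_coeff

#: survey units per zone (7 + 20 + 12 = 39)
DEFAULT_UNITS_PER_ZONE: dict[Zone, int] = {Zone.A: 7, Zone.B: 20, Zone.C: 12}

GUILDS = ("songbird", "waterfowl", "raptor", "terrestrial")

_SEASON_OF_MONTH = {
    3: Season.spring, 4: Season.spring, 5: Season.spring,
    6: Season.summer, 7: Season.summer, 8: Season.summer,
    9: Season.autumn, 10: Season.autumn, 11: Season.autumn,
    12: Season.winter, 1: Season.winter, 2: Season.winter,
}

MAX_RISK_SPECIES = "planted maximal-risk species"
MIN_RISK_SPECIES = "planted minimal-risk species"


@dataclass
class CommunitySpec:
    """Parameters of the synthetic community.

    Defaults emulate the scale of a 118-species airport community. Guild
    shares and distribution scales are round numbers chosen to span the
    realistic range (10 g passerines to multi-kilogram waterfowl, solitary
    raptors to flocks of hundreds).
    """

    n_species: int = 118
    seed: int = 0
    raptor_fraction: float = 0.08
    waterfowl_fraction: float = 0.15
    terrestrial_fraction: float = 0.12
    #: lognormal body mass (log-space mean/sd of grams), clipped to [10, 12000]
    mass_log_mean: float = np.log(80.0)
    mass_log_sd: float = 1.3
    #: lognormal per-species encounter-rate multiplier (abundance model)
    abundance_log_sd: float = 1.0
    plant_max_risk: bool = False
    plant_min_risk: bool = False

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        fractions = (
            self.raptor_fraction,
            self.waterfowl_fraction,
            self.terrestrial_fraction,
        )
        if any(not 0 <= f <= 1 for f in fractions) or sum(fractions) > 1:
            raise ValueError("guild fractions must be in [0,1] and sum to <= 1")
        if self.mass_log_sd <= 0 or self.abundance_log_sd < 0:
            raise ValueError("distribution scales must be positive")


@dataclass
class SpeciesTruth:
    """Latent ground truth of one synthetic species."""

    species_name: str
    family: str
    order: str
    guild: str
    mean_body_mass_g: float
    is_raptor: bool
    typical_height_m: float
    max_cluster_size: int
    occupied_zones: tuple[str, ...]
    nearest_zone: str
    seasons: tuple[str, ...]
    abundance: float

    @property
    def cluster_band_coeff(self) -> float:
        return cluster_coeff(self.max_cluster_size)


@dataclass
class Community:
    spec: CommunitySpec
    traits: list[SpeciesTrait]
    truth: list[SpeciesTruth]


# guild -> (log-median height m, log sd)
_HEIGHT_MODELS = {
    "songbird": (np.log(8.0), 0.8),
    "waterfowl": (np.log(45.0), 0.5),
    "raptor": (np.log(60.0), 0.6),
    "terrestrial": (np.log(2.5), 0.6),
}

# guild -> (low, high) of log10 latent maximal cluster size
_CLUSTER_MODELS = {
    "songbird": (0.0, 2.0),
    "waterfowl": (0.5, 2.3),
    "raptor": (0.0, 0.5),
    "terrestrial": (0.0, 0.8),
}

#: probability that a species' core (nearest) zone is A, B, C — most of the
#: community ranges in the outer belts rather than on the airfield itself
_NEAREST_ZONE_PROBS = (0.15, 0.35, 0.5)

_FAMILY_OF_GUILD = {
    "songbird": ("passeridae", "corvidae", "alaudidae", "motacillidae"),
    "waterfowl": ("anatidae", "ardeidae", "rallidae"),
    "raptor": ("accipitridae", "falconidae", "strigidae"),
    "terrestrial": ("phasianidae", "columbidae"),
}
_ORDER_OF_GUILD = {
    "songbird": "passeriformes",
    "waterfowl": "anseriformes",
    "raptor": "falconiformes",
    "terrestrial": "galliformes",
}

_SEASON_PATTERNS = (
    # (seasons, probability): residents, passage migrants, summer/winter visitors
    ((Season.spring, Season.summer, Season.autumn, Season.winter), 0.45),
    ((Season.spring, Season.autumn), 0.25),
    ((Season.spring, Season.summer, Season.autumn), 0.20),
    ((Season.autumn, Season.winter), 0.10),
)


def generate_community(spec: CommunitySpec) -> Community:
    """Draw a synthetic community, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    guild_probs = [
        1 - spec.raptor_fraction - spec.waterfowl_fraction - spec.terrestrial_fraction,
        spec.waterfowl_fraction,
        spec.raptor_fraction,
        spec.terrestrial_fraction,
    ]
    guilds = rng.choice(
        ["songbird", "waterfowl", "raptor", "terrestrial"], size=n, p=guild_probs
    )

    traits: list[SpeciesTrait] = []
    truth: list[SpeciesTruth] = []
    pattern_probs = [p for _, p in _SEASON_PATTERNS]
    for i in range(n):
        guild = str(guilds[i])
        name = f"species_{i + 1:03d}"
        mass = float(
            np.clip(
                rng.lognormal(spec.mass_log_mean, spec.mass_log_sd), 10.0, 12000.0
            )
        )
        if guild == "waterfowl":  # waterfowl skew heavy
            mass = float(np.clip(mass * 4.0, 100.0, 12000.0))
        mu, sd = _HEIGHT_MODELS[guild]
        height = float(rng.lognormal(mu, sd))
        lo, hi = _CLUSTER_MODELS[guild]
        cluster = int(round(10 ** rng.uniform(lo, hi)))
        cluster = max(1, cluster)
        nearest = rng.choice(["A", "B", "C"], p=list(_NEAREST_ZONE_PROBS))
        zones = [nearest]
        for z in "ABC"[("ABC".index(nearest) + 1):]:
            if rng.random() < 0.5:
                zones.append(z)
        pattern_idx = rng.choice(len(_SEASON_PATTERNS), p=pattern_probs)
        seasons = _SEASON_PATTERNS[pattern_idx][0]
        abundance = float(rng.lognormal(0.0, spec.abundance_log_sd))
        is_raptor = guild == "raptor"
        family = str(rng.choice(_FAMILY_OF_GUILD[guild]))
        traits.append(
            SpeciesTrait(
                species_name=name, mean_body_mass_g=mass, is_raptor=is_raptor
            )
        )
        truth.append(
            SpeciesTruth(
                species_name=name,
                family=family,
                order=_ORDER_OF_GUILD[guild],
                guild=guild,
                mean_body_mass_g=mass,
                is_raptor=is_raptor,
                typical_height_m=height,
                max_cluster_size=cluster,
                occupied_zones=tuple(sorted(zones)),
                nearest_zone=nearest,
                seasons=tuple(s.value for s in seasons),
                abundance=abundance,
            )
        )
    return Community(spec=spec, traits=traits, truth=truth)


def _survey_units(n_units: int) -> list[tuple[str, Zone]]:
    """Allocate units to zones in the default 7:20:12 proportion."""
    total_default = sum(DEFAULT_UNITS_PER_ZONE.values())
    counts = {
        z: max(1, round(n_units * k / total_default))
        for z, k in DEFAULT_UNITS_PER_ZONE.items()
    }
    # fix rounding drift against the requested total
    while sum(counts.values()) > n_units:
        counts[max(counts, key=lambda z: counts[z])] -= 1
    while sum(counts.values()) < n_units:
        counts[min(counts, key=lambda z: counts[z])] += 1
    units = []
    for zone in Zone:
        for j in range(counts[zone]):
            units.append((f"{zone.value}{j + 1:02d}", zone))
    return units


def _draw_record(
    rng: np.random.Generator,
    sp: SpeciesTruth,
    unit_id: str,
    zone: Zone,
    date: _dt.date,
    force_group: int | None = None,
) -> SurveyRecord:
    if force_group is not None:
        group = force_group
    elif rng.random() < 0.3:
        group = sp.max_cluster_size
    else:
        group = int(rng.integers(1, sp.max_cluster_size + 1))
    count = group + int(rng.poisson(0.5 * sp.abundance))
    height = float(sp.typical_height_m * np.exp(rng.normal(0.0, 0.2)))
    crossed = bool(zone == Zone.A and rng.random() < 0.25)
    return SurveyRecord(
        species_name=sp.species_name,
        family=sp.family,
        order=sp.order,
        survey_unit_id=unit_id,
        date=date,
        zone=zone,
        count=count,
        flight_height_m=height,
        group_size=group,
        crossed_runway=crossed,
    )


def generate_surveys(
    community: Community,
    n_units: int = 39,
    n_months: int = 12,
    seed: int | None = None,
) -> list[SurveyRecord]:
    """Simulate monthly surveys of every unit over ``n_months`` months.

    Produces ``n_units * n_months`` unit-visits (468 by default). Encounter
    probability is higher in a species' nearest zone than in its other
    occupied zones and increases with its latent abundance; a species
    produces no records outside its occupied zones or present seasons.
    """
    if seed is None:
        seed = community.spec.seed + 1
    rng = np.random.default_rng(seed)
    units = _survey_units(n_units)
    months = [((m - 1) % 12) + 1 for m in range(1, n_months + 1)]
    year = 2019

    records: list[SurveyRecord] = []
    normal_species = [
        sp
        for sp in community.truth
        if sp.species_name not in (MAX_RISK_SPECIES, MIN_RISK_SPECIES)
    ]
    # per-(species, zone) encounter probabilities
    p_core = {
        sp.species_name: min(0.9, 1.0 - np.exp(-0.7 * sp.abundance))
        for sp in normal_species
    }
    p_edge = {
        sp.species_name: min(0.6, 1.0 - np.exp(-0.2 * sp.abundance))
        for sp in normal_species
    }

    visit_dates: dict[tuple[str, int], _dt.date] = {}
    for unit_id, _zone in units:
        for idx, month in enumerate(months):
            day = int(rng.integers(5, 25))
            visit_dates[(unit_id, idx)] = _dt.date(year, month, day)

    for idx, month in enumerate(months):
        season = _SEASON_OF_MONTH[month]
        for unit_id, zone in units:
            date = visit_dates[(unit_id, idx)]
            for sp in normal_species:
                if season.value not in sp.seasons:
                    continue
                if zone.value not in sp.occupied_zones:
                    continue
                is_core = zone.value == sp.nearest_zone
                p = p_core[sp.species_name] if is_core else p_edge[sp.species_name]
                if rng.random() >= p:
                    continue
                records.append(_draw_record(rng, sp, unit_id, zone, date))

    # core-zone detectability: every regular species' characteristic flock is
    # registered once per present season in its nearest zone whenever that
    # season was surveyed there — a monthly protocol is assumed intensive
    # enough to catch each regular species at its typical aggregation
    months_by_season: dict[str, list[int]] = {}
    for idx, month in enumerate(months):
        months_by_season.setdefault(_SEASON_OF_MONTH[month].value, []).append(idx)
    units_by_zone: dict[str, list[str]] = {}
    for unit_id, zone in units:
        units_by_zone.setdefault(zone.value, []).append(unit_id)
    for sp in normal_species:
        for season in sp.seasons:
            idx_choices = months_by_season.get(season)
            unit_choices = units_by_zone.get(sp.nearest_zone)
            if not idx_choices or not unit_choices:
                continue
            idx = idx_choices[int(rng.integers(len(idx_choices)))]
            unit_id = unit_choices[int(rng.integers(len(unit_choices)))]
            records.append(
                _draw_record(
                    rng,
                    sp,
                    unit_id,
                    Zone(sp.nearest_zone),
                    visit_dates[(unit_id, idx)],
                    force_group=sp.max_cluster_size,
                )
            )

    records.extend(_planted_records(community, records, units, visit_dates, months))
    records.sort(key=lambda r: (r.date, r.survey_unit_id, r.species_name))
    return records


def _planted_records(
    community: Community,
    records: list[SurveyRecord],
    units: list[tuple[str, Zone]],
    visit_dates: dict[tuple[str, int], _dt.date],
    months: list[int],
) -> list[SurveyRecord]:
    """Records for the planted extreme species, built after the community so
    the maximal-risk plant provably dominates every other species."""
    spec = community.spec
    planted: list[SurveyRecord] = []
    truth_by_name = {sp.species_name: sp for sp in community.truth}

    if spec.plant_max_risk and MAX_RISK_SPECIES in truth_by_name:
        sp = truth_by_name[MAX_RISK_SPECIES]
        mass_by_name = {t.species_name: t.mean_body_mass_g for t in community.traits}
        totals: dict[str, int] = {}
        for r in records:
            totals[r.species_name] = totals.get(r.species_name, 0) + r.count
        max_total = max(totals.values(), default=0)
        max_biomass = max(
            (n * mass_by_name[name] for name, n in totals.items()), default=0.0
        )
        a_units = [u for u, z in units if z == Zone.A]
        visits = [(u, idx) for u in a_units for idx in range(len(months))]
        # dominate both the community's count total and its biomass total
        target_total = max(
            int(max_total * 1.2),
            int(np.ceil(1.2 * max_biomass / sp.mean_body_mass_g)),
        ) + len(visits) * 150
        per_visit = max(150, target_total // len(visits) + 1)
        for u, idx in visits:
            planted.append(
                SurveyRecord(
                    species_name=sp.species_name,
                    family=sp.family,
                    order=sp.order,
                    survey_unit_id=u,
                    date=visit_dates[(u, idx)],
                    zone=Zone.A,
                    count=per_visit,
                    flight_height_m=40.0,
                    group_size=150,
                    crossed_runway=True,
                )
            )
    if spec.plant_min_risk and MIN_RISK_SPECIES in truth_by_name:
        sp = truth_by_name[MIN_RISK_SPECIES]
        c_units = [u for u, z in units if z == Zone.C]
        planted.append(
            SurveyRecord(
                species_name=sp.species_name,
                family=sp.family,
                order=sp.order,
                survey_unit_id=c_units[0],
                date=visit_dates[(c_units[0], 0)],
                zone=Zone.C,
                count=1,
                flight_height_m=200.0,
                group_size=1,
                crossed_runway=False,
            )
        )
    return planted


def plant_extremes(community: Community) -> Community:
    """Append the planted extreme species demanded by ``spec.plant_*`` flags."""
    spec = community.spec
    if spec.plant_max_risk:
        community.traits.append(
            SpeciesTrait(
                species_name=MAX_RISK_SPECIES,
                mean_body_mass_g=9000.0,
                is_raptor=False,
            )
        )
        community.truth.append(
            SpeciesTruth(
                species_name=MAX_RISK_SPECIES,
                family="anatidae",
                order="anseriformes",
                guild="waterfowl",
                mean_body_mass_g=9000.0,
                is_raptor=False,
                typical_height_m=40.0,
                max_cluster_size=150,
                occupied_zones=("A",),
                nearest_zone="A",
                seasons=tuple(s.value for s in Season),
                abundance=10.0,
            )
        )
    if spec.plant_min_risk:
        community.traits.append(
            SpeciesTrait(
                species_name=MIN_RISK_SPECIES,
                mean_body_mass_g=10.0,
                is_raptor=False,
            )
        )
        community.truth.append(
            SpeciesTruth(
                species_name=MIN_RISK_SPECIES,
                family="alaudidae",
                order="passeriformes",
                guild="songbird",
                mean_body_mass_g=10.0,
                is_raptor=False,
                typical_height_m=200.0,
                max_cluster_size=1,
                occupied_zones=("C",),
                nearest_zone="C",
                seasons=(Season.summer.value,),
                abundance=0.01,
            )
        )
    return community


def simulate(
    spec: CommunitySpec, n_units: int = 39, n_months: int = 12
) -> tuple[Community, list[SurveyRecord]]:
    """Generate a community (with any planted extremes) and its survey year."""
    community = plant_extremes(generate_community(spec))
    records = generate_surveys(community, n_units=n_units, n_months=n_months)
    return community, records


def write_dataset(
    out_dir: str | Path,
    community: Community,
    records: list[SurveyRecord],
) -> dict[str, Path]:
    """Write survey/trait CSVs plus a JSON sidecar with the spec and truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    survey_path = out_dir / "survey.csv"
    trait_path = out_dir / "traits.csv"
    sidecar_path = out_dir / "truth.json"

    lines = ["species,family,order,unit,date,zone,count,height_m,group_size,crossed_runway"]
    for r in records:
        lines.append(
            f"{r.species_name},{r.family},{r.order},{r.survey_unit_id},"
            f"{r.date.isoformat()},{r.zone.value},{r.count},"
            f"{r.flight_height_m:.2f},{r.group_size},{str(r.crossed_runway).lower()}"
        )
    survey_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["species,mass_g,is_raptor"]
    for t in community.traits:
        lines.append(
            f"{t.species_name},{t.mean_body_mass_g:.1f},{str(t.is_raptor).lower()}"
        )
    trait_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    sidecar = {
        "spec": asdict(community.spec),
        "truth": [asdict(sp) for sp in community.truth],
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")
    return {"survey": survey_path, "traits": trait_path, "truth": sidecar_path}
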