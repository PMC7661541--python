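"""Reading, validating and aggregating survey observation and trait tables.

Survey CSVs are UTF-8 with a header row and the columns
``species,family,order,unit,date,zone,count,height_m,group_size,crossed_runway``
(ISO-8601 dates); trait CSVs carry ``species,mass_g,is_raptor``. Column
names can be remapped through a schema dict. Rows that fail validation are
rejected individually and reported with their row number and a reason,
while a missing required column aborts the read.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_SEASON_OF_MONTH, RiskModelConfig
from .models import Season, SpeciesProfile, SpeciesTrait, SurveyRecord, Zone

#: canonical field -> default CSV column name
DEFAULT_SURVEY_SCHEMA: dict[str, str] = {
    "species_name": "species",
    "family": "family",
    "order": "order",
    "survey_unit_id": "unit",
    "date": "date",
    "zone": "zone",
    "count": "count",
    "flight_height_m": "height_m",
    "group_size": "group_size",
    "crossed_runway": "crossed_runway",
}

DEFAULT_TRAIT_SCHEMA: dict[str, str] = {
    "species_name": "species",
    "mean_body_mass_g": "mass_g",
    "is_raptor": "is_raptor",
}

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


class SurveySchemaError(ValueError):
    """A required column is absent from an input table."""


class MissingTraitError(KeyError):
    """Survey records reference species absent from the trait table."""

    def __init__(self, species: list[str]):
        self.species = sorted(species)
        super().__init__(
            "species missing from trait table: " + ", ".join(self.species)
        )


@dataclass(frozen=True)
class RowRejection:
    row_number: int  # 1-based data row number (header excluded)
    reason: str


@dataclass
class SurveyReadResult:
    records: list[SurveyRecord]
    rejected: list[RowRejection] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_bool(raw) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY or text == "nan":
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def read_survey(
    path: str | Path, schema: dict[str, str] | None = None
) -> SurveyReadResult:
    """Read a survey observation CSV into validated :class:`SurveyRecord` rows.

    Returns a :class:`SurveyReadResult` whose ``rejected`` list carries the
    1-based data row numbers of unparseable rows with a reason each.
    """
    mapping = dict(DEFAULT_SURVEY_SCHEMA)
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise SurveySchemaError(
            f"missing required column(s) in {path}: {', '.join(missing)}"
        )

    records: list[SurveyRecord] = []
    rejected: list[RowRejection] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            zone_raw = str(row[mapping["zone"]]).strip().upper()
            if zone_raw not in ("A", "B", "C"):
                raise ValueError(f"unknown zone {zone_raw!r}")
            record = SurveyRecord(
                species_name=str(row[mapping["species_name"]]).strip(),
                family=str(row[mapping["family"]]).strip(),
                order=str(row[mapping["order"]]).strip(),
                survey_unit_id=str(row[mapping["survey_unit_id"]]).strip(),
                date=_dt.date.fromisoformat(str(row[mapping["date"]]).strip()),
                zone=Zone(zone_raw),
                count=int(str(row[mapping["count"]]).strip()),
                flight_height_m=float(str(row[mapping["flight_height_m"]]).strip()),
                group_size=int(str(row[mapping["group_size"]]).strip()),
                crossed_runway=_parse_bool(row[mapping["crossed_runway"]]),
            )
        except (ValueError, KeyError) as exc:
            rejected.append(RowRejection(row_number=i, reason=str(exc)))
            continue
        records.append(record)
    return SurveyReadResult(records=records, rejected=rejected)


def read_traits(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[SpeciesTrait]:
    """Read a species trait CSV (mean body mass in grams, raptor flag)."""
    mapping = dict(DEFAULT_TRAIT_SCHEMA)
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise SurveySchemaError(
            f"missing required column(s) in {path}: {', '.join(missing)}"
        )
    traits: list[SpeciesTrait] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = str(row[mapping["species_name"]]).strip()
        if name in seen:
            raise ValueError(f"duplicate species in trait table: {name!r}")
        seen.add(name)
        traits.append(
            SpeciesTrait(
                species_name=name,
                mean_body_mass_g=float(str(row[mapping["mean_body_mass_g"]]).strip()),
                is_raptor=_parse_bool(row[mapping["is_raptor"]]),
            )
        )
    return traits


def assign_season(
    date: _dt.date, scheme: dict[int, Season] | None = None
) -> Season:
    """Map a calendar date to a season.

    The default scheme is Mar-May spring, Jun-Aug summer, Sep-Nov autumn,
    Dec-Feb winter.
    """
    scheme = scheme if scheme is not None else DEFAULT_SEASON_OF_MONTH
    return scheme[date.month]


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches
    half the total. Falls back to the plain median when all weights are zero."""
    if weights.sum() <= 0:
        return float(np.median(values))
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(values[idx])


def aggregate_profiles(
    records: list[SurveyRecord],
    traits: list[SpeciesTrait],
    config: RiskModelConfig | None = None,
) -> list[SpeciesProfile]:
    """Collapse survey records into one :class:`SpeciesProfile` per species.

    Totals are raw sums over all accepted records (no survey-effort
    normalization); the representative flight height is the count-weighted
    median of sighting heights (configurable to the mean); the cluster size
    is the maximum observed group size (configurable to a quantile); the
    nearest zone is the closest zone to the flight area (A < B < C) in
    which the species was ever recorded.
    """
    config = config or RiskModelConfig()
    trait_by_name = {t.species_name: t for t in traits}
    by_species: dict[str, list[SurveyRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_name, []).append(rec)

    missing = [name for name in by_species if name not in trait_by_name]
    if missing:
        raise MissingTraitError(missing)

    profiles: list[SpeciesProfile] = []
    for name in sorted(by_species):
        recs = by_species[name]
        trait = trait_by_name[name]
        heights = np.array([r.flight_height_m for r in recs], dtype=float)
        counts = np.array([r.count for r in recs], dtype=float)
        if config.height_statistic == "mean":
            height = (
                float(np.average(heights, weights=counts))
                if counts.sum() > 0
                else float(heights.mean())
            )
        else:
            height = _weighted_median(heights, counts)
        groups = [r.group_size for r in recs]
        if config.cluster_statistic == "max":
            cluster = max(groups)
        else:
            cluster = int(np.ceil(np.quantile(groups, config.cluster_statistic)))
        total = int(sum(r.count for r in recs))
        profiles.append(
            SpeciesProfile(
                species_name=name,
                family=recs[0].family,
                order=recs[0].order,
                total_count=total,
                total_biomass_g=total * trait.mean_body_mass_g,
                representative_flight_height_m=height,
                max_cluster_size=max(1, cluster),
                nearest_zone=min((r.zone for r in recs), key=lambda z: z.rank),
                is_raptor=trait.is_raptor,
                runway_crossings=sum(r.crossed_runway for r in recs),
                seasons_present=frozenset(
                    assign_season(r.date, config.season_of_month) for r in recs
                ),
            )
        )
    return profiles
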