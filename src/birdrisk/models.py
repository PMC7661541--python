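"""Core domain types for airport birdstrike risk assessment.

The model works on per-species aggregates of field survey data collected at
an airport (zone A), within 4 km of it (zone B) and within 8 km (zone C).
Each species receives five risk factors, a likelihood and a severity score
on a 0-100 scale, ordinal bands for both, and a danger level in {1, 2, 3}
(low / moderate / high danger).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum


class Zone(str, Enum):
    """Survey zone, ordered by proximity to the flight area (A nearest)."""

    A = "A"
    B = "B"
    C = "C"

    @property
    def rank(self) -> int:
        return "ABC".index(self.value)


class Season(str, Enum):
    spring = "spring"
    summer = "summer"
    autumn = "autumn"
    winter = "winter"


class Band(str, Enum):
    """Ordinal rating band for likelihood and severity scores."""

    very_low = "very_low"
    low = "low"
    moderate = "moderate"
    high = "high"
    very_high = "very_high"

    @property
    def ordinal(self) -> int:
        """1-based position, very_low = 1 ... very_high = 5."""
        return list(Band).index(self) + 1


@dataclass(frozen=True)
class SurveyRecord:
    """One field observation of one species at one survey unit.

    ``count`` is the number of individuals seen in the sighting and
    ``group_size`` the size of the largest cluster within it, so
    ``group_size <= count`` whenever individuals were actually counted.
    """

    species_name: str
    family: str
    order: str
    survey_unit_id: str
    date: _dt.date
    zone: Zone
    count: int
    flight_height_m: float
    group_size: int
    crossed_runway: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")
        if self.flight_height_m < 0:
            raise ValueError(
                f"flight_height_m must be non-negative, got {self.flight_height_m}"
            )
        if self.group_size < 1:
            raise ValueError(f"group_size must be positive, got {self.group_size}")
        if self.count >= 1 and self.group_size > self.count:
            raise ValueError(
                f"group_size {self.group_size} exceeds count {self.count}"
            )


@dataclass(frozen=True)
class SpeciesTrait:
    """Per-species traits needed by the scoring model."""

    species_name: str
    mean_body_mass_g: float
    is_raptor: bool = False

    def __post_init__(self) -> None:
        if self.mean_body_mass_g <= 0:
            raise ValueError(
                f"mean_body_mass_g must be positive, got {self.mean_body_mass_g}"
            )


@dataclass
class SpeciesProfile:
    """Aggregate of all survey records of one species over a survey period."""

    species_name: str
    family: str
    order: str
    total_count: int
    total_biomass_g: float
    representative_flight_height_m: float
    max_cluster_size: int
    nearest_zone: Zone
    is_raptor: bool
    runway_crossings: int
    seasons_present: frozenset[Season]


@dataclass(frozen=True)
class RiskFactors:
    """The five per-species risk coefficients.

    ``comparative_number`` and ``comparative_weight`` are stored as fractions
    in [0, 1] (species total over community maximum); the x100 scaling is
    applied once, inside the severity formula, which yields severity on the
    0-100 scale that the rating bands expect.
    """

    comparative_number: float
    comparative_weight: float
    flight_height_coeff: float
    cluster_coeff: float
    activity_coeff: float


@dataclass
class RiskScore:
    """Likelihood/severity scores, their bands, and the danger levels."""

    likelihood: float
    severity: float
    likelihood_band: Band
    severity_band: Band
    base_level: int
    adjusted_level: int
    adjustments_applied: list[str] = field(default_factory=list)
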